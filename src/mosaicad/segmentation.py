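"""Sparse change-point detection on the transformed b-deviation signal.

Two-stage design: a permissive candidate-breakpoint generator followed by
backward elimination (BE).  The generator is a deterministic multiscale
matched filter: for dyadic window sizes ``w`` it computes, at every probe
boundary, the t-statistic of the difference between the flanking ``w``-probe
means, and keeps local maxima of ``|t|`` above a sparseness threshold
``tau(a) = 2 (1 - a)``.  Larger ``a`` therefore admits more candidates.
Any boundary whose flanking windows differ by at least four noise SDs
yields ``|t| >= 4 sqrt(w/2) >> tau`` at the smallest scale and is always
recalled.  The BE stage then iteratively removes the least significant
remaining breakpoint (smallest ``|t|`` recomputed between the adjacent
segments) until all survivors reach the user threshold ``T``; because
removals proceed in a fixed significance order, the surviving set for a
higher ``T`` is nested inside the set for a lower one, which is what makes
``T`` a cheap FDR dial.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .bdev import BdevSignal
from .calls import SegmentCall
from .fdr import segment_pvalue
from .params import SegParams

__all__ = [
    "Breakpoint",
    "estimate_sigma",
    "sbl_candidates",
    "t_statistics",
    "backward_eliminate",
    "segment_signal",
    "GadaSegmenter",
]

_MIN_SCALE = 4
_MIN_GAP = 3


@dataclass(frozen=True)
class Breakpoint:
    """A boundary after probe ``index`` (0-based), with its t-statistic."""

    index: int
    t_stat: float


def estimate_sigma(values: np.ndarray) -> float:
    """Robust noise scale from successive differences.

    median(|x[i+1] - x[i]|) / (sqrt(2) * 0.6745): the MAD of first
    differences rescaled to the SD of Gaussian noise.  Insensitive to the
    level shifts the segmentation is meant to find.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(values)))) / (np.sqrt(2.0) * 0.6745)


_TAU_CAP = 5.5  # < 4 sqrt(2): keeps every 4-sigma boundary recallable at w = 4


def candidate_threshold(a: float, n: int) -> float:
    """Sparseness threshold of the candidate stage for a signal of length n.

    ``tau(a, n) = min(2 (1 - a) sqrt(2 ln n), 5.5)``.  The ``sqrt(2 ln n)``
    factor is the null extreme-value scale of the scan, so ``a`` near 1
    admits essentially every local maximum while ``a`` around 0.5 admits
    only boundaries that beat the null maximum — mirroring how a sparse
    hierarchical prior suppresses null breakpoints.  The cap keeps the
    guaranteed-recall contract: a boundary whose flanking windows differ
    by 4 noise SDs scores ``|t| = 4 sqrt(2) > 5.5`` at the smallest scale.
    """
    if a <= 0:
        raise ValueError(f"a must be positive, got {a}")
    scale = np.sqrt(2.0 * np.log(max(n, 8)))
    return min(max(2.0 * (1.0 - a) * scale, 0.0), _TAU_CAP)


def _suppression_radius(n: int) -> int:
    """Non-maximum-suppression / refinement radius, adaptive in signal length."""
    return int(np.clip(n // 8, _MIN_GAP, 16))


def _refine_positions(
    csum: np.ndarray, positions: list[int], sigma: float, radius: int
) -> list[int]:
    """Locally optimise each boundary position to maximise its |t|.

    Sweeps each boundary over ``+- radius`` probes (kept strictly between
    its neighbours) and moves it to the exhaustive maximum of the boundary
    t-statistic against the adjacent segments — the constrained
    single-change-point maximum-likelihood position.
    """
    n = len(csum) - 1
    refined = list(positions)
    for k, pos in enumerate(positions):
        lo = (refined[k - 1] if k else 0) + 1
        hi = (positions[k + 1] if k + 1 < len(positions) else n) - 1
        lo, hi = max(lo, pos - radius), min(hi, pos + radius)
        if hi <= lo:
            continue
        s = np.arange(lo, hi + 1)
        left_anchor = refined[k - 1] if k else 0
        right_anchor = positions[k + 1] if k + 1 < len(positions) else n
        m_l = (csum[s] - csum[left_anchor]) / (s - left_anchor)
        m_r = (csum[right_anchor] - csum[s]) / (right_anchor - s)
        t = (m_r - m_l) / (sigma * np.sqrt(1.0 / (s - left_anchor) + 1.0 / (right_anchor - s)))
        refined[k] = int(s[np.argmax(np.abs(t))])
    return sorted(set(refined))


def sbl_candidates(
    values: np.ndarray,
    a: float = 0.8,
    b: float = 0.0,
    max_iter: int = 0,
    tol: float = 0.0,
    sigma: float | None = None,
) -> list[Breakpoint]:
    """Generate sparse candidate breakpoints with provisional t-statistics.

    Multiscale matched filter: at each dyadic window size the t-statistic
    of the flanking-mean difference is computed at every interior boundary;
    local maxima exceeding :func:`candidate_threshold` contribute, evidence
    is aggregated across scales, nearby candidates are suppressed in
    favour of the strongest, and each survivor is refined to the local
    maximum-likelihood change-point position.

    ``b`` is accepted for interface compatibility (an uninformative second
    prior); ``max_iter``/``tol`` likewise — the generator is a single
    deterministic pass, so no convergence loop is involved.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2 * _MIN_SCALE:
        return []
    if sigma is None:
        sigma = estimate_sigma(values)
    sigma = max(float(sigma), 1e-12)
    tau = candidate_threshold(a, n)

    csum = np.concatenate(([0.0], np.cumsum(values)))
    score: dict[int, float] = {}
    w = _MIN_SCALE
    while w <= n // 2:
        i = np.arange(w, n - w + 1)  # boundary before probe i
        left = (csum[i] - csum[i - w]) / w
        right = (csum[i + w] - csum[i]) / w
        at = np.abs(right - left) / (sigma * np.sqrt(2.0 / w))
        if len(at) >= 3:
            local = np.flatnonzero((at[1:-1] > at[:-2]) & (at[1:-1] >= at[2:])) + 1
            for j in local:
                if at[j] >= tau:
                    bnd = int(i[j])
                    score[bnd] = max(score.get(bnd, 0.0), float(at[j]))
        w *= 2

    # non-maximum suppression: strongest aggregated evidence wins a radius
    radius = _suppression_radius(n)
    ordered = sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))
    kept: list[int] = []
    taken = np.zeros(n + 1, dtype=bool)
    for bnd, _ in ordered:
        lo, hi = max(0, bnd - radius), min(n, bnd + radius) + 1
        if not taken[lo:hi].any():
            kept.append(bnd)
            taken[bnd] = True
    if not kept:
        return []
    kept = _refine_positions(csum, sorted(kept), sigma, radius)
    t_prov = t_statistics(values, np.asarray(kept) - 1, sigma)
    # refinement can pull neighbours together; suppress the weaker again
    ordered2 = sorted(zip(kept, t_prov), key=lambda kv: (-abs(kv[1]), kv[0]))
    taken = np.zeros(n + 1, dtype=bool)
    final: list[int] = []
    for bnd, _ in ordered2:
        lo, hi = max(0, bnd - radius), min(n, bnd + radius) + 1
        if not taken[lo:hi].any():
            final.append(bnd)
            taken[bnd] = True
    final = sorted(final)
    t_prov = t_statistics(values, np.asarray(final) - 1, sigma)
    return [Breakpoint(index=p - 1, t_stat=float(t)) for p, t in zip(final, t_prov)]


def t_statistics(
    values: np.ndarray, breakpoints: list[int] | np.ndarray, sigma: float
) -> np.ndarray:
    """t-statistic of each boundary between its two adjacent segments.

    For the boundary between segments L and R:
    ``t = (mean_R - mean_L) / (sigma * sqrt(1/n_L + 1/n_R))``.
    ``breakpoints`` are sorted 0-based boundary-after-probe indices that
    partition the signal into segments of length >= 1.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    bps = np.asarray([int(b) for b in breakpoints], dtype=int)
    if len(bps) == 0:
        return np.array([])
    if np.any(np.diff(bps) <= 0) or bps[0] < 0 or bps[-1] >= n - 1:
        raise ValueError("breakpoints must be sorted and leave non-empty segments")
    sigma = max(float(sigma), 1e-12)
    bounds = np.concatenate(([0], bps + 1, [n]))
    csum = np.concatenate(([0.0], np.cumsum(values)))
    lens = np.diff(bounds)
    means = (csum[bounds[1:]] - csum[bounds[:-1]]) / lens
    return (means[1:] - means[:-1]) / (sigma * np.sqrt(1.0 / lens[:-1] + 1.0 / lens[1:]))


def backward_eliminate(
    values: np.ndarray,
    candidates: list[Breakpoint],
    T: float,
    min_seg_len: int = 2,
    sigma: float | None = None,
) -> list[Breakpoint]:
    """Backward elimination of candidate breakpoints, then short-segment merge.

    Repeatedly removes the breakpoint with the smallest ``|t|`` (recomputing
    the t-statistics of its neighbours after each removal) until every
    surviving breakpoint satisfies ``|t| >= T``.  Afterwards any segment
    shorter than ``min_seg_len`` is merged into the neighbour with the
    closer mean (ties merge left).  The surviving set for ``T2 > T1`` is a
    subset of the set for ``T1``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0 or not candidates:
        return []
    if sigma is None:
        sigma = estimate_sigma(values)
    sigma = max(float(sigma), 1e-12)
    csum = np.concatenate(([0.0], np.cumsum(values)))

    # linked list over boundary positions, sentinels at 0 and n
    bounds = sorted({bp.index + 1 for bp in candidates})
    if bounds and (bounds[0] < 1 or bounds[-1] > n - 1):
        raise ValueError("candidate breakpoints out of range")
    nodes = [0] + bounds + [n]
    nxt = {p: q for p, q in zip(nodes[:-1], nodes[1:])}
    prv = {q: p for p, q in zip(nodes[:-1], nodes[1:])}

    def boundary_t(pos: int) -> float:
        lo, hi = prv[pos], nxt[pos]
        m_l = (csum[pos] - csum[lo]) / (pos - lo)
        m_r = (csum[hi] - csum[pos]) / (hi - pos)
        return (m_r - m_l) / (sigma * np.sqrt(1.0 / (pos - lo) + 1.0 / (hi - pos)))

    version = {p: 0 for p in bounds}
    heap = [(abs(boundary_t(p)), p, 0) for p in bounds]
    heapq.heapify(heap)
    while heap:
        at, pos, ver = heapq.heappop(heap)
        if pos not in version or version[pos] != ver:
            continue
        if at >= T:
            break
        lo, hi = prv[pos], nxt[pos]
        del version[pos]
        nxt[lo], prv[hi] = hi, lo
        for nb in (lo, hi):
            if nb in version:
                version[nb] += 1
                heapq.heappush(heap, (abs(boundary_t(nb)), nb, version[nb]))

    surviving = sorted(version)

    # merge segments shorter than min_seg_len into the more similar neighbour
    if min_seg_len > 1 and surviving:
        bnd = [0] + surviving + [n]
        while len(bnd) > 2:
            lens = np.diff(bnd)
            short = [k for k in range(len(lens)) if lens[k] < min_seg_len]
            if not short:
                break
            k = min(short, key=lambda k: (lens[k], k))  # shortest, ties leftmost
            mean_k = (csum[bnd[k + 1]] - csum[bnd[k]]) / lens[k]
            if k == 0:
                drop = k + 1  # only a right neighbour: drop boundary after it
            elif k == len(lens) - 1:
                drop = k
            else:
                m_l = (csum[bnd[k]] - csum[bnd[k - 1]]) / (bnd[k] - bnd[k - 1])
                m_r = (csum[bnd[k + 2]] - csum[bnd[k + 1]]) / (bnd[k + 2] - bnd[k + 1])
                drop = k if abs(mean_k - m_l) <= abs(mean_k - m_r) else k + 1
            del bnd[drop]
        surviving = bnd[1:-1]

    if not surviving:
        return []
    t_final = t_statistics(values, np.asarray(surviving) - 1, sigma)
    return [Breakpoint(index=p - 1, t_stat=float(t)) for p, t in zip(surviving, t_final)]


def segment_signal(
    signal: BdevSignal,
    params: SegParams | None = None,
    background: float | None = None,
) -> list[SegmentCall]:
    """Segment one chromosome's transformed signal and emit altered calls.

    Orchestrates noise-scale estimation, candidate generation and backward
    elimination, then emits every segment whose mean transformed
    b-deviation exceeds the background level with a one-sided segment
    t-statistic ``(mean - background) * sqrt(n) / sigma >= T``.  The
    background defaults to the 10%-trimmed mean of this signal; when
    calling a multi-chromosome genome, pass the pooled genome-wide value so
    whole-chromosome events remain detectable.
    """
    params = params or SegParams()
    seg = GadaSegmenter(
        a=params.a,
        b=params.b,
        T=params.T,
        min_seg_len=params.min_seg_len,
        background=background,
    )
    seg.fit(signal.values)
    calls = []
    for (start, end), mean, t_seg in zip(
        seg.segments_, seg.segment_means_, seg.segment_t_
    ):
        n_probes = end - start + 1
        if n_probes < params.min_seg_len or not (mean > seg.background_ and t_seg >= params.T):
            continue
        calls.append(
            SegmentCall(
                chromosome=signal.chromosome,
                start_probe=start,
                end_probe=end,
                start_bp=int(signal.positions[start]),
                end_bp=int(signal.positions[end]),
                n_probes=n_probes,
                mean_tbdev=float(mean),
                t_stat=float(t_seg),
                p_value=segment_pvalue(t_seg, n_probes),
            )
        )
    return calls


class GadaSegmenter(BaseEstimator):
    """Change-point segmentation of a 1-D signal, scikit-learn style.

    ``fit(X)`` with ``X`` a 1-D array (or an ``(n, 1)`` column) detects
    constant-mean segments; ``fit_predict`` returns per-sample segment
    labels.  See the module docstring for the two-stage algorithm.

    Attributes (after fit)
    ----------------------
    sigma_ : float          robust noise scale
    candidates_ : list      unthresholded candidate breakpoints
    breakpoints_ : list     surviving :class:`Breakpoint` objects
    segments_ : list        (start, end) inclusive index pairs
    segment_means_ : ndarray  mean signal per segment
    segment_t_ : ndarray    one-sided t vs the background level
    background_ : float     background reference level
    labels_ : ndarray       per-sample segment label
    """

    def __init__(
        self,
        a: float = 0.8,
        b: float = 0.0,
        T: float = 8.0,
        min_seg_len: int = 300,
        background: float | None = None,
        trim: float = 0.1,
    ):
        self.a = a
        self.b = b
        self.T = T
        self.min_seg_len = min_seg_len
        self.background = background
        self.trim = trim

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("GadaSegmenter expects a 1-D signal")
        if len(X) < 2:
            raise ValueError("signal too short to segment")
        if not np.all(np.isfinite(X)):
            raise ValueError("signal contains non-finite values")
        n = len(X)
        self.sigma_ = max(estimate_sigma(X), 1e-12)
        self.candidates_ = sbl_candidates(X, a=self.a, b=self.b, sigma=self.sigma_)
        self.breakpoints_ = backward_eliminate(
            X, self.candidates_, T=self.T, min_seg_len=self.min_seg_len, sigma=self.sigma_
        )
        bounds = [0] + [bp.index + 1 for bp in self.breakpoints_] + [n]
        self.segments_ = [(bounds[k], bounds[k + 1] - 1) for k in range(len(bounds) - 1)]
        csum = np.concatenate(([0.0], np.cumsum(X)))
        lens = np.diff(bounds)
        self.segment_means_ = (csum[bounds[1:]] - csum[bounds[:-1]]) / lens
        self.background_ = (
            float(stats.trim_mean(X, self.trim))
            if self.background is None
            else float(self.background)
        )
        self.segment_t_ = (self.segment_means_ - self.background_) * np.sqrt(lens) / self.sigma_
        self.labels_ = np.repeat(np.arange(len(lens)), lens)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
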