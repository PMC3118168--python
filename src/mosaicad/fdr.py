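"""Segment p-values and a conservative genome-wide FDR estimator.

The null hypothesis for a called segment is that its mean transformed
b-deviation equals the background level.  The segment t-statistic is then
Student-t with ``n - 1`` degrees of freedom (standard normal for large
segments).  The genome-wide FDR for a threshold ``T`` is bounded by
treating the array as ``N / MinSegLen`` disjoint minimum-length windows,
each an independent test with tail probability ``P(|t_nu| > T)``,
``nu = MinSegLen - 1``:

    expected_false = (N / MinSegLen) * P(|t_nu| > T)
    FDR            = min(1, expected_false / n_called)

The bound is conservative by design and is validated against simulated
null tracks (see the benchmark module); it is monotone non-increasing in
both ``T`` and ``MinSegLen``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import SegParams

__all__ = [
    "FdrEstimate",
    "segment_pvalue",
    "estimate_fdr",
    "recommend_settings",
    "min_detectable_span_mb",
]

# above this segment size the normal tail replaces the Student-t tail
_NORMAL_SWITCH_N = 200

# coarse threshold ladder for preliminary scans: loose / moderate / strict
_T_GRID = (2.0, 4.0, 8.0)
_BASE_MIN_SEG_LEN = 300
_BASE_ARRAY_SIZE = 1_000_000


@dataclass(frozen=True)
class FdrEstimate:
    fdr: float
    expected_false: float
    n_called: int
    N: int
    T: float
    min_seg_len: int

    def __post_init__(self) -> None:
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")
        if self.expected_false < 0:
            raise ValueError("expected_false must be non-negative")


def _two_sided_tail(t: float, nu: int) -> float:
    if nu + 1 > _NORMAL_SWITCH_N:
        return float(2.0 * stats.norm.sf(abs(t)))
    return float(2.0 * stats.t.sf(abs(t), df=nu))


def segment_pvalue(t: float, n: int) -> float:
    """Two-sided tail probability P(|t_nu| > |t|) with nu = n - 1.

    For ``n > 200`` the standard-normal tail substitutes for the Student-t
    tail (they agree to better than 1e-3 well before that size).
    """
    if n < 2:
        raise ValueError(f"segment must span at least 2 probes, got {n}")
    return _two_sided_tail(float(t), n - 1)


def estimate_fdr(n_called: int, N: int, T: float, min_seg_len: int) -> FdrEstimate:
    """Conservative genome-wide FDR for a segmentation run.

    ``n_called`` emitted segments out of an array of ``N`` probes analysed
    at threshold ``T`` and minimum segment length ``min_seg_len``.  With no
    calls the FDR is reported as 0 (the expected number of false calls is
    still recorded), keeping parameter scans well defined.
    """
    if min_seg_len < 2 or N < min_seg_len:
        raise ValueError("need N >= min_seg_len >= 2")
    if n_called < 0:
        raise ValueError("n_called must be non-negative")
    expected_false = (N / min_seg_len) * _two_sided_tail(T, min_seg_len - 1)
    fdr = 0.0 if n_called == 0 else min(1.0, expected_false / n_called)
    return FdrEstimate(
        fdr=fdr,
        expected_false=expected_false,
        n_called=n_called,
        N=N,
        T=float(T),
        min_seg_len=min_seg_len,
    )


def recommend_settings(N: int, target_fdr: float) -> SegParams:
    """Parameters for a preliminary scan meeting a target FDR bound.

    ``MinSegLen`` is scaled proportionally to array density
    (300 probes per million array probes, floor 2) and the smallest
    threshold on the documented ladder ``T in {2, 4, 8}`` whose estimated
    FDR (at one call) meets ``target_fdr`` is selected.  Deterministic.

    Raises
    ------
    ValueError
        If no grid point satisfies the target; the message reports the
        closest achievable FDR.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 < target_fdr <= 1:
        raise ValueError("target_fdr must lie in (0, 1]")
    min_seg_len = max(2, round(_BASE_MIN_SEG_LEN * N / _BASE_ARRAY_SIZE))
    best = np.inf
    for T in _T_GRID:
        fdr = estimate_fdr(1, N, T, min_seg_len).fdr
        best = min(best, fdr)
        if fdr <= target_fdr:
            return SegParams(a=0.8, T=T, min_seg_len=min_seg_len)
    raise ValueError(
        f"target FDR {target_fdr} unsatisfiable on the T grid {_T_GRID}; "
        f"closest achievable is {best:.3g}"
    )


def min_detectable_span_mb(
    min_seg_len: int, n_probes: int, genome_mb: float = 3000.0
) -> float:
    """Genomic span (Mb) of ``min_seg_len`` probes at the array's density.

    Assumes probes uniformly cover ``genome_mb`` megabases; e.g. 300 probes
    on a 1M-probe array span 0.9 Mb.
    """
    if min_seg_len <= 0 or n_probes <= 0:
        raise ValueError("min_seg_len and n_probes must be positive")
    return min_seg_len * genome_mb / n_probes
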