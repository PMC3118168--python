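"""Event classification, cell-fraction estimation and the end-to-end caller.

Segments are called from BAF alone; the mean LRR of each call — relative
to the average LRR of the diploid autosomal genome outside all calls —
then classifies the event: deletion below -0.10, duplication above +0.10,
copy-neutral (UPD) inside the closed band [-0.10, +0.10].  A copy-number
call spanning more than 95% of its chromosome is promoted to a
whole-chromosome event (trisomy for gains, mosaic monosomy for losses).

The affected cell fraction follows from allelic dosage in a mixture of
normal and altered cells.  With fraction ``p`` altered and ``b`` the
heterozygous-band deviation |BAF - 0.5|:

    UPD          B = (1 + p) / 2        ->  p = 2 b
    deletion     B = 1 / (2 - p)        ->  p = 2 b / (0.5 + b)
    duplication  B = (1 + p) / (2 + p)  ->  p = 2 b / (0.5 - b)

(trisomy uses the duplication mapping, monosomy the deletion one).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .bdev import transform_track
from .calls import SegmentCall
from .fdr import FdrEstimate, estimate_fdr
from .params import SegParams
from .segmentation import segment_signal
from .tracks import ProbeTrack, chromosome_sort_key
from scipy import stats

__all__ = [
    "relative_mean_lrr",
    "classify_segment",
    "estimate_cell_fraction",
    "call_mosaics",
    "MosaicCaller",
]


def _raw_span(track: ProbeTrack, call: SegmentCall) -> tuple[int, int]:
    """Inclusive raw probe-index range covered by a call's bp span."""
    lo = int(np.searchsorted(track.positions, call.start_bp, side="left"))
    hi = int(np.searchsorted(track.positions, call.end_bp, side="right")) - 1
    return lo, hi


def relative_mean_lrr(
    tracks: dict[str, ProbeTrack],
    call: SegmentCall,
    all_calls: list[SegmentCall] | None = None,
) -> float:
    """Mean LRR of a call relative to the diploid autosomal baseline.

    The baseline is the mean LRR over all autosomal probes lying outside
    every called segment (X/Y are excluded from the baseline; the call's
    own span always is).  Adding a constant to every LRR leaves the result
    unchanged.
    """
    all_calls = all_calls if all_calls is not None else [call]
    baseline_parts, n_baseline = 0.0, 0
    for chrom, track in tracks.items():
        if not track.is_autosome:
            continue
        mask = np.ones(len(track), dtype=bool)
        for c in all_calls:
            if c.chromosome == chrom:
                lo, hi = _raw_span(track, c)
                mask[lo : hi + 1] = False
        lrr = track.lrr[mask]
        lrr = lrr[~np.isnan(lrr)]
        baseline_parts += float(lrr.sum())
        n_baseline += len(lrr)
    if n_baseline == 0:
        raise ValueError("no autosomal probes left to form an LRR baseline")
    baseline = baseline_parts / n_baseline
    track = tracks[call.chromosome]
    lo, hi = _raw_span(track, call)
    seg_lrr = track.lrr[lo : hi + 1]
    seg_lrr = seg_lrr[~np.isnan(seg_lrr)]
    if len(seg_lrr) == 0:
        return math.nan
    return float(seg_lrr.mean()) - baseline


def classify_segment(
    lrr_rel: float, chrom_coverage: float, params: SegParams | None = None
) -> str:
    """Classify a called segment from its relative LRR and chromosome coverage."""
    params = params or SegParams()
    if not 0 <= chrom_coverage <= 1:
        raise ValueError(f"chrom_coverage {chrom_coverage} outside [0, 1]")
    if math.isnan(lrr_rel):
        return "unclassified"
    band = params.lrr_upd_band
    if lrr_rel < -band:
        event = "deletion"
    elif lrr_rel > band:
        event = "duplication"
    else:
        event = "UPD"  # closed band: +-0.10 map to UPD
    if chrom_coverage > params.trisomy_fraction:
        if event == "duplication":
            return "trisomy"
        if event == "deletion":
            return "monosomy"
    return event


def estimate_cell_fraction(bdev_mean: float, event: str) -> float:
    """Affected cell proportion from the mean b-deviation of a call.

    ``bdev_mean`` is on the original BAF scale (not probit), must lie in
    [0, 0.5).  The mapping is the inverse of the allelic-dosage forward
    model for each event type, clipped to [0, 1]; strictly increasing in
    ``bdev_mean``.  Returns NaN for unclassified events.
    """
    if not 0 <= bdev_mean < 0.5:
        raise ValueError(f"bdev_mean must lie in [0, 0.5), got {bdev_mean}")
    if event == "UPD":
        p = 2.0 * bdev_mean
    elif event in ("deletion", "monosomy"):
        p = 2.0 * bdev_mean / (0.5 + bdev_mean)
    elif event in ("duplication", "trisomy"):
        p = 2.0 * bdev_mean / (0.5 - bdev_mean)
    elif event == "unclassified":
        return math.nan
    else:
        raise ValueError(f"unknown event label {event!r}")
    return float(np.clip(p, 0.0, 1.0))


def call_mosaics(
    tracks: dict[str, ProbeTrack], params: SegParams | None = None
) -> tuple[list[SegmentCall], FdrEstimate]:
    """Run the full pipeline on a genome of validated probe tracks.

    Per chromosome: transform to probit b-deviation over informative
    probes and segment against the genome-wide background; then annotate
    every call with p-value, relative LRR, event class and estimated cell
    fraction, and report the conservative genome-wide FDR.  Deterministic
    given inputs and parameters.
    """
    params = params or SegParams()
    chroms = sorted(tracks, key=chromosome_sort_key)
    signals = {}
    for chrom in chroms:
        sig = transform_track(tracks[chrom], params)
        if len(sig) < params.min_seg_len:
            warnings.warn(
                f"chromosome {chrom}: only {len(sig)} informative probes "
                f"(< MinSegLen {params.min_seg_len}); skipped",
                stacklevel=2,
            )
            continue
        signals[chrom] = sig
    if not signals:
        raise ValueError("no chromosome has enough informative probes")
    background = float(
        stats.trim_mean(np.concatenate([s.values for s in signals.values()]), 0.1)
    )
    calls: list[SegmentCall] = []
    for chrom, sig in signals.items():
        calls.extend(segment_signal(sig, params, background=background))

    N = sum(len(t) for t in tracks.values())
    fdr = estimate_fdr(len(calls), N, params.T, params.min_seg_len)

    for call in calls:
        track = tracks[call.chromosome]
        lo, hi = _raw_span(track, call)
        coverage = (hi - lo + 1) / len(track)
        try:
            lrr_rel = relative_mean_lrr(tracks, call, all_calls=calls)
        except ValueError:
            lrr_rel = math.nan
        call.mean_lrr = lrr_rel
        call.event = classify_segment(lrr_rel, coverage, params)
        sig = signals[call.chromosome]
        bdev_med = float(
            np.median(sig.bdev[call.start_probe : call.end_probe + 1])
        )
        call.cell_fraction = estimate_cell_fraction(min(bdev_med, 0.4999), call.event)
    return calls, fdr


class MosaicCaller(BaseEstimator):
    """End-to-end mosaic-alteration caller, scikit-learn style.

    ``fit`` takes a genome as ``{chromosome: ProbeTrack}`` (or a single
    :class:`ProbeTrack`) and populates ``calls_`` and ``fdr_``.  Parameter
    handling follows the scikit-learn convention (``get_params`` /
    ``set_params``), so the caller composes with its model-selection
    utilities.
    """

    def __init__(
        self,
        a: float = 0.8,
        b: float = 0.0,
        T: float = 8.0,
        min_seg_len: int = 300,
        epsilon: float = 5e-3,
        het_window: tuple[float, float] = (0.1, 0.9),
        lrr_upd_band: float = 0.10,
        trisomy_fraction: float = 0.95,
        segment_all_probes: bool = False,
    ):
        self.a = a
        self.b = b
        self.T = T
        self.min_seg_len = min_seg_len
        self.epsilon = epsilon
        self.het_window = het_window
        self.lrr_upd_band = lrr_upd_band
        self.trisomy_fraction = trisomy_fraction
        self.segment_all_probes = segment_all_probes

    def _params(self) -> SegParams:
        return SegParams(
            a=self.a,
            b=self.b,
            T=self.T,
            min_seg_len=self.min_seg_len,
            epsilon=self.epsilon,
            het_window=tuple(self.het_window),
            lrr_upd_band=self.lrr_upd_band,
            trisomy_fraction=self.trisomy_fraction,
            segment_all_probes=self.segment_all_probes,
        )

    def fit(self, X, y=None):
        if isinstance(X, ProbeTrack):
            X = {X.chromosome: X}
        self.calls_, self.fdr_ = call_mosaics(X, self._params())
        self.n_probes_ = sum(len(t) for t in X.values())
        return self

    def to_frame(self):
        """Fitted calls as a pandas DataFrame (one row per call)."""
        import pandas as pd

        if not hasattr(self, "calls_"):
            raise AttributeError("MosaicCaller is not fitted yet")
        from dataclasses import asdict

        return pd.DataFrame(
            [asdict(c) for c in self.calls_],
            columns=list(SegmentCall.__dataclass_fields__),
        )
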