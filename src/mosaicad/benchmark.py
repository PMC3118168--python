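"""Validation experiments: sensitivity curves, ROC grids, FDR calibration.

All experiments consume the synthetic generator, run the caller and score
against ground truth.  Scoring granularity is probe-level on the raw
(all-probe) index scale: a call's base-pair span is mapped back onto raw
probe indices before intersection with the truth block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bdev import transform_track
from .calls import SegmentCall
from .fdr import estimate_fdr
from .params import SegParams
from .segmentation import backward_eliminate, sbl_candidates, segment_signal
from .simulate import SimScenario, SimTruth, simulate_proportion_series, simulate_study_grid, simulate_track
from .tracks import ProbeTrack

__all__ = [
    "SensitivityCurve",
    "detection_success",
    "sensitivity_curve",
    "roc_experiment",
    "roc_auc",
    "fdr_calibration",
]


@dataclass
class SensitivityCurve:
    """Sensitivity as a function of mosaic cell proportion."""

    proportions: np.ndarray
    sensitivity: np.ndarray
    reps: int
    params: SegParams
    area: float = field(init=False)
    normalized_area: float = field(init=False)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if np.any((self.sensitivity < 0) | (self.sensitivity > 1)):
            raise ValueError("sensitivities must lie in [0, 1]")
        self.area = float(np.trapezoid(self.sensitivity, self.proportions))
        width = float(self.proportions[-1] - self.proportions[0])
        self.normalized_area = self.area / width if width > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"proportion": self.proportions, "sensitivity": self.sensitivity}
        )


def _covered_raw(track: ProbeTrack, call: SegmentCall) -> tuple[int, int]:
    lo = int(np.searchsorted(track.positions, call.start_bp, side="left"))
    hi = int(np.searchsorted(track.positions, call.end_bp, side="right")) - 1
    return lo, hi


def detection_success(
    calls: list[SegmentCall],
    truth: SimTruth,
    track: ProbeTrack,
    min_overlap: float = 0.5,
) -> bool:
    """True iff some call covers >= ``min_overlap`` of the truth block's probes.

    Coverage is evaluated per call (not pooled): one call must individually
    cover the required fraction of the simulated block.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must lie in (0, 1]")
    block = truth.end - truth.start + 1
    for call in calls:
        lo, hi = _covered_raw(track, call)
        overlap = min(hi, truth.end) - max(lo, truth.start) + 1
        if overlap / block >= min_overlap:
            return True
    return False


def _single_track_calls(track: ProbeTrack, params: SegParams) -> list[SegmentCall]:
    sig = transform_track(track, params)
    if len(sig) < params.min_seg_len:
        return []
    return segment_signal(sig, params)


def sensitivity_curve(
    proportions: list[float] | None = None,
    reps: int = 200,
    params: SegParams | None = None,
    master_seed: int = 0,
    min_overlap: float = 0.5,
    n_probes: int = 20_000,
    block_len: int = 1_000,
    sigma: float = 0.03,
) -> SensitivityCurve:
    """Detection sensitivity over a grid of mosaic cell proportions.

    Defaults reproduce the low-fraction benchmark: one 1,000-probe
    copy-neutral block inside a 20,000-probe track, proportions
    0, 0.01, ..., 0.15, 200 replicates each, caller at a = 0.5, T = 2,
    MinSegLen = 900, success when a call covers at least half the block.
    The curve area uses the trapezoid rule; the normalised area divides by
    the width of the proportion range (perfect-sensitivity area).
    """
    if proportions is None:
        proportions = [round(0.01 * k, 2) for k in range(16)]
    params = params or SegParams(a=0.5, T=2.0, min_seg_len=900)
    hits = np.zeros(len(proportions), dtype=int)
    series = simulate_proportion_series(
        proportions, reps=reps, master_seed=master_seed,
        n_probes=n_probes, block_len=block_len, sigma=sigma,
    )
    for k, p in enumerate(proportions):
        for _ in range(reps):
            track, truth = next(series)
            calls = _single_track_calls(track, params)
            hits[k] += detection_success(calls, truth, track, min_overlap)
    return SensitivityCurve(
        proportions=np.asarray(proportions),
        sensitivity=hits / reps,
        reps=reps,
        params=params,
    )


def roc_experiment(
    scenarios: list[SimScenario] | None = None,
    a_values: tuple[float, ...] = (0.2, 0.8),
    T_values: tuple[float, ...] = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
    reps: int = 25,
    master_seed: int = 0,
    min_seg_len: int = 300,
) -> pd.DataFrame:
    """Probe-level TPR/FPR over a parameter grid, one row per (scenario, a, T).

    TPR is the fraction of truth-block raw probes covered by calls, FPR the
    fraction of raw probes outside the block covered, both pooled over
    replicates.  Scenarios without altered probes report TPR as NaN.
    """
    scenarios = scenarios if scenarios is not None else simulate_study_grid(master_seed)
    rows = []
    rng_seeds = np.random.SeedSequence(master_seed).spawn(len(scenarios))
    for scen, sseq in zip(scenarios, rng_seeds):
        rep_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in sseq.spawn(reps)]
        counters = {
            (a, T): np.zeros(4)  # tp, block, fp, outside
            for a in a_values
            for T in T_values
        }
        for rep_seed in rep_seeds:
            track, truth = simulate_track(replace(scen, seed=rep_seed))
            n = len(track)
            has_block = truth.event != "none" and truth.proportion > 0
            for a in a_values:
                p0 = SegParams(a=a, T=min(T_values), min_seg_len=min_seg_len)
                sig = transform_track(track, p0)
                if len(sig) < min_seg_len:
                    continue
                for T in T_values:
                    params = SegParams(a=a, T=T, min_seg_len=min_seg_len)
                    calls = segment_signal(sig, params)
                    covered = np.zeros(n, dtype=bool)
                    for c in calls:
                        lo, hi = _covered_raw(track, c)
                        covered[lo : hi + 1] = True
                    block = np.zeros(n, dtype=bool)
                    if has_block:
                        block[truth.start : truth.end + 1] = True
                    tp = int((covered & block).sum())
                    fp = int((covered & ~block).sum())
                    counters[(a, T)] += (tp, int(block.sum()), fp, int((~block).sum()))
        for (a, T), (tp, nblock, fp, nout) in counters.items():
            rows.append(
                {
                    "scenario": scen.name or repr(scen),
                    "a": a,
                    "T": T,
                    "tpr": tp / nblock if nblock else np.nan,
                    "fpr": fp / nout if nout else np.nan,
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def roc_auc(table: pd.DataFrame) -> float:
    """Area under the ROC polyline of one (scenario, a) slice.

    Points are sorted by FPR with anchors (0, 0) and (1, 1) appended;
    the area uses the trapezoid rule.
    """
    pts = table[["fpr", "tpr"]].dropna().to_numpy()
    pts = np.vstack(([0.0, 0.0], pts, [1.0, 1.0]))
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def fdr_calibration(
    scenarios: list[SimScenario] | None = None,
    T_values: tuple[float, ...] = (4.0, 5.0, 8.0),
    reps: int = 50,
    master_seed: int = 0,
    a: float = 0.8,
    min_seg_len: int = 300,
) -> pd.DataFrame:
    """Simulated versus estimated FDR, one row per (scenario, T).

    Simulated FDR pools calls over replicates: a call is false when its
    raw-probe span is disjoint from the truth block.  The estimated FDR
    applies the analytic bound with the pooled call count.  The estimator
    is conservative, so estimated >= simulated is the expected pattern.
    """
    scenarios = scenarios if scenarios is not None else simulate_study_grid(master_seed)
    rows = []
    seeds = np.random.SeedSequence(master_seed).spawn(len(scenarios))
    for scen, sseq in zip(scenarios, seeds):
        rep_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in sseq.spawn(reps)]
        calls_per_T = {T: [0, 0] for T in T_values}  # total, false
        for rep_seed in rep_seeds:
            track, truth = simulate_track(replace(scen, seed=rep_seed))
            p0 = SegParams(a=a, T=min(T_values), min_seg_len=min_seg_len)
            sig = transform_track(track, p0)
            if len(sig) < min_seg_len:
                continue
            for T in T_values:
                params = SegParams(a=a, T=T, min_seg_len=min_seg_len)
                for c in segment_signal(sig, params):
                    lo, hi = _covered_raw(track, c)
                    disjoint = hi < truth.start or lo > truth.end
                    calls_per_T[T][0] += 1
                    calls_per_T[T][1] += int(disjoint)
        for T in T_values:
            total, false = calls_per_T[T]
            expected_false = estimate_fdr(1, scen.n_probes, T, min_seg_len).expected_false
            est = min(1.0, reps * expected_false / total) if total else 0.0
            rows.append(
                {
                    "scenario": scen.name or repr(scen),
                    "T": T,
                    "n_calls": total,
                    "n_false": false,
                    "fdr_simulated": false / total if total else 0.0,
                    "fdr_estimated": est,
                }
            )
    return pd.DataFrame(rows)
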