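"""B-deviation computation, probit transform and informative-probe selection.

The per-probe b-deviation is the absolute difference between the observed
B-allele frequency and the level expected for the probe's genotype (0, 0.5
or 1).  Under allelic imbalance the heterozygous cluster splits into twin
bands at 0.5 +- shift, so heterozygous b-deviation shifts away from its
noise floor.  The b-deviation distribution is folded (one-sided) and far
from Gaussian; a clamped probit transform Phi^-1(b_dev) is applied so that
a Gaussian-noise segmentation model is adequate downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import SegParams
from .tracks import ProbeTrack

GENOTYPE_LEVELS = {"AA": 0.0, "AB": 0.5, "BB": 1.0}

_LEVELS = np.array([0.0, 0.5, 1.0])


@dataclass
class BdevSignal:
    """Probit-transformed b-deviation over the informative probes of a track.

    ``probe_index`` maps each signal position back to the row of the source
    :class:`~mosaicad.tracks.ProbeTrack`; ``bdev`` keeps the untransformed
    b-deviation (used later for cell-fraction estimation).
    """

    values: np.ndarray
    probe_index: np.ndarray
    bdev: np.ndarray
    positions: np.ndarray
    chromosome: str
    epsilon: float

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.probe_index) == len(self.bdev) == len(self.positions)):
            raise ValueError("BdevSignal arrays must have identical length")
        if len(self.probe_index) > 1 and not np.all(np.diff(self.probe_index) > 0):
            raise ValueError("probe_index must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed values must be finite (clamping failed)")

    def __len__(self) -> int:
        return len(self.values)


def expected_baf(baf, genotype=None):
    """Expected BAF level in {0, 0.5, 1} for a probe.

    With a genotype call, AA -> 0, AB -> 0.5, BB -> 1.  Without one (or for
    a no-call), the nearest level to the observed BAF is used, ties broken
    toward 0.5 — favouring sensitivity to allelic imbalance at the 0.25 /
    0.75 boundaries.  Accepts scalars or arrays.
    """
    baf = np.asarray(baf, dtype=float)
    # distance to each level; stable argmin would pick 0 at the 0.25 tie,
    # so order levels as (0.5, 0, 1) to break ties toward 0.5
    order = np.array([0.5, 0.0, 1.0])
    nearest = order[np.argmin(np.abs(baf[..., None] - order), axis=-1)]
    if genotype is None:
        return nearest if nearest.ndim else float(nearest)
    if np.ndim(genotype) == 0:
        return GENOTYPE_LEVELS.get(genotype, float(nearest))
    genotype = np.asarray(genotype, dtype=object)
    out = nearest.copy()
    for g, level in GENOTYPE_LEVELS.items():
        out[genotype == g] = level
    return out


def compute_bdev(baf, expected):
    """b-deviation: absolute difference between observed and expected BAF."""
    return np.abs(np.asarray(baf, dtype=float) - expected)


def probit_bdev(bdev, epsilon: float = 5e-3):
    """Clamped probit transform Phi^-1(clip(b_dev, epsilon, 1 - epsilon)).

    Phi^-1(x) = sqrt(2) * erfinv(2x - 1); the clamp keeps the transform
    finite at b_dev = 0 (its value there is Phi^-1(epsilon)).
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    return stats.norm.ppf(np.clip(bdev, epsilon, 1.0 - epsilon))


def select_informative_probes(
    track: ProbeTrack,
    het_window: tuple[float, float] = (0.1, 0.9),
    use_genotypes: bool = True,
) -> np.ndarray:
    """Boolean mask of probes carrying allelic-imbalance information.

    With genotype calls present the AB probes are kept; otherwise probes
    whose BAF lies strictly inside ``het_window`` are kept.  Missing-BAF
    probes are always excluded.  Homozygous probes sit at BAF 0/1 in every
    mosaic state and would only dilute the segmentation signal.
    """
    ok = ~track.missing_baf
    if use_genotypes and track.genotype is not None:
        return ok & (track.genotype == "AB")
    lo, hi = het_window
    return ok & (track.baf > lo) & (track.baf < hi)


def transform_track(track: ProbeTrack, params: SegParams | None = None) -> BdevSignal:
    """Compute the probit-transformed b-deviation signal for one chromosome.

    Composes informative-probe selection, expected-BAF assignment,
    b-deviation and the clamped probit, preserving probe order.
    """
    params = params or SegParams()
    if params.segment_all_probes:
        mask = ~track.missing_baf
    else:
        mask = select_informative_probes(track, params.het_window)
    idx = np.flatnonzero(mask)
    baf = track.baf[idx]
    genotype = track.genotype[idx] if track.genotype is not None else None
    expected = expected_baf(baf, genotype)
    bdev = compute_bdev(baf, expected)
    values = probit_bdev(bdev, params.epsilon)
    return BdevSignal(
        values=np.asarray(values, dtype=float),
        probe_index=idx,
        bdev=bdev,
        positions=track.positions[idx],
        chromosome=track.chromosome,
        epsilon=params.epsilon,
    )
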