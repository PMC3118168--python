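"""Synthetic SNP-array tracks with mosaic alterations and ground truth.

The generator emulates the statistical structure of validation arrays:
20,000 probes per chromosome; homozygous BAF clusters hugging 0 and 1
(a skewed, log-normal-shaped deviation from the anchor with SD equal to
the noise level and mode near 0.005 at good quality); a heterozygous
cluster at Normal(0.5, sigma); and, inside an altered block, heterozygous
probes split evenly at random between twin bands at 0.5 +- shift.  Noise
levels: sigma = 0.03 ("good") or 0.1 ("noisy").  Band shifts 0.05 / 0.10
correspond to 10% / 20% of affected cells under the copy-neutral mapping
shift = p / 2.

LRR is generated per event so classification is testable end to end:
probe noise Normal(0, 0.15) plus a block offset of 0 for copy-neutral
events, log2((2 - p)/2) for deletions and log2((2 + p)/2) for gains.

What this generator does NOT emulate: GC waves, probe-specific bias,
raw two-channel intensities, genotyping error.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .tracks import ProbeTrack

__all__ = [
    "SimScenario",
    "SimTruth",
    "shift_for_proportion",
    "proportion_for_shift",
    "simulate_track",
    "simulate_study_grid",
    "simulate_proportion_series",
]

_LRR_NOISE_SD = 0.15
_PROBE_SPACING_BP = 1000
_EVENTS = ("UPD", "deletion", "duplication", "trisomy", "none")


def shift_for_proportion(p: float, event: str) -> float:
    """Heterozygous band displacement |BAF - 0.5| for cell fraction ``p``."""
    if not 0 <= p <= 1:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    if event == "none" or p == 0:
        return 0.0
    if event == "UPD":
        return p / 2.0
    if event == "deletion":
        return p / (2.0 * (2.0 - p))
    if event in ("duplication", "trisomy"):
        return p / (2.0 * (2.0 + p))
    raise ValueError(f"unknown event {event!r}")


def proportion_for_shift(shift: float, event: str) -> float:
    """Inverse of :func:`shift_for_proportion` (clipped to [0, 1])."""
    if shift < 0:
        raise ValueError(f"shift must be non-negative, got {shift}")
    if event == "none" or shift == 0:
        return 0.0
    if event == "UPD":
        p = 2.0 * shift
    elif event == "deletion":
        p = 4.0 * shift / (1.0 + 2.0 * shift)
    elif event in ("duplication", "trisomy"):
        p = 4.0 * shift / (1.0 - 2.0 * shift)
    else:
        raise ValueError(f"unknown event {event!r}")
    return float(np.clip(p, 0.0, 1.0))


def _lrr_offset(event: str, p: float) -> float:
    if event in ("none", "UPD"):
        return 0.0
    if event in ("deletion",):
        return math.log2((2.0 - p) / 2.0)
    if event in ("duplication", "trisomy"):
        return math.log2((2.0 + p) / 2.0)
    raise ValueError(f"unknown event {event!r}")


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated chromosome.

    ``mosaic_shift`` is the heterozygous band displacement; the implied
    cell fraction depends on the event type (``proportion`` property).
    ``block_start`` of None places the altered block at a seeded random
    position; trisomy alters the whole chromosome regardless of
    ``block_len``.
    """

    n_probes: int = 20_000
    sigma: float = 0.03
    mosaic_shift: float = 0.05
    block_len: int = 1_000
    event: str = "UPD"
    genotype_freqs: tuple[float, float, float] = (0.25, 0.50, 0.25)
    seed: int | None = None
    block_start: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.event not in _EVENTS:
            raise ValueError(f"unknown event {self.event!r}")
        if not 0 < self.block_len <= self.n_probes:
            raise ValueError("block_len must lie in (0, n_probes]")
        if abs(sum(self.genotype_freqs) - 1.0) > 1e-9:
            raise ValueError("genotype_freqs must sum to 1")
        if self.mosaic_shift < 0 or self.mosaic_shift >= 0.5:
            raise ValueError("mosaic_shift must lie in [0, 0.5)")

    @property
    def proportion(self) -> float:
        """Cell fraction implied by the band shift under this event type."""
        return proportion_for_shift(self.mosaic_shift, self.event)

    @classmethod
    def from_proportion(cls, p: float, event: str = "UPD", **kwargs) -> "SimScenario":
        return cls(mosaic_shift=shift_for_proportion(p, event), event=event, **kwargs)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated track: altered block and its nature."""

    start: int
    end: int
    event: str
    proportion: float
    scenario: SimScenario

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end < self.scenario.n_probes:
            raise ValueError("truth block indices out of range")


def _homozygous_deviation(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    # log-normal-shaped deviation from the homozygous anchor: SD = sigma,
    # mode ~ 0.17 * sigma (0.005 at sigma = 0.03)
    return np.exp(rng.normal(np.log(sigma) - 0.7705, 1.0, size))


def simulate_track(
    scenario: SimScenario, chromosome: str = "1"
) -> tuple[ProbeTrack, SimTruth]:
    """Generate one chromosome and its ground truth.

    Byte-identical output for a fixed ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_probes
    genotype = rng.choice(np.array(["AA", "AB", "BB"], dtype=object), size=n,
                          p=scenario.genotype_freqs)
    baf = np.empty(n)
    aa, ab, bb = genotype == "AA", genotype == "AB", genotype == "BB"
    baf[aa] = np.clip(_homozygous_deviation(rng, scenario.sigma, int(aa.sum())), 0, 1)
    baf[bb] = 1.0 - np.clip(_homozygous_deviation(rng, scenario.sigma, int(bb.sum())), 0, 1)
    baf[ab] = np.clip(rng.normal(0.5, scenario.sigma, int(ab.sum())), 0, 1)

    event, p = scenario.event, scenario.proportion
    lrr = rng.normal(0.0, _LRR_NOISE_SD, n)
    if event == "trisomy":
        start, block_len = 0, n
    else:
        block_len = scenario.block_len
        start = (
            int(rng.integers(0, n - block_len + 1))
            if scenario.block_start is None
            else scenario.block_start
        )
    end = start + block_len - 1
    if event != "none":
        in_block = np.zeros(n, dtype=bool)
        in_block[start : end + 1] = True
        het_block = np.flatnonzero(in_block & ab)
        upper = rng.random(len(het_block)) < 0.5
        centers = np.where(upper, 0.5 + scenario.mosaic_shift, 0.5 - scenario.mosaic_shift)
        baf[het_block] = np.clip(
            rng.normal(centers, scenario.sigma), 0, 1
        )
        lrr[start : end + 1] += _lrr_offset(event, p)

    positions = 1 + _PROBE_SPACING_BP * np.arange(n, dtype=np.int64)
    names = np.array([f"rs{chromosome}_{k}" for k in range(n)], dtype=object)
    track = ProbeTrack(
        chromosome=chromosome,
        probe_names=names,
        positions=positions,
        baf=baf,
        lrr=lrr,
        genotype=genotype,
    )
    truth = SimTruth(start=start, end=end, event=event,
                     proportion=p if event != "none" else 0.0, scenario=scenario)
    return track, truth


def _child_seeds(master_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def simulate_study_grid(master_seed: int = 0) -> list[SimScenario]:
    """The eight study scenarios: {10%, 20%} x {small, large} x {good, noisy}.

    Band shifts 0.05 / 0.10; block lengths 1,000 (small) / 10,000 (large);
    noise SD 0.03 (good) / 0.1 (noisy).  Seeds derive from ``master_seed``.
    """
    seeds = _child_seeds(master_seed, 8)
    grid = []
    k = 0
    for shift, pct in ((0.05, 10), (0.10, 20)):
        for block_len, size in ((1_000, "small"), (10_000, "large")):
            for sigma, quality in ((0.03, "good"), (0.1, "noisy")):
                grid.append(
                    SimScenario(
                        mosaic_shift=shift,
                        block_len=block_len,
                        sigma=sigma,
                        seed=seeds[k],
                        name=f"{quality}-{pct}-{size}",
                    )
                )
                k += 1
    return grid


def simulate_proportion_series(
    proportions: list[float] | None = None,
    reps: int = 200,
    master_seed: int = 0,
    n_probes: int = 20_000,
    block_len: int = 1_000,
    sigma: float = 0.03,
) -> Iterator[tuple[ProbeTrack, SimTruth]]:
    """Tracks for the sensitivity-versus-proportion experiment.

    For each proportion ``p`` (default 0, 0.01, ..., 0.15) yields ``reps``
    independent tracks carrying one ``block_len``-probe copy-neutral block
    with band shift ``p / 2``.  Seeds are reproducible per (p, rep).
    Yields tuples in proportion-major order.
    """
    if proportions is None:
        proportions = [round(0.01 * k, 2) for k in range(16)]
    if any(not 0 <= p <= 1 for p in proportions):
        raise ValueError("proportions must lie in [0, 1]")
    seeds = _child_seeds(master_seed, len(proportions) * reps)
    k = 0
    for p in proportions:
        for _ in range(reps):
            scenario = SimScenario.from_proportion(
                p,
                event="UPD",
                n_probes=n_probes,
                block_len=block_len,
                sigma=sigma,
                seed=seeds[k],
                name=f"p={p}",
            )
            yield simulate_track(scenario)
            k += 1
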