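"""Per-chromosome probe containers and their validation rules."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

GENOTYPES = ("AA", "AB", "BB", "NC")

_SEX_LABELS = {"X", "Y", "chrX", "chrY", "23", "24"}


@dataclass
class ProbeTrack:
    """Ordered probe records for one chromosome.

    Attributes
    ----------
    chromosome : str
        Chromosome label ("1".."22", "X", "Y"); kept as a string.
    probe_names : ndarray of str
    positions : ndarray of int
        1-based base-pair positions, strictly increasing after
        :func:`sort_and_validate`.
    baf : ndarray of float
        B-allele frequency in [0, 1]; missing values are NaN (never
        silently 0).
    lrr : ndarray of float
        log2 intensity ratio; missing values are NaN.
    genotype : ndarray of str or None
        Optional calls in {AA, AB, BB, NC}.
    """

    chromosome: str
    probe_names: np.ndarray
    positions: np.ndarray
    baf: np.ndarray
    lrr: np.ndarray
    genotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probe_names = np.asarray(self.probe_names, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.baf = np.asarray(self.baf, dtype=np.float64)
        self.lrr = np.asarray(self.lrr, dtype=np.float64)
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype, dtype=object)
        n = len(self.positions)
        for name in ("probe_names", "baf", "lrr"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{name} has length {len(getattr(self, name))}, expected {n}"
                )
        if self.genotype is not None and len(self.genotype) != n:
            raise ValueError(f"genotype has length {len(self.genotype)}, expected {n}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def missing_baf(self) -> np.ndarray:
        """Boolean mask of probes with missing BAF."""
        return np.isnan(self.baf)

    @property
    def is_autosome(self) -> bool:
        return self.chromosome not in _SEX_LABELS


def chromosome_sort_key(label: str):
    """Natural ordering for chromosome labels: 1..22, X, Y, then others."""
    name = label[3:] if label.lower().startswith("chr") else label
    try:
        return (0, int(name), "")
    except ValueError:
        order = {"X": 23, "Y": 24, "MT": 25, "M": 25}
        return (0, order[name], "") if name in order else (1, 0, name)


def sort_and_validate(track: ProbeTrack) -> ProbeTrack:
    """Sort a track by position and enforce the container invariants.

    Probes are stably sorted by base-pair position; duplicate positions keep
    the first occurrence (a warning is emitted).  BAF values must be NaN or
    within [0, 1] — out-of-range values raise, naming the offending probe.

    Raises
    ------
    ValueError
        If every BAF is missing (unusable track) or a BAF is out of range.
    """
    if len(track) == 0:
        raise ValueError(f"chromosome {track.chromosome}: empty track")
    order = np.argsort(track.positions, kind="stable")
    pos = track.positions[order]
    keep = np.ones(len(pos), dtype=bool)
    if len(pos) > 1:
        keep[1:] = pos[1:] != pos[:-1]
    if not keep.all():
        warnings.warn(
            f"chromosome {track.chromosome}: dropped {int((~keep).sum())} probe(s) "
            "at duplicated positions (kept first occurrence)",
            stacklevel=2,
        )
    idx = order[keep]
    baf = track.baf[idx]
    finite = ~np.isnan(baf)
    if not finite.any():
        raise ValueError(f"chromosome {track.chromosome}: all BAF values are missing")
    bad = finite & ((baf < 0) | (baf > 1))
    if bad.any():
        name = track.probe_names[idx][bad][0]
        raise ValueError(
            f"chromosome {track.chromosome}: BAF out of [0, 1] at probe {name!r}"
        )
    return ProbeTrack(
        chromosome=track.chromosome,
        probe_names=track.probe_names[idx],
        positions=track.positions[idx],
        baf=baf,
        lrr=track.lrr[idx],
        genotype=None if track.genotype is None else track.genotype[idx],
    )
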