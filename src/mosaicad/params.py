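"""Tunable parameters of the mosaic-alteration caller.

All knobs that influence segmentation, FDR control and classification live
in a single :class:`SegParams` container so that a run is fully described
by one object (and can be dumped into a reproducibility manifest).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class SegParams:
    """Parameter set for the b-deviation segmentation pipeline.

    Parameters
    ----------
    a : float
        Sparseness parameter of the candidate-breakpoint stage
        (dimensionless, typical range 0.2-0.8).  Larger values admit more
        candidate breakpoints, i.e. higher sensitivity before backward
        elimination.
    b : float
        Second prior parameter of the candidate stage.  Kept at 0 as an
        uninformative prior; sparseness is then controlled by ``a`` alone.
    T : float
        Backward-elimination threshold: breakpoints whose t-statistic falls
        below ``T`` are iteratively removed.  Also gates the one-sided
        segment-level significance test used to emit altered calls.
    min_seg_len : int
        Minimum number of informative probes per emitted segment.  Segments
        shorter than this are merged into their more similar neighbour.
    epsilon : float
        Clamp constant for the probit transform; b-deviation values are
        clipped to ``[epsilon, 1 - epsilon]`` before applying the normal
        quantile.  The default 5e-3 keeps the transformed null signal
        close to symmetric (|skewness| well below 0.5 at sigma = 0.03);
        much smaller clamps leave a long left tail from near-zero
        deviations.
    het_window : tuple of float
        Open BAF interval used to select heterozygous (informative) probes
        when genotype calls are absent.
    lrr_upd_band : float
        Symmetric relative-LRR band for copy-neutral calls: segments with
        mean relative LRR inside ``[-band, +band]`` are classified UPD.
    trisomy_fraction : float
        Chromosome-coverage fraction above which a copy-number call is
        promoted to a whole-chromosome event (trisomy / monosomy).
    sigma_estimator : str
        Noise-scale rule; ``"mad_diff"`` is the median absolute successive
        difference divided by ``sqrt(2) * 0.6745``.
    segment_all_probes : bool
        If True, segment every non-missing probe instead of the informative
        (heterozygous) subset.  Off by default: homozygous probes carry
        b-deviation ~0 regardless of mosaic state and dilute the signal.
    """

    a: float = 0.8
    b: float = 0.0
    T: float = 8.0
    min_seg_len: int = 300
    epsilon: float = 5e-3
    het_window: tuple[float, float] = (0.1, 0.9)
    lrr_upd_band: float = 0.10
    trisomy_fraction: float = 0.95
    sigma_estimator: str = "mad_diff"
    segment_all_probes: bool = False

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.min_seg_len < 2:
            raise ValueError(f"min_seg_len must be >= 2, got {self.min_seg_len}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must lie in (0, 0.5), got {self.epsilon}")
        lo, hi = self.het_window
        if not 0 <= lo < hi <= 1:
            raise ValueError(f"het_window must be an interval within [0, 1], got {self.het_window}")
        if not 0 <= self.trisomy_fraction <= 1:
            raise ValueError(
                f"trisomy_fraction must lie in [0, 1], got {self.trisomy_fraction}"
            )
        if self.lrr_upd_band < 0:
            raise ValueError(f"lrr_upd_band must be non-negative, got {self.lrr_upd_band}")
        if self.sigma_estimator != "mad_diff":
            raise ValueError(f"unknown sigma_estimator {self.sigma_estimator!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["het_window"] = list(self.het_window)
        return d
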