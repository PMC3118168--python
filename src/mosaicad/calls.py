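"""Segment-call record shared across the pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

EVENT_LABELS = ("deletion", "duplication", "UPD", "trisomy", "monosomy", "unclassified")


@dataclass
class SegmentCall:
    """A called region of allelic imbalance.

    ``start_probe``/``end_probe`` are 0-based inclusive indices into the
    informative-probe subset of the chromosome; ``start_bp``/``end_bp`` are
    the 1-based inclusive base-pair positions of those probes.  ``t_stat``
    is the one-sided segment t-statistic against the genome-wide background
    level of the transformed b-deviation.
    """

    chromosome: str
    start_probe: int
    end_probe: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_tbdev: float
    t_stat: float
    p_value: float
    mean_lrr: float = math.nan
    event: str = "unclassified"
    cell_fraction: float = math.nan

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")
        if self.start_probe > self.end_probe:
            raise ValueError(f"start_probe {self.start_probe} > end_probe {self.end_probe}")
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not math.isnan(self.cell_fraction) and not 0 <= self.cell_fraction <= 1:
            raise ValueError(f"cell_fraction {self.cell_fraction} outside [0, 1]")
        if self.event not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.event!r}")
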