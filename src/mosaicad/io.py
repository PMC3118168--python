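"""Reading and writing SNP-array probe tables and segment calls.

Input follows the BeadStudio "Final Report" / PennCNV signal-file layout:
a delimited table with one row per probe and columns for probe name,
chromosome, position, ``Log R Ratio`` and ``B Allele Freq`` (a genotype
column is optional).  Columns may carry a sample prefix
(``SAMPLE.B Allele Freq``); the dialect matches either exactly or by
suffix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import SegmentCall
from .tracks import ProbeTrack, chromosome_sort_key, sort_and_validate

__all__ = [
    "TableDialect",
    "PENNCNV_DIALECT",
    "read_probe_table",
    "write_probe_table",
    "write_segment_calls",
    "read_segment_calls",
]


@dataclass(frozen=True)
class TableDialect:
    """Column names (or suffixes) identifying the probe-table fields."""

    name: str = "Name"
    chromosome: str = "Chr"
    position: str = "Position"
    lrr: str = "Log R Ratio"
    baf: str = "B Allele Freq"
    genotype: str | None = "GType"


PENNCNV_DIALECT = TableDialect()

_CALL_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "start_probe",
    "end_probe",
    "n_probes",
    "mean_tbdev",
    "t_stat",
    "p_value",
    "mean_lrr",
    "event",
    "cell_fraction",
]


def _resolve_column(df: pd.DataFrame, wanted: str, required: bool):
    if wanted in df.columns:
        return wanted
    # sample-prefixed variant, e.g. "NA12878.B Allele Freq"
    matches = [c for c in df.columns if c.endswith("." + wanted) or c.endswith(wanted)]
    if len(matches) == 1:
        return matches[0]
    if required:
        raise ValueError(f"probe table is missing mandatory column {wanted!r}")
    return None


def read_probe_table(
    path: str | Path,
    dialect: TableDialect = PENNCNV_DIALECT,
) -> dict[str, ProbeTrack]:
    """Read a probe table into one validated :class:`ProbeTrack` per chromosome.

    The delimiter (tab or comma) is sniffed.  Non-numeric BAF/LRR entries
    are flagged missing (NaN); rows are sorted by position within each
    chromosome.  Returns a dict keyed by chromosome label, in natural
    chromosome order.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"{path}: empty probe table") from None
    if df.empty:
        raise ValueError(f"{path}: empty probe table")
    cols = {
        key: _resolve_column(df, getattr(dialect, key), required=key != "genotype")
        for key in ("name", "chromosome", "position", "lrr", "baf", "genotype")
        if getattr(dialect, key) is not None
    }
    out: dict[str, ProbeTrack] = {}
    chrom_series = df[cols["chromosome"]].astype(str).str.strip()
    for chrom in sorted(chrom_series.unique(), key=chromosome_sort_key):
        sub = df[chrom_series == chrom]
        genotype = None
        if cols.get("genotype"):
            genotype = sub[cols["genotype"]].fillna("NC").to_numpy(dtype=object)
        track = ProbeTrack(
            chromosome=chrom,
            probe_names=sub[cols["name"]].to_numpy(dtype=object),
            positions=pd.to_numeric(sub[cols["position"]], errors="raise").to_numpy(
                dtype=np.int64
            ),
            baf=pd.to_numeric(sub[cols["baf"]], errors="coerce").to_numpy(dtype=float),
            lrr=pd.to_numeric(sub[cols["lrr"]], errors="coerce").to_numpy(dtype=float),
            genotype=genotype,
        )
        out[chrom] = sort_and_validate(track)
    return out


def write_probe_table(
    tracks: dict[str, ProbeTrack] | ProbeTrack,
    path: str | Path,
    dialect: TableDialect = PENNCNV_DIALECT,
) -> None:
    """Write tracks back to the tab-delimited probe-table layout."""
    if isinstance(tracks, ProbeTrack):
        tracks = {tracks.chromosome: tracks}
    frames = []
    for chrom in sorted(tracks, key=chromosome_sort_key):
        t = tracks[chrom]
        data = {
            dialect.name: t.probe_names,
            dialect.chromosome: t.chromosome,
            dialect.position: t.positions,
            dialect.lrr: t.lrr,
            dialect.baf: t.baf,
        }
        if t.genotype is not None and dialect.genotype is not None:
            data[dialect.genotype] = t.genotype
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_segment_calls(
    calls: list[SegmentCall], path: str | Path, bed: bool = False
) -> None:
    """Write segment calls as TSV (default) or 0-based half-open BED.

    The TSV dialect round-trips through :func:`read_segment_calls`.  The
    BED dialect emits chrom / start / end / event / cell_fraction with
    coordinates converted from the internal 1-based inclusive convention.
    """
    path = Path(path)
    if bed:
        rows = [
            {
                "chrom": c.chromosome,
                "start": c.start_bp - 1,
                "end": c.end_bp,
                "name": c.event,
                "score": 0 if math.isnan(c.cell_fraction) else round(1000 * c.cell_fraction),
            }
            for c in calls
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]).to_csv(
            path, sep="\t", index=False, header=False
        )
        return
    rows = [
        {
            "chrom": c.chromosome,
            "start_bp": c.start_bp,
            "end_bp": c.end_bp,
            "start_probe": c.start_probe,
            "end_probe": c.end_probe,
            "n_probes": c.n_probes,
            "mean_tbdev": c.mean_tbdev,
            "t_stat": c.t_stat,
            "p_value": c.p_value,
            "mean_lrr": c.mean_lrr,
            "event": c.event,
            "cell_fraction": c.cell_fraction,
        }
        for c in calls
    ]
    # default float formatting is repr-based and round-trips bit-exactly
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segment_calls(path: str | Path) -> list[SegmentCall]:
    """Read back a TSV produced by :func:`write_segment_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing segment-call column(s) {missing}")
    return [
        SegmentCall(
            chromosome=str(r.chrom),
            start_probe=int(r.start_probe),
            end_probe=int(r.end_probe),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_probes=int(r.n_probes),
            mean_tbdev=float(r.mean_tbdev),
            t_stat=float(r.t_stat),
            p_value=float(r.p_value),
            mean_lrr=float(r.mean_lrr),
            event=str(r.event),
            cell_fraction=float(r.cell_fraction),
        )
        for r in df.itertuples()
    ]
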