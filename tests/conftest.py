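"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mosaicad import ProbeTrack, SegParams, SimScenario, simulate_track

# property tests must behave identically on every machine and run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# independent change-point oracles: exhaustive least-squares searches,
# deliberately written without reusing any package internals
# ---------------------------------------------------------------------------

def exhaustive_one_changepoint(x: np.ndarray) -> int:
    """Boundary-after-probe index of the best single-change-point LS fit."""
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(np.square(x))])
    rss = [
        (c2[s] - c[s] ** 2 / s) + (c2[n] - c2[s] - (c[n] - c[s]) ** 2 / (n - s))
        for s in range(1, n)
    ]
    return int(np.argmin(rss))


def exhaustive_two_changepoints(x: np.ndarray) -> tuple[int, int]:
    """Boundary indices of the best two-change-point LS fit."""
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(np.square(x))])

    def rss(i, j):
        return c2[j] - c2[i] - (c[j] - c[i]) ** 2 / (j - i)

    best, best_r = None, np.inf
    for s in range(1, n - 1):
        left = rss(0, s)
        for t in range(s + 1, n):
            r = left + rss(s, t) + rss(t, n)
            if r < best_r:
                best, best_r = (s - 1, t - 1), r
    return best


# ---------------------------------------------------------------------------
# small constructed tracks
# ---------------------------------------------------------------------------

def make_track(
    baf,
    lrr=None,
    positions=None,
    chromosome="1",
    genotype=None,
) -> ProbeTrack:
    baf = np.asarray(baf, dtype=float)
    n = len(baf)
    return ProbeTrack(
        chromosome=chromosome,
        probe_names=np.array([f"p{i}" for i in range(n)], dtype=object),
        positions=np.arange(1, n + 1, dtype=np.int64) * 100
        if positions is None
        else np.asarray(positions, dtype=np.int64),
        baf=baf,
        lrr=np.zeros(n) if lrr is None else np.asarray(lrr, dtype=float),
        genotype=None if genotype is None else np.asarray(genotype, dtype=object),
    )


@pytest.fixture
def toy_table(tmp_path):
    """5-row probe table spanning chromosomes 1 and 2, tab-delimited."""
    path = tmp_path / "probes.tsv"
    path.write_text(
        "Name\tChr\tPosition\tLog R Ratio\tB Allele Freq\tGType\n"
        "p1\t1\t100\t0.01\t0.50\tAB\n"
        "p2\t1\t200\t-0.02\t0.98\tBB\n"
        "p3\t2\t100\t0.00\t0.02\tAA\n"
        "p4\t2\t300\t0.05\t0.49\tAB\n"
        "p5\t2\t200\t-0.01\t1.00\tBB\n"
    )
    return path


@pytest.fixture(scope="session")
def upd_genome():
    """Two-chromosome genome: one null, one with a 10,000-probe UPD at 20%."""
    tr1, _ = simulate_track(
        SimScenario.from_proportion(0.0, "UPD", seed=101), chromosome="1"
    )
    tr2, truth = simulate_track(
        SimScenario.from_proportion(0.2, "UPD", block_len=10_000, seed=102,
                                    block_start=5_000),
        chromosome="2",
    )
    return {"1": tr1, "2": tr2}, truth


@pytest.fixture(scope="session")
def default_params():
    return SegParams(a=0.8, T=8.0, min_seg_len=300)
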