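"""Event classification, cell-fraction estimation and the full caller."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from mosaicad import (
    MosaicCaller,
    SegParams,
    SegmentCall,
    SimScenario,
    call_mosaics,
    classify_segment,
    estimate_cell_fraction,
    relative_mean_lrr,
    simulate_track,
)
from conftest import make_track


def _call(chrom="1", start_bp=1_000, end_bp=5_000):
    return SegmentCall(chrom, 0, 4, start_bp, end_bp, 5, -1.0, 10.0, 1e-6)


class TestRelativeMeanLrr:
    def test_flat_baseline_recovers_segment_mean(self):
        lrr = np.zeros(100)
        lrr[10:20] = -0.25
        track = make_track([0.5] * 100, lrr=lrr)
        call = _call(start_bp=track.positions[10], end_bp=track.positions[19])
        assert relative_mean_lrr({"1": track}, call) == pytest.approx(-0.25)

    def test_invariant_to_global_intensity_offset(self):
        rng = np.random.default_rng(0)
        lrr = rng.normal(0, 0.1, 200)
        lrr[50:80] -= 0.3
        track = make_track([0.5] * 200, lrr=lrr)
        call = _call(start_bp=track.positions[50], end_bp=track.positions[79])
        base = relative_mean_lrr({"1": track}, call)
        shifted = make_track([0.5] * 200, lrr=lrr + 0.3)
        assert relative_mean_lrr({"1": shifted}, call) == pytest.approx(base)

    def test_baseline_excludes_called_segments(self):
        # segment mean -0.05 against a +0.05 baseline reads as -0.10
        lrr = np.full(100, 0.05)
        lrr[40:60] = -0.05
        track = make_track([0.5] * 100, lrr=lrr)
        call = _call(start_bp=track.positions[40], end_bp=track.positions[59])
        assert relative_mean_lrr({"1": track}, call) == pytest.approx(-0.10)

    def test_sex_chromosomes_excluded_from_baseline(self):
        auto = make_track([0.5] * 50, lrr=np.zeros(50), chromosome="1")
        sex = make_track([0.5] * 50, lrr=np.full(50, 5.0), chromosome="X")
        call = _call(chrom="1", start_bp=auto.positions[0], end_bp=auto.positions[9])
        assert relative_mean_lrr({"1": auto, "X": sex}, call) == pytest.approx(0.0)

    def test_no_baseline_probes_raises(self):
        track = make_track([0.5] * 10, chromosome="X")
        with pytest.raises(ValueError, match="baseline"):
            relative_mean_lrr({"X": track}, _call(chrom="X", end_bp=10_000))


class TestClassifySegment:
    @pytest.mark.parametrize(
        "lrr_rel, coverage, expected",
        [
            (-0.30, 0.2, "deletion"),
            (0.00, 0.3, "UPD"),
            (0.15, 0.99, "trisomy"),     # whole-chromosome gain
            (-0.10, 0.3, "UPD"),         # band boundaries are inclusive
            (0.10, 0.3, "UPD"),
            (0.101, 0.3, "duplication"),
            (-0.101, 0.3, "deletion"),
            (-0.30, 0.99, "monosomy"),   # whole-chromosome loss
            (0.00, 0.99, "UPD"),         # copy-neutral never promoted
            (math.nan, 0.5, "unclassified"),
        ],
    )
    def test_rules(self, lrr_rel, coverage, expected):
        assert classify_segment(lrr_rel, coverage) == expected

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            classify_segment(0.0, 1.2)


class TestEstimateCellFraction:
    @pytest.mark.parametrize(
        "bdev, event, expected",
        [
            (0.05, "UPD", 0.10),          # band 0.55 <-> 10% of cells
            (0.10, "UPD", 0.20),          # band 0.60 <-> 20% of cells
            (0.0, "UPD", 0.0),
            (0.0, "deletion", 0.0),
            (0.1, "duplication", 0.50),   # B = (1+p)/(2+p) solved for p
            (0.1, "deletion", 1 / 3),     # B = 1/(2-p) solved for p
            (0.1, "trisomy", 0.50),
            (0.1, "monosomy", 1 / 3),
        ],
    )
    def test_allelic_dosage_mappings(self, bdev, event, expected):
        assert estimate_cell_fraction(bdev, event) == pytest.approx(expected)

    def test_unclassified_gives_nan(self):
        assert math.isnan(estimate_cell_fraction(0.1, "unclassified"))

    @given(
        b=st.floats(0.001, 0.35),
        d=st.floats(0.001, 0.1),
        event=st.sampled_from(["UPD", "deletion", "duplication"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_in_bdev(self, b, d, event):
        lo = estimate_cell_fraction(b, event)
        hi = estimate_cell_fraction(min(b + d, 0.4999), event)
        if lo < 1.0:  # below the clip ceiling
            assert hi > lo

    def test_out_of_range_bdev_rejected(self):
        with pytest.raises(ValueError):
            estimate_cell_fraction(0.5, "UPD")
        with pytest.raises(ValueError):
            estimate_cell_fraction(-0.01, "UPD")


class TestCallMosaics:
    def test_upd_genome_single_annotated_call(self, upd_genome, default_params):
        tracks, truth = upd_genome
        calls, fdr = call_mosaics(tracks, default_params)
        assert len(calls) == 1
        call = calls[0]
        assert call.chromosome == "2"
        assert call.event == "UPD"
        assert call.cell_fraction == pytest.approx(0.2, abs=0.03)
        assert abs(call.mean_lrr) <= 0.10
        assert fdr.n_called == 1 and fdr.fdr < 1e-4

    def test_whole_chromosome_gain_promoted_to_trisomy(self, default_params):
        tr1, _ = simulate_track(
            SimScenario.from_proportion(0.0, "UPD", seed=31), chromosome="1"
        )
        tr2, _ = simulate_track(
            SimScenario.from_proportion(0.2, "trisomy", seed=32), chromosome="2"
        )
        calls, _ = call_mosaics({"1": tr1, "2": tr2}, default_params)
        tri = [c for c in calls if c.chromosome == "2"]
        assert len(tri) == 1 and tri[0].event == "trisomy"
        track_len = len(tr2)
        covered = (tri[0].end_bp - tri[0].start_bp) / 1_000 + 1
        assert covered / track_len > 0.95
        assert tri[0].cell_fraction == pytest.approx(0.2, abs=0.05)

    def test_null_genome_produces_no_calls(self, default_params):
        tracks = {
            str(k): simulate_track(
                SimScenario.from_proportion(0.0, "UPD", seed=50 + k), chromosome=str(k)
            )[0]
            for k in (1, 2)
        }
        calls, fdr = call_mosaics(tracks, default_params)
        assert calls == []
        assert fdr.fdr == 0.0

    @pytest.mark.parametrize("event,lrr_sign", [("deletion", -1), ("duplication", 1)])
    def test_copy_number_events_classified_by_lrr(self, event, lrr_sign, default_params):
        tr, truth = simulate_track(
            SimScenario.from_proportion(0.2, event, block_len=10_000, seed=61,
                                        block_start=5_000)
        )
        calls, _ = call_mosaics({"1": tr}, default_params)
        assert len(calls) == 1
        assert calls[0].event == event
        assert np.sign(calls[0].mean_lrr) == lrr_sign
        assert calls[0].cell_fraction == pytest.approx(0.2, abs=0.03)

    def test_sparse_chromosome_skipped_with_warning(self, default_params):
        small = make_track([0.5] * 10)
        big, _ = simulate_track(SimScenario.from_proportion(0.0, "UPD", seed=70),
                                chromosome="2")
        with pytest.warns(UserWarning, match="informative"):
            calls, _ = call_mosaics({"1": small, "2": big}, default_params)
        assert calls == []


class TestMosaicCallerEstimator:
    def test_sklearn_protocol_and_frame(self, upd_genome):
        tracks, _ = upd_genome
        caller = MosaicCaller(a=0.8, T=8.0, min_seg_len=300)
        assert clone(caller).get_params()["T"] == 8.0
        caller.fit(tracks)
        frame = caller.to_frame()
        assert list(frame.columns)[:3] == ["chromosome", "start_probe", "end_probe"]
        assert len(frame) == len(caller.calls_) == 1
        assert caller.fdr_.n_called == 1

    def test_unfitted_frame_raises(self):
        with pytest.raises(AttributeError):
            MosaicCaller().to_frame()
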