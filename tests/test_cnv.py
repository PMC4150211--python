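"""Tests for window tiling, the binomial window test and segment merging."""

import math

import numpy as np
import pandas as pd
import pytest

from somaticsieve import (CnvConfig, GenomeIntervals, SimulationConfig,
                          WindowTrack, annotate_segments, call_cnv_segments,
                          call_significant_windows, merge_segments,
                          simulate_window_counts, tile_windows,
                          window_binomial_test)
from somaticsieve.cnv import evaluate_track


def binom_tail_oracle(t, T, p, upper=True):
    """Independent tail evaluation: direct log-space summation of binomial mass."""
    ks = range(t, T + 1) if upper else range(0, t + 1)
    logs = [math.lgamma(T + 1) - math.lgamma(k + 1) - math.lgamma(T - k + 1)
            + k * math.log(p) + (T - k) * math.log1p(-p) for k in ks]
    m = max(logs)
    return math.exp(m) * math.fsum(math.exp(x - m) for x in logs)


class TestTiling:
    def test_basic_arithmetic(self):
        cfg = CnvConfig()
        wins = tile_windows({"chr1": 120_000}, cfg)
        assert list(wins["start"]) == [0, 10_000, 20_000]
        assert (wins["end"] - wins["start"] == 100_000).all()

    def test_short_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            wins = tile_windows({"chrS": 99_999}, CnvConfig())
        assert len(wins) == 0

    def test_closed_form_count(self):
        # floor((L - W)/s) + 1 = floor(900000/10000) + 1 = 91
        wins = tile_windows({"chr1": 1_000_000}, CnvConfig())
        assert len(wins) == 91


class TestBinomialTest:
    def test_null_window(self):
        res = window_binomial_test([100], [100], 10_000, 10_000)
        assert res.loc[0, "ratio"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] >= 0.5

    def test_exact_enumeration_t15(self):
        # upper tail at t=15, T=20, p=0.5 equals sum_{k>=15} C(20,k)/2^20
        res = window_binomial_test([15], [10], 20, 20)  # p_w = 10/20 = 0.5
        assert res.loc[0, "direction"] == "gain"
        assert res.loc[0, "p_value"] == pytest.approx(21700 / 1048576, rel=1e-12)

    def test_closed_form_lower_tail(self):
        # t=0 at p=0.01, T=1000: lower tail = 0.99^1000
        res = window_binomial_test([0], [10], 1000, 1000)
        assert res.loc[0, "direction"] == "loss"
        assert res.loc[0, "p_value"] == pytest.approx(0.99 ** 1000, rel=1e-12)

    def test_zero_normal_count_masked(self):
        res = window_binomial_test([50, 10], [0, 10], 1000, 1000)
        assert res.loc[0, "direction"] == "untestable"
        assert not res.loc[0, "testable"]
        assert np.isnan(res.loc[0, "p_value"])
        assert res.loc[1, "testable"]

    def test_oracle_equivalence_random_grid(self):
        """Both tails match direct summation for T <= 1000, rel. error < 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(80):
            T = int(rng.integers(1, 1001))
            N = int(rng.integers(T, 2 * T + 1))
            n_w = int(rng.integers(1, N + 1))
            t_w = int(rng.integers(0, T + 1))
            p_w = n_w / N
            res = window_binomial_test([t_w], [n_w], T, N)
            upper = res.loc[0, "direction"] == "gain"
            expected = binom_tail_oracle(t_w, T, p_w, upper=upper)
            assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_upper_tail_monotone_in_t(self):
        T, n, N = 500, 100, 1000
        t = np.arange(251, 500)  # ratios > 1 throughout
        res = window_binomial_test(t, np.full_like(t, n), T, N)
        assert (res["direction"] == "gain").all()
        assert (np.diff(res["p_value"]) <= 1e-15).all()

    def test_large_totals_stable(self):
        # read totals of order 1e7 must not overflow or go NaN; a ~45-sigma
        # deviation underflows cleanly while a mild one stays in (0, 1)
        res = window_binomial_test([60_000, 50_500], [50_000, 50_000],
                                   10_000_000, 10_000_000)
        assert res["p_value"].notna().all()
        assert res.loc[0, "p_value"] < 1e-300
        assert 0.0 < res.loc[1, "p_value"] < 0.05
        assert res.loc[0, "ratio"] == pytest.approx(1.2)


def _flagged_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "normal_count",
                                       "tumor_count", "p_value", "ratio",
                                       "direction", "testable"])


class TestCallAndMerge:
    def make_track(self, windows):
        return WindowTrack(windows[["chrom", "start", "end", "normal_count",
                                    "tumor_count"]],
                           normal_total=1_000_000, tumor_total=1_000_000)

    def test_gate_logic(self):
        # ratio below the gain gate is not flagged however small its p-value;
        # a gated ratio with too-large p is not flagged either
        cfg = CnvConfig()
        win = pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [0, 10_000, 20_000],
            "end": [100_000, 110_000, 120_000],
            "normal_count": [10_000, 10_000, 10_000],
            "tumor_count": [14_000, 10_100, 15_000],   # ratios 1.4, 1.01, 1.5
        })
        flagged = call_significant_windows(self.make_track(win), cfg)
        diag = evaluate_track(self.make_track(win), cfg)
        assert diag.loc[0, "p_value"] < 1e-12 and diag.loc[0, "ratio"] < 1.5
        assert list(flagged["start"]) == [20_000]

    def test_merge_union_and_bookends(self):
        cfg = CnvConfig()
        flagged = _flagged_frame([
            ("chr1", 0, 100_000, 10_000, 16_000, 1e-20, 1.6, "gain", True),
            ("chr1", 10_000, 110_000, 10_000, 16_000, 1e-22, 1.6, "gain", True),
            ("chr2", 0, 100_000, 10_000, 4_000, 1e-30, 0.4, "loss", True),
        ])
        track = self.make_track(flagged)
        segs = merge_segments(flagged, track, cfg)
        assert len(segs) == 2
        gain = [s for s in segs if s.direction == "gain"][0]
        assert (gain.chrom, gain.start, gain.end) == ("chr1", 0, 110_000)
        assert gain.min_p == 1e-22
        assert gain.ratio == pytest.approx(1.6)
        assert gain.dosage == 3
        loss = [s for s in segs if s.direction == "loss"][0]
        assert loss.dosage == 1

    def test_disjoint_windows_stay_separate(self):
        cfg = CnvConfig()
        flagged = _flagged_frame([
            ("chr1", 0, 100_000, 10_000, 16_000, 1e-20, 1.6, "gain", True),
            ("chr1", 500_000, 600_000, 10_000, 16_000, 1e-20, 1.6, "gain", True),
        ])
        segs = merge_segments(flagged, self.make_track(flagged), cfg)
        assert len(segs) == 2

    def test_dosage_two_suppressed(self):
        # a flagged window whose recomputed ratio rounds to dosage 2 is dropped
        cfg = CnvConfig()
        flagged = _flagged_frame([
            ("chr1", 0, 100_000, 10_000, 10_900, 1e-9, 1.09, "gain", True),
        ])
        segs = merge_segments(flagged, self.make_track(flagged), cfg)
        assert segs == []

    def test_segment_size_arithmetic_reference_rows(self, cnv_reference_segments):
        """Printed sizes equal (end - start + 1)/1000 for all 17 reference rows."""
        import somaticsieve.fixtures as fx
        df = fx.load_table("thymoma_cnv_segments.tsv")
        for seg, (_, row) in zip(cnv_reference_segments, df.iterrows()):
            assert seg.size_kb == int(row["Size (kb)"])
        chr1 = [s for s in cnv_reference_segments if s.chrom == "chr1"][0]
        chr21 = [s for s in cnv_reference_segments if s.chrom == "chr21"][0]
        assert chr1.size_kb == 130 and chr21.size_kb == 210


class TestTrackSymmetry:
    def test_swapping_samples_inverts_ratios(self):
        cfg = SimulationConfig(seed=5, embedded_cnvs=())
        track, _ = simulate_window_counts(cfg)
        fwd = evaluate_track(track, CnvConfig())
        rev = evaluate_track(track.swapped(), CnvConfig())
        both = fwd["testable"] & rev["testable"]
        f, r = fwd[both], rev[both]
        assert np.allclose(f["ratio"], 1.0 / r["ratio"])
        flips = {("gain", "loss"), ("loss", "gain")}
        pairs = set(zip(f["direction"], r["direction"]))
        assert pairs <= flips | {("loss", "loss")}  # ratio exactly 1 maps loss->loss


class TestNullCalibration:
    def test_no_false_positives_small(self):
        """No embedded CNV: zero flagged windows across seeded replicates."""
        cfg_t = CnvConfig()
        flagged_total = 0
        for seed in range(20):
            track, _ = simulate_window_counts(SimulationConfig(seed=seed))
            flagged_total += len(call_significant_windows(track, cfg_t))
        assert flagged_total == 0


class TestAnnotation:
    def test_empty_gene_file(self):
        segs = [s for s in call_cnv_segments_fixture()]
        out = annotate_segments(segs, GenomeIntervals())
        assert all(s.genes == [] for s in out)

    def test_hoxa_cluster_listed(self):
        genes = GenomeIntervals(
            [("chr7", 27_130_000, 27_135_000), ("chr7", 27_180_000, 27_185_000),
             ("chr7", 27_209_000, 27_213_000), ("chr7", 27_500_000, 27_600_000)],
            data=["HOXA9", "HOXA11", "MIR196B", "FAR_AWAY"])
        from somaticsieve.records import CnvSegment
        seg = CnvSegment(chrom="chr7", start=27_120_000, end=27_240_000,
                         direction="gain", ratio=1.5, dosage=3, min_p=1e-12)
        out = annotate_segments([seg], genes)
        assert out[0].genes == ["HOXA9", "HOXA11", "MIR196B"]


def call_cnv_segments_fixture():
    from somaticsieve import CnvTruth
    cfg = SimulationConfig(seed=9, embedded_cnvs=(
        CnvTruth("chr1", 3_000_001, 3_200_000, 3),
        CnvTruth("chr2", 6_000_001, 7_500_000, 0)))
    track, _ = simulate_window_counts(cfg)
    return call_cnv_segments(track, CnvConfig())
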