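"""Unit and property tests for the somatic small-variant filter cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticsieve import FilterConfig, GenomeIntervals, VariantRecord
from somaticsieve.errors import (InconclusiveContextError, MalformedRecordError,
                                 WrongVariantClassError)
from somaticsieve.somatic_filter import (consequence_filter, evaluate_record,
                                         frequency_filter, indel_context_filter,
                                         run_filter_cascade, segdup_filter)


def make_record(**kw):
    base = dict(chrom="chr1", pos=1000, ref="A", alt="G", variant_class="snv",
                tumor_alt_depth=40, tumor_ref_depth=60,
                normal_alt_depth=0, normal_ref_depth=50,
                consequence="missense")
    base.update(kw)
    return VariantRecord(**base)


class TestFrequencyFilter:
    @pytest.mark.parametrize("freqs,expected", [
        ({"ESP": 0.005}, False),              # 0.5% > 0.1% -> germline leak-through
        ({}, True),                           # novel variant
        ({"HapMap": 0.001}, True),            # boundary: exactly 0.1% passes (strict >)
        ({"HapMap": 0.0, "ESP": 0.0011}, False),
        ({"Wellderly": 0.0009}, True),
    ])
    def test_threshold(self, freqs, expected, filter_config):
        rec = make_record(panel_frequencies=freqs)
        assert frequency_filter(rec, filter_config) is expected

    def test_negative_frequency_rejected(self, filter_config):
        rec = make_record()
        rec.panel_frequencies["ESP"] = -0.1  # bypass constructor validation
        with pytest.raises(MalformedRecordError):
            frequency_filter(rec, filter_config)


class TestSegdupFilter:
    def test_empty_mask_passes_everything(self, filter_config):
        assert segdup_filter(make_record(pos=123456), filter_config)

    def test_inside_interval_fails(self):
        cfg = FilterConfig(segdup_intervals=GenomeIntervals([("chr1", 100, 200)]))
        assert not segdup_filter(make_record(pos=151), cfg)

    def test_half_open_boundaries(self):
        """Enumerate positions around a [100, 200) interval: start in, end out."""
        mask = GenomeIntervals([("chr1", 100, 200)])
        inside = [p for p in range(95, 206) if mask.contains_point("chr1", p)]
        assert inside == list(range(100, 200))


class TestIndelContextFilter:
    def test_homopolymer_flank(self, filter_config):
        rec = make_record(variant_class="deletion", ref="G", alt="-",
                          context_5p="ACTACGTACGTA", context_3p="GGGGGTTACGTA")
        ok, reason = indel_context_filter(rec, filter_config)
        assert (ok, reason) == (False, "homopolymer")

    def test_identical_adjacent_repeat(self, filter_config):
        rec = make_record(variant_class="insertion", ref="-", alt="AT",
                          context_5p="CGCGCGCGCGCG", context_3p="ATATATATACGC")
        ok, reason = indel_context_filter(rec, filter_config)
        assert (ok, reason) == (False, "identical_repeat")

    def test_clean_deletion_passes(self, filter_config):
        # mirrors the surviving single-base frameshift deletion with
        # non-repetitive flanks
        rec = make_record(chrom="chr20", pos=31022486, variant_class="deletion",
                          ref="G", alt="-", consequence="frameshift",
                          context_5p="GATCGATCGATC", context_3p="ATCGATCGATCG")
        assert indel_context_filter(rec, filter_config) == (True, None)

    def test_mononucleotide_indel_extends_adjacent_run(self, filter_config):
        # deleted GG plus a GGG flank run makes a homopolymer of 5
        rec = make_record(variant_class="deletion", ref="GG", alt="-",
                          context_5p="ACTACGTACGTA", context_3p="GGGTTACGTACG")
        ok, reason = indel_context_filter(rec, filter_config)
        assert (ok, reason) == (False, "homopolymer")
        # but a GG deletion next to a single G (total run of 3) is clean
        rec4 = make_record(variant_class="deletion", ref="GG", alt="-",
                           context_5p="ACTACGTACGTA", context_3p="GTTACGTACGTA")
        assert indel_context_filter(rec4, filter_config) == (True, None)

    def test_simple_repeat_interval(self):
        cfg = FilterConfig(simple_repeat_intervals=GenomeIntervals([("chr1", 990, 1010)]))
        rec = make_record(variant_class="deletion", ref="C", alt="-",
                          context_5p="GATCGATCGATC", context_3p="ATCGATCGATCG")
        ok, reason = indel_context_filter(rec, cfg)
        assert (ok, reason) == (False, "simple_repeat")

    def test_snv_rejected(self, filter_config):
        with pytest.raises(WrongVariantClassError):
            indel_context_filter(make_record(), filter_config)

    def test_missing_context_inconclusive(self, filter_config):
        rec = make_record(variant_class="deletion", ref="G", alt="-",
                          context_5p="", context_3p="")
        with pytest.raises(InconclusiveContextError):
            indel_context_filter(rec, filter_config)
        verdict = evaluate_record(rec, filter_config)
        assert verdict.kept and verdict.warnings == ["context_inconclusive"]


class TestConsequenceFilter:
    @pytest.mark.parametrize("cons,expected", [
        ("missense", True), ("nonsense", True), ("frameshift", True),
        ("inframe", True), ("splice_donor_acceptor", True),
        ("synonymous", False), ("noncoding", False), ("other", False),
    ])
    def test_retained_set(self, cons, expected, filter_config):
        assert consequence_filter(make_record(consequence=cons), filter_config) is expected

    def test_unknown_label_rejected_at_construction(self):
        with pytest.raises(MalformedRecordError):
            make_record(consequence="weird")


class TestCascade:
    def test_reference_table_all_kept(self, table1_records, filter_config):
        """All 17 reference coding mutations survive: 14 missense, 1 nonsense, 2 frameshift."""
        verdicts, summary = run_filter_cascade(table1_records, filter_config)
        assert summary["n_kept"] == 17
        assert summary["kept_by_consequence"] == {
            "missense": 14, "nonsense": 1, "frameshift": 2}

    def test_empty_input(self, filter_config):
        verdicts, summary = run_filter_cascade([], filter_config)
        assert verdicts == [] and summary["n_kept"] == 0 == summary["n_input"]

    def test_conservation_and_idempotence(self, filter_config):
        from somaticsieve import SimulationConfig, simulate_variant_table
        records, truths, masks = simulate_variant_table(
            SimulationConfig(seed=11, n_somatic_variants=60, n_germline_variants=40))
        cfg = FilterConfig(segdup_intervals=masks["segdup"],
                           simple_repeat_intervals=masks["simple_repeat"])
        verdicts, summary = run_filter_cascade(records, cfg)
        assert summary["n_kept"] + summary["n_removed"] == len(records)
        kept = [v.record for v in verdicts if v.kept]
        verdicts2, summary2 = run_filter_cascade(kept, cfg)
        assert all(v.kept for v in verdicts2)
        assert summary2["n_kept"] == len(kept)

    def test_bruteforce_oracle(self):
        """Cascade kept set equals an independent rule-by-rule re-check."""
        from somaticsieve import SimulationConfig, simulate_variant_table
        records, truths, masks = simulate_variant_table(
            SimulationConfig(seed=7, n_somatic_variants=70, n_germline_variants=30))
        cfg = FilterConfig(segdup_intervals=masks["segdup"],
                           simple_repeat_intervals=masks["simple_repeat"])
        verdicts, _ = run_filter_cascade(records, cfg)
        kept = {id(v.record) for v in verdicts if v.kept}

        retained = {"missense", "nonsense", "frameshift", "inframe",
                    "splice_donor_acceptor"}
        oracle_kept = set()
        for rec in records:
            ok = all(f <= 0.001 for f in rec.panel_frequencies.values())
            ok &= not any(s <= rec.pos - 1 < e for (c, s, e, _d)
                          in cfg.segdup_intervals.iter_intervals() if c == rec.chrom)
            if rec.variant_class in ("insertion", "deletion"):
                seq = rec.indel_sequence().upper()
                up, down = rec.context_5p.upper(), rec.context_3p.upper()
                in_rep = any(s <= rec.pos - 1 < e for (c, s, e, _d)
                             in cfg.simple_repeat_intervals.iter_intervals()
                             if c == rec.chrom)
                ident = bool(seq) and (down.startswith(seq) or up.endswith(seq))
                def runlen(s):
                    n = 0
                    for ch in s:
                        if ch != s[0]:
                            break
                        n += 1
                    return n if s else 0
                homo = runlen(down) >= 5 or runlen(up[::-1]) >= 5
                if seq and len(set(seq)) == 1:
                    ext = len(seq)
                    if down and down[0] == seq[0]:
                        ext += runlen(down)
                    if up and up[-1] == seq[0]:
                        ext += runlen(up[::-1])
                    homo = homo or ext >= 5
                ok &= not (in_rep or ident or homo)
            ok &= rec.consequence in retained
            if ok:
                oracle_kept.add(id(rec))
        assert kept == oracle_kept


@given(freq=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
@settings(max_examples=60, deadline=None)
def test_frequency_boundary_property(freq):
    """A single-panel record fails iff its frequency strictly exceeds 0.1%."""
    rec = make_record(panel_frequencies={"ESP": freq})
    assert frequency_filter(rec, FilterConfig()) == (freq <= 0.001)


@given(run=st.integers(min_value=0, max_value=8),
       base=st.sampled_from("ACGT"))
@settings(max_examples=60, deadline=None)
def test_homopolymer_run_length_property(run, base):
    """A deletion abutting a run of >= 5 identical bases fails; shorter runs pass.

    The deleted base differs from the run base so only the flank run counts.
    """
    other = "A" if base != "A" else "C"
    tail = "GATCGATCGATC".replace(base, "T" if base != "T" else "G")
    ctx3 = base * run + tail
    rec = make_record(variant_class="deletion", ref=other, alt="-",
                      context_5p=tail[::-1], context_3p=ctx3)
    ok, reason = indel_context_filter(rec, FilterConfig())
    assert ok == (run < 5)
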