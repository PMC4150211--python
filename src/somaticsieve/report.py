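"""Pipeline driver: run all stages, assemble report tables and track exports.

``run_pipeline`` executes the stages in order — somatic small-variant
filtration, zygosity/LOH screening of the survivors, window-based CNV
calling, SV support filtering — writing each stage's table to the output
directory and returning a consistency-checked RunSummary. Inputs either
come from files named in the PipelineConfig or are generated by the
synthetic-data module when a SimulationConfig is attached.

``export_overview_tracks`` writes the tab-delimited per-chromosome tracks a
circular genome-overview plot needs (mutation positions + genes, CNV
segments keyed gain/loss with dosage, SV link pairs); graphical rendering
itself is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as sio
from .cnv import annotate_segments, call_cnv_segments
from .config import PipelineConfig
from .errors import PipelineStageError
from .intervals import GenomeIntervals
from .records import CnvSegment, RunSummary, SvCall, VariantRecord
from .somatic_filter import run_filter_cascade
from .sv import filter_sv_calls
from .synthetic import (simulate_sv_table, simulate_variant_table,
                        simulate_window_counts)
from .tables import cnv_table, coding_mutation_table, sv_table, write_table
from .zygosity import classify_zygosity, loh_screen, scan_high_af

log = logging.getLogger("somaticsieve")


@dataclasses.dataclass
class PipelineResult:
    """Everything a run produced, for programmatic use."""

    summary: RunSummary
    verdicts: list
    kept_records: list[VariantRecord]
    cnv_segments: list[CnvSegment]
    somatic_svs: list[SvCall]
    zygosity_labels: dict[int, str]
    high_af_hits: list
    loh: dict | None


def _header(config: PipelineConfig) -> list[str]:
    if config.write_timestamp:
        return [time.strftime("generated %Y-%m-%d %H:%M:%S")]
    return []


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        records, _truths, masks = simulate_variant_table(sim)
        track, _cnv_truth = simulate_window_counts(sim)
        sv_calls, _sv_truth, centromeres = simulate_sv_table(sim)
        if not config.filter.segdup_intervals:
            config.filter.segdup_intervals = masks["segdup"]
        if not config.filter.simple_repeat_intervals:
            config.filter.simple_repeat_intervals = masks["simple_repeat"]
        if not config.sv.centromere_intervals:
            config.sv.centromere_intervals = centromeres
        return records, track, sv_calls
    records = (sio.read_variant_table(config.variant_path)
               if config.variant_path else [])
    track = (sio.read_window_track(config.window_path)
             if config.window_path else None)
    sv_calls = []
    if config.sv_tumor_path:
        sv_calls += sio.read_sv_table(config.sv_tumor_path, sample="tumor")
    if config.sv_normal_path:
        sv_calls += sio.read_sv_table(config.sv_normal_path, sample="normal")
    return records, track, sv_calls


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)

    try:
        records, track, sv_calls = _load_inputs(config)
    except Exception as exc:
        raise PipelineStageError("load", str(exc)) from exc

    # --- somatic small-variant filtration -----------------------------------
    log.info("variant filter: %d candidates; max panel freq %.4f, homopolymer >= %d",
             len(records), config.filter.max_panel_frequency,
             config.filter.homopolymer_min_len)
    try:
        verdicts, fsummary = run_filter_cascade(records, config.filter)
    except Exception as exc:
        raise PipelineStageError("somatic_filter", str(exc)) from exc
    kept = [v.record for v in verdicts if v.kept]
    log.info("variant filter: kept %d / %d", len(kept), len(records))

    audit = pd.DataFrame({
        "chrom": [v.record.chrom for v in verdicts],
        "pos": [v.record.pos for v in verdicts],
        "kept": [v.kept for v in verdicts],
        "failed_rules": [";".join(v.failed_rules) or "." for v in verdicts],
        "warnings": [";".join(v.warnings) or "." for v in verdicts],
    })
    write_table(audit, outdir / "variant_audit.tsv", header)
    write_table(coding_mutation_table(kept), outdir / "coding_mutations.tsv", header)

    # --- zygosity ------------------------------------------------------------
    try:
        zyg = {i: classify_zygosity(rec, config.zygosity)
               for i, rec in enumerate(kept)}
        high_af = scan_high_af(kept, config.zygosity)
        normal_het_candidates = [r for r in records
                                 if r.normal_alt_depth > 0 and r.normal_ref_depth > 0]
        loh = (loh_screen(normal_het_candidates, None, config.zygosity)
               if normal_het_candidates else None)
    except Exception as exc:
        raise PipelineStageError("zygosity", str(exc)) from exc

    # --- CNV -----------------------------------------------------------------
    segments: list[CnvSegment] = []
    if track is not None:
        log.info("cnv: %d windows; P<%g, gates >=%.2f / <=%.2f",
                 len(track), config.cnv.p_threshold,
                 config.cnv.gain_ratio_min, config.cnv.loss_ratio_max)
        try:
            segments = call_cnv_segments(track, config.cnv)
            if config.gene_bed:
                genes = GenomeIntervals.from_bed(config.gene_bed)
                segments = annotate_segments(segments, genes)
        except Exception as exc:
            raise PipelineStageError("cnv_windows", str(exc)) from exc
    write_table(cnv_table(segments), outdir / "cnv_segments.tsv", header)

    # --- SV ------------------------------------------------------------------
    n_sv_tumor = sum(c.sample == "tumor" for c in sv_calls)
    try:
        somatic_svs = filter_sv_calls(sv_calls, config.sv)
    except Exception as exc:
        raise PipelineStageError("sv_filter", str(exc)) from exc
    log.info("sv: %d tumor candidates -> %d somatic (tumor >= %d, normal >= %d reads)",
             n_sv_tumor, len(somatic_svs), config.sv.tumor_min_support,
             config.sv.normal_min_support)
    write_table(sv_table(somatic_svs), outdir / "structural_variants.tsv", header)

    # --- summary -------------------------------------------------------------
    summary = RunSummary(
        n_input_variants=fsummary["n_input"],
        n_kept_variants=fsummary["n_kept"],
        n_removed_variants=fsummary["n_removed"],
        kept_by_consequence=fsummary["kept_by_consequence"],
        removed_by_rule=fsummary["removed_by_first_rule"],
        n_kept_snvs=sum(not r.is_indel for r in kept),
        n_kept_indels=sum(r.is_indel for r in kept),
        n_cnv_gains=sum(s.direction == "gain" for s in segments),
        n_cnv_losses=sum(s.direction == "loss" for s in segments),
        n_sv_input_tumor=n_sv_tumor,
        n_sv_somatic=len(somatic_svs),
        n_high_af=len(high_af),
        loh_status=loh["status"] if loh else None,
    )
    summary.check_consistency()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")

    result = PipelineResult(summary=summary, verdicts=verdicts, kept_records=kept,
                            cnv_segments=segments, somatic_svs=somatic_svs,
                            zygosity_labels=zyg, high_af_hits=high_af, loh=loh)
    export_overview_tracks(result, outdir, header)
    return result


def export_overview_tracks(result: PipelineResult, outdir: str | Path,
                           header_lines=()) -> None:
    """Write circular-plot-ready tracks: mutations, CNV gain/loss, SV links."""
    outdir = Path(outdir)
    muts = pd.DataFrame({
        "chrom": [r.chrom for r in result.kept_records],
        "pos": [r.pos for r in result.kept_records],
        "gene": [r.gene or "." for r in result.kept_records],
        "impact": [r.consequence for r in result.kept_records],
    })
    write_table(muts, outdir / "track_mutations.tsv", header_lines)

    cnv = pd.DataFrame({
        "chrom": [s.chrom for s in result.cnv_segments],
        "start": [s.start for s in result.cnv_segments],
        "end": [s.end for s in result.cnv_segments],
        "direction": [s.direction for s in result.cnv_segments],
        "dosage": [s.dosage for s in result.cnv_segments],
    })
    write_table(cnv, outdir / "track_cnv.tsv", header_lines)

    links = pd.DataFrame({
        "chrom1": [c.breakpoint1[0] for c in result.somatic_svs],
        "start1": [c.breakpoint1[1] for c in result.somatic_svs],
        "end1": [c.breakpoint1[2] for c in result.somatic_svs],
        "chrom2": [c.breakpoint2[0] for c in result.somatic_svs],
        "start2": [c.breakpoint2[1] for c in result.somatic_svs],
        "end2": [c.breakpoint2[2] for c in result.somatic_svs],
    })
    write_table(links, outdir / "track_sv_links.tsv", header_lines)


def demo_simulation_config(seed: int = 0):
    """The end-to-end demonstration conditions: a truth-labeled synthetic case.

    The variant plan plants 17 protein-impacting clean somatic variants
    (14 missense, 1 nonsense, 2 frameshift — one missense pinned at the
    published 61/62, 0/41 depths) among distractors that each fail one
    rule, plus panel-common germline leak-through; the window track embeds
    a dosage-3 gain and a homozygous (dosage-0) deletion; six somatic SV
    truths are joined by below-threshold, normal-matched and centromeric
    distractors.
    """
    from .config import SimulationConfig, SvTruth, VariantSpec
    from .synthetic import random_sv_truth

    plan = [
        VariantSpec(count=1, consequence="missense",
                    fixed_depths=(61, 1, 0, 41)),
        VariantSpec(count=13, consequence="missense"),
        VariantSpec(count=1, consequence="nonsense"),
        VariantSpec(count=2, variant_class="deletion", consequence="frameshift"),
        # distractors, one rule each
        VariantSpec(count=3, consequence="missense", panel_class="common"),
        VariantSpec(count=2, variant_class="deletion", consequence="frameshift",
                    context_class="homopolymer"),
        VariantSpec(count=1, variant_class="insertion", consequence="inframe",
                    context_class="identical_repeat"),
        VariantSpec(count=1, variant_class="deletion", consequence="frameshift",
                    context_class="simple_repeat"),
        VariantSpec(count=1, consequence="missense", in_segdup=True),
        VariantSpec(count=4, consequence="synonymous"),
        VariantSpec(count=3, consequence="noncoding"),
        VariantSpec(count=8, origin="germline", panel_class="common",
                    consequence="missense"),
    ]
    base = SimulationConfig(seed=seed)
    sv_truth = random_sv_truth(6, base, seed=seed + 101,
                               tumor_support_mean=20.0) + [
        SvTruth(sv_type="Deletion", state="Unbal",
                breakpoint1=("chr1", 1_000_000, 1_003_000),
                breakpoint2=("chr1", 1_500_000, 1_503_000),
                tumor_support_mean=10, normal_support_mean=8,
                with_normal_support=True),
        SvTruth(sv_type="Inversion", state="Unbal",
                breakpoint1=("chr2", 2_000_000, 2_003_000),
                breakpoint2=("chr2", 2_500_000, 2_503_000),
                tumor_support_mean=10, centromeric=True),
    ]
    from .config import CnvTruth
    return SimulationConfig(
        seed=seed,
        embedded_cnvs=(
            CnvTruth("chr1", 3_000_001, 3_200_000, 3),
            CnvTruth("chr2", 6_000_001, 7_500_000, 0),
        ),
        n_somatic_variants=sum(s.count for s in plan if s.origin == "somatic"),
        n_germline_variants=sum(s.count for s in plan if s.origin == "germline"),
        variant_plan=plan,
        sv_truth=sv_truth,
    )
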