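"""Seeded synthetic tumor/normal data with truth labels.

Three generators emulate the statistical structure the downstream stages
assume, at desk scale (default 20-Mb genome), so every stage is testable
without external sequencing data:

* ``simulate_window_counts`` — low-pass WGS read-density tracks. Reads are
  distributed over non-overlapping step-sized tiles by a multinomial whose
  per-tile probabilities are Dirichlet-perturbed around uniform (the
  ``mapability_dispersion`` parameter is the squared coefficient of
  variation of the per-tile mapping probability). The tumor shares the
  normal's tile probabilities rescaled by dosage/2 inside embedded CNV
  segments and renormalized — the renormalization is physical: a CNV adds
  or removes tumor read mass genome-wide. Tiles are then aggregated into
  sliding windows (100 kb at 10-kb steps by default).

* ``simulate_variant_table`` — exome-like candidate somatic variant calls:
  true somatic records (normal alt depth ~0, tumor AF from a Beta
  distribution), germline leak-through (normal AF ~0.5 or ~1.0, usually
  panel-common), panel frequencies straddling the 0.1% filter boundary,
  and indels placed in clean / simple-repeat / identical-repeat /
  homopolymer contexts.

* ``simulate_sv_table`` — SV candidate link tables with Poisson support
  noise, optional matched normal calls and centromeric placement.

Every record carries a truth label; identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CnvTruth, SimulationConfig, SvTruth, VariantSpec
from .errors import ConfigError
from .intervals import GenomeIntervals
from .records import SvCall, VariantRecord, WindowTrack

BASES = "ACGT"


# --------------------------------------------------------------------------
# Window counts


def _tile_grid(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping step-sized tiles covering each chromosome."""
    rows = []
    n_tiles = config.genome_length // config.step
    for chrom in config.chrom_names:
        starts = np.arange(n_tiles, dtype=np.int64) * config.step
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": starts + config.step}))
    return pd.concat(rows, ignore_index=True)


def _tile_dosage_scale(tiles: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Per-tile copy scaling factor dosage/2, overlap-weighted at segment edges."""
    scale = np.ones(len(tiles))
    for seg in config.embedded_cnvs:
        mask = tiles["chrom"] == seg.chrom
        s0, e0 = seg.start - 1, seg.end  # to 0-based half-open
        ov = (np.minimum(tiles["end"].to_numpy(), e0)
              - np.maximum(tiles["start"].to_numpy(), s0)).clip(min=0)
        frac = np.where(mask, ov / config.step, 0.0)
        scale += frac * (seg.dosage / 2.0 - 1.0)
    return scale


def simulate_window_counts(config: SimulationConfig
                           ) -> tuple[WindowTrack, list[CnvTruth]]:
    """Generate a paired tumor/normal window-count track plus the CNV truth list."""
    rng = np.random.default_rng(config.seed)
    tiles = _tile_grid(config)
    K = len(tiles)
    if K == 0:
        raise ConfigError("genome too short for a single tile")

    if config.mapability_dispersion > 0:
        alpha = np.full(K, 1.0 / config.mapability_dispersion)
        p = rng.dirichlet(alpha)
    else:
        p = np.full(K, 1.0 / K)

    scale = _tile_dosage_scale(tiles, config)
    q = p * scale
    q = q / q.sum()

    normal_tiles = rng.multinomial(config.normal_total_reads, p)
    tumor_tiles = rng.multinomial(config.tumor_total_reads, q)

    k = config.window_size // config.step
    frames = []
    for chrom, idx in tiles.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        n_c = np.asarray(normal_tiles)[idx]
        t_c = np.asarray(tumor_tiles)[idx]
        if len(idx) < k:
            continue
        csum_n = np.concatenate([[0], np.cumsum(n_c)])
        csum_t = np.concatenate([[0], np.cumsum(t_c)])
        n_win = len(idx) - k + 1
        starts = tiles.loc[idx[:n_win], "start"].to_numpy()
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + config.window_size,
            "normal_count": csum_n[k:] - csum_n[:-k],
            "tumor_count": csum_t[k:] - csum_t[:-k],
        }))
    windows = pd.concat(frames, ignore_index=True)
    track = WindowTrack(windows, normal_total=config.normal_total_reads,
                        tumor_total=config.tumor_total_reads)
    return track, list(config.embedded_cnvs)


# --------------------------------------------------------------------------
# Variant tables


@dataclass(frozen=True)
class VariantTruth:
    """Construction-time truth for one simulated variant record."""

    index: int
    origin: str           # somatic | germline
    variant_class: str
    consequence: str
    panel_class: str      # novel | rare | common
    context_class: str    # clean | simple_repeat | identical_repeat | homopolymer
    in_segdup: bool
    true_tumor_af: float


def _default_plan(config: SimulationConfig, rng: np.random.Generator
                  ) -> list[VariantSpec]:
    """Expand the count/mix parameters into an explicit per-record plan."""
    plan: list[VariantSpec] = []
    snv_cons = ["missense", "synonymous", "noncoding", "nonsense",
                "splice_donor_acceptor", "other"]
    snv_w = [0.45, 0.20, 0.15, 0.08, 0.06, 0.06]
    indel_cons = ["frameshift", "inframe"]
    ctx_names = list(config.indel_context_mix) or ["clean"]
    ctx_w = list(config.indel_context_mix.values()) or [1.0]
    for _ in range(config.n_somatic_variants):
        is_indel = rng.random() < config.indel_fraction
        if is_indel:
            vclass = "insertion" if rng.random() < 0.5 else "deletion"
            cons = indel_cons[int(rng.random() < 0.4)]
            ctx = ctx_names[rng.choice(len(ctx_names), p=np.asarray(ctx_w) / sum(ctx_w))]
        else:
            vclass, ctx = "snv", "clean"
            cons = snv_cons[rng.choice(len(snv_cons), p=snv_w)]
        u = rng.random()
        if u < config.fraction_common_panel:
            panel = "common"
        elif u < config.fraction_common_panel + 0.1:
            panel = "rare"
        else:
            panel = "novel"
        plan.append(VariantSpec(count=1, origin="somatic", variant_class=vclass,
                                consequence=cons, panel_class=panel,
                                context_class=ctx))
    for _ in range(config.n_germline_variants):
        panel = "common" if rng.random() < 0.9 else "novel"
        cons = snv_cons[rng.choice(len(snv_cons), p=snv_w)]
        plan.append(VariantSpec(count=1, origin="germline", variant_class="snv",
                                consequence=cons, panel_class=panel))
    return plan


def _clean_flank(rng: np.random.Generator, length: int, avoid_start: str,
                 avoid_end: str) -> str:
    """Non-repetitive flank: a rotated ACGT cycle (max run length 1)."""
    phase = int(rng.integers(4))
    cyc = (BASES * (length // 4 + 2))[phase:phase + length]
    if avoid_start and cyc.startswith(avoid_start[0]):
        cyc = BASES[(BASES.index(cyc[0]) + 1) % 4] + cyc[1:]
    if avoid_end and cyc.endswith(avoid_end[-1]):
        cyc = cyc[:-1] + BASES[(BASES.index(cyc[-1]) + 1) % 4]
    return cyc


def _contexts_for(spec: VariantSpec, seq: str, rng: np.random.Generator,
                  flank_len: int = 12) -> tuple[str, str]:
    """Flanks realizing the planned context class around an indel sequence."""
    if spec.context_class == "homopolymer":
        base = BASES[int(rng.integers(4))]
        run = base * 5
        tail = _clean_flank(rng, flank_len - 5, base, "")
        up = _clean_flank(rng, flank_len, "", seq or "N")
        return up, run + tail
    if spec.context_class == "identical_repeat" and seq:
        tail = _clean_flank(rng, flank_len - len(seq) % flank_len, seq, "")
        up = _clean_flank(rng, flank_len, "", seq)
        return up, (seq + tail)[:flank_len + len(seq)]
    # clean and simple_repeat (the latter is interval-driven, flanks stay clean)
    up = _clean_flank(rng, flank_len, "", seq or "N")
    down = _clean_flank(rng, flank_len, seq or "N", "")
    return up, down


def _indel_seq(spec: VariantSpec, rng: np.random.Generator) -> str:
    if spec.context_class == "homopolymer":
        # mononucleotide indel next to the run (the classic artifact)
        return BASES[int(rng.integers(4))]
    n = int(rng.integers(1, 4))
    return "".join(BASES[int(rng.integers(4))] for _ in range(n))


def simulate_variant_table(config: SimulationConfig
                           ) -> tuple[list[VariantRecord], list[VariantTruth],
                                      dict[str, GenomeIntervals]]:
    """Generate candidate variants, truth labels and the companion interval masks.

    The masks dict carries 'segdup' and 'simple_repeat' interval sets covering
    exactly the records planned to fail those rules, ready to plug into a
    FilterConfig.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    plan = list(config.variant_plan) if config.variant_plan is not None \
        else _default_plan(config, rng)

    records: list[VariantRecord] = []
    truths: list[VariantTruth] = []
    segdup = GenomeIntervals()
    simple_rep = GenomeIntervals()

    slot = 0
    a, b = config.somatic_af_distribution
    for spec in plan:
        for _ in range(spec.count):
            chrom = config.chrom_names[slot % config.n_chromosomes]
            pos = 2_000 + (slot // config.n_chromosomes) * 2_000  # 1-based, no collisions
            slot += 1
            if pos > config.genome_length - 1_000:
                raise ConfigError("variant plan does not fit in the synthetic genome")

            if spec.variant_class == "snv":
                ref = BASES[int(rng.integers(4))]
                alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
                seq = ""
                ctx5, ctx3 = _clean_flank(rng, 12, "", ""), _clean_flank(rng, 12, "", "")
            else:
                seq = _indel_seq(spec, rng)
                ref, alt = (("-", seq) if spec.variant_class == "insertion"
                            else (seq, "-"))
                ctx5, ctx3 = _contexts_for(spec, seq, rng)

            if spec.fixed_depths is not None:
                t_alt, t_ref, n_alt, n_ref = spec.fixed_depths
                true_af = t_alt / max(1, t_alt + t_ref)
            else:
                t_depth = max(20, int(rng.poisson(config.mean_depth_tumor)))
                n_depth = max(20, int(rng.poisson(config.mean_depth_normal)))
                if spec.origin == "somatic":
                    true_af = float(rng.beta(a, b))
                    t_alt = max(1, int(rng.binomial(t_depth, true_af)))
                    n_alt = int(rng.random() < 0.05)  # rare stray contaminating read
                else:
                    true_af = 1.0 if rng.random() < 0.2 else 0.5
                    t_alt = int(rng.binomial(t_depth, true_af))
                    n_alt = int(rng.binomial(n_depth, true_af))
                t_ref, n_ref = t_depth - t_alt, n_depth - n_alt

            if spec.panel_class == "novel":
                freqs: dict[str, float] = {}
            elif spec.panel_class == "rare":
                panel = ("HapMap", "1000Genomes", "ESP", "Wellderly")[int(rng.integers(4))]
                freqs = {panel: float(rng.choice([0.001, 0.0005, 0.0002]))}
            else:
                n_panels = int(rng.integers(1, 5))
                names = list(("HapMap", "1000Genomes", "ESP", "Wellderly"))
                rng.shuffle(names)
                freqs = {nm: float(rng.uniform(0.002, 0.2)) for nm in names[:n_panels]}

            if spec.in_segdup:
                segdup.add(chrom, pos - 50, pos + 50)
            if spec.context_class == "simple_repeat" and spec.variant_class != "snv":
                simple_rep.add(chrom, pos - 25, pos + 25)

            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                variant_class=spec.variant_class,
                tumor_alt_depth=t_alt, tumor_ref_depth=t_ref,
                normal_alt_depth=n_alt, normal_ref_depth=n_ref,
                panel_frequencies=freqs, consequence=spec.consequence,
                context_5p=ctx5, context_3p=ctx3,
            )
            records.append(rec)
            truths.append(VariantTruth(
                index=len(records) - 1, origin=spec.origin,
                variant_class=spec.variant_class, consequence=spec.consequence,
                panel_class=spec.panel_class, context_class=spec.context_class,
                in_segdup=spec.in_segdup, true_tumor_af=true_af))

    return records, truths, {"segdup": segdup, "simple_repeat": simple_rep}


# --------------------------------------------------------------------------
# Structural variants


@dataclass(frozen=True)
class SvCallTruth:
    """Construction-time truth for one simulated tumor SV call."""

    index: int
    somatic: bool
    has_normal_match: bool
    centromeric: bool


def centromere_intervals(config: SimulationConfig) -> GenomeIntervals:
    """Synthetic centromeres: the central 100 kb of each chromosome."""
    cen = GenomeIntervals()
    half = config.genome_length // 2
    for chrom in config.chrom_names:
        cen.add(chrom, half - 50_000, half + 50_000)
    return cen


def simulate_sv_table(config: SimulationConfig
                      ) -> tuple[list[SvCall], list[SvCallTruth], GenomeIntervals]:
    """Generate tumor (and matched normal) SV candidate calls with truth labels."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cen = centromere_intervals(config)
    half = config.genome_length // 2
    calls: list[SvCall] = []
    truths: list[SvCallTruth] = []
    for truth in config.sv_truth:
        bp1, bp2 = truth.breakpoint1, truth.breakpoint2
        if truth.centromeric:
            chrom = bp1[0]
            bp1 = (chrom, half - 25_000, half - 20_000)
        support = int(rng.poisson(truth.tumor_support_mean))
        calls.append(SvCall(sv_type=truth.sv_type, state=truth.state,
                            breakpoint1=bp1, breakpoint2=bp2,
                            support_reads=support, sample="tumor"))
        if truth.with_normal_support is None:
            matched = bool(rng.random() < config.fraction_with_normal_support)
        else:
            matched = truth.with_normal_support
        if matched:
            n_support = int(rng.poisson(truth.normal_support_mean))
            calls.append(SvCall(sv_type=truth.sv_type, state=truth.state,
                                breakpoint1=bp1, breakpoint2=bp2,
                                support_reads=n_support, sample="normal"))
        truths.append(SvCallTruth(index=len(truths), centromeric=truth.centromeric,
                                  has_normal_match=matched,
                                  somatic=not (matched or truth.centromeric)))
    return calls, truths, cen


def random_sv_truth(n: int, config: SimulationConfig, seed: int,
                    tumor_support_mean: float = 10.0) -> list[SvTruth]:
    """Convenience: n random same-chromosome SV truth records away from centromeres."""
    rng = np.random.default_rng(seed)
    types = ["Inversion", "Insertion", "Coamplicon", "Deletion"]
    out = []
    for _ in range(n):
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        s1 = int(rng.integers(100_000, config.genome_length // 2 - 200_000))
        s2 = int(rng.integers(config.genome_length // 2 + 200_000,
                              config.genome_length - 100_000))
        out.append(SvTruth(sv_type=types[int(rng.integers(len(types)))],
                           state="Bal" if rng.random() < 0.5 else "Unbal",
                           breakpoint1=(chrom, s1, s1 + 3_000),
                           breakpoint2=(chrom, s2, s2 + 3_000),
                           tumor_support_mean=tumor_support_mean))
    return out
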