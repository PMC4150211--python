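"""Configuration objects for every pipeline stage.

Defaults encode the published filtration thresholds: population allele
frequency > 0.1% removes a variant; homopolymer runs of length >= 5 flag an
indel; CNV calling uses 100-kb windows at 10-kb steps, a binomial P-value
threshold of 1e-8 and adjusted-ratio gates of 1.5 (gain) / 0.5 (loss); SV
calls need >= 7 supporting reads in the tumor and >= 3 in the normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import ConfigError
from .intervals import GenomeIntervals
from .records import CONSEQUENCES

RETAINED_CONSEQUENCES_DEFAULT = frozenset({
    "missense", "nonsense", "frameshift", "inframe", "splice_donor_acceptor",
})


@dataclass
class FilterConfig:
    """Thresholds for the somatic small-variant filter cascade."""

    max_panel_frequency: float = 0.001
    homopolymer_min_len: int = 5
    retained_consequences: frozenset[str] = RETAINED_CONSEQUENCES_DEFAULT
    segdup_intervals: GenomeIntervals = field(default_factory=GenomeIntervals)
    simple_repeat_intervals: GenomeIntervals = field(default_factory=GenomeIntervals)
    # Optional sanity predicate re-checking somatic status from depths; the
    # upstream somatic caller is trusted, so this is off by default.
    require_normal_absence: bool = False
    max_normal_af: float = 0.02

    def __post_init__(self):
        if not (0.0 <= self.max_panel_frequency <= 1.0):
            raise ConfigError("max_panel_frequency must be in [0,1]")
        if self.homopolymer_min_len < 1:
            raise ConfigError("homopolymer_min_len must be >= 1")
        unknown = set(self.retained_consequences) - CONSEQUENCES
        if unknown:
            raise ConfigError(f"unknown consequences in retained set: {sorted(unknown)}")
        self.retained_consequences = frozenset(self.retained_consequences)


@dataclass
class CnvConfig:
    """Sliding-window binomial CNV caller parameters."""

    window_size: int = 100_000
    step: int = 10_000
    p_threshold: float = 1e-8
    gain_ratio_min: float = 1.5
    loss_ratio_max: float = 0.5
    two_sided: bool = False  # one-sided tail matching observed direction by default

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigError("p_threshold must be in (0,1)")
        if not (self.loss_ratio_max < 1.0 < self.gain_ratio_min):
            raise ConfigError("need loss_ratio_max < 1 < gain_ratio_min")
        if self.step <= 0 or self.window_size <= 0 or self.step > self.window_size:
            raise ConfigError("need 0 < step <= window_size")
        if self.window_size % self.step != 0:
            raise ConfigError("step must divide window_size")


@dataclass
class SvConfig:
    """Structural-variant support filtering parameters."""

    tumor_min_support: int = 7
    normal_min_support: int = 3
    centromere_intervals: GenomeIntervals = field(default_factory=GenomeIntervals)
    breakpoint_match_slop: int = 0
    require_same_type: bool = True

    def __post_init__(self):
        if self.tumor_min_support < 1 or self.normal_min_support < 1:
            raise ConfigError("support thresholds must be >= 1")
        if self.breakpoint_match_slop < 0:
            raise ConfigError("slop must be >= 0")


@dataclass
class ZygosityConfig:
    """Allele-fraction classification and LOH-screen parameters."""

    high_af_threshold: float = 0.60
    homozygous_af_min: float = 0.90
    min_depth: int = 20
    loh_window: int = 1_000_000
    het_af_band: tuple[float, float] = (0.35, 0.65)
    # Median folded (major-allele) fraction beyond this bound suggests LOH;
    # default = upper edge of a +/-0.15 band around 0.5.
    loh_major_af_max: float = 0.65
    min_informative_sites: int = 3

    def __post_init__(self):
        for name in ("high_af_threshold", "homozygous_af_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0,1)")
        if self.homozygous_af_min <= self.high_af_threshold:
            raise ConfigError("homozygous_af_min must exceed high_af_threshold")
        lo, hi = self.het_af_band
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("het_af_band must satisfy 0 < lo < hi < 1")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")


# --------------------------------------------------------------------------
# Synthetic-data generation


@dataclass(frozen=True)
class CnvTruth:
    """An embedded copy-number segment: 1-based inclusive coords, integer dosage != 2."""

    chrom: str
    start: int
    end: int
    dosage: int


@dataclass(frozen=True)
class SvTruth:
    """One structural-variant truth record for the SV simulator.

    ``with_normal_support``: True/False forces a matched normal call;
    None leaves it to the configured fraction. ``centromeric`` places
    breakpoint 1 inside the synthetic centromere of its chromosome.
    """

    sv_type: str
    state: str
    breakpoint1: tuple[str, int, int]
    breakpoint2: tuple[str, int, int]
    tumor_support_mean: float = 10.0
    normal_support_mean: float = 5.0
    with_normal_support: Optional[bool] = None
    centromeric: bool = False


@dataclass(frozen=True)
class VariantSpec:
    """One planned variant category for the variant-table simulator.

    ``count`` records of class ``variant_class`` / consequence ``consequence``
    are emitted. ``panel_class`` is one of 'novel' (absent from all panels),
    'rare' (present at <= 0.1%), 'common' (> 0.1%); ``context_class`` applies
    to indels: 'clean', 'simple_repeat', 'identical_repeat', 'homopolymer'.
    ``fixed_depths`` optionally pins (tumor_alt, tumor_ref, normal_alt,
    normal_ref) for every record of the category.
    """

    count: int
    origin: str = "somatic"           # "somatic" | "germline"
    variant_class: str = "snv"
    consequence: str = "missense"
    panel_class: str = "novel"
    context_class: str = "clean"
    in_segdup: bool = False
    fixed_depths: Optional[tuple[int, int, int, int]] = None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic tumor/normal generator.

    The defaults emulate the sequencing design at desk scale: a 20-Mb genome
    over 2 chromosomes tiled into 100-kb windows at 10-kb steps, with
    genome-wide read totals corresponding to ~7.4x normal and ~7.7x tumor
    coverage at 100-bp reads (1.48e6 / 1.54e6 reads), and per-window
    mapping-probability heterogeneity with ~10% coefficient of variation.
    """

    genome_length: int = 10_000_000          # per chromosome
    n_chromosomes: int = 2
    normal_total_reads: int = 1_480_000
    tumor_total_reads: int = 1_540_000
    mapability_dispersion: float = 0.01      # CV^2 of per-tile mapping probability
    window_size: int = 100_000
    step: int = 10_000
    embedded_cnvs: Sequence[CnvTruth] = ()
    n_somatic_variants: int = 20
    n_germline_variants: int = 10
    somatic_af_distribution: tuple[float, float] = (8.0, 12.0)  # Beta(a, b), mean 0.4
    indel_fraction: float = 0.3
    indel_context_mix: dict[str, float] = field(default_factory=lambda: {
        "clean": 0.4, "simple_repeat": 0.2, "identical_repeat": 0.2, "homopolymer": 0.2})
    fraction_common_panel: float = 0.1       # somatic candidates that are panel-common artifacts
    mean_depth_tumor: float = 120.0          # exome-like depths for the variant table
    mean_depth_normal: float = 90.0
    variant_plan: Optional[Sequence[VariantSpec]] = None
    sv_truth: Sequence[SvTruth] = ()
    fraction_with_normal_support: float = 0.0
    fraction_centromeric: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("genome_length and n_chromosomes must be positive")
        if self.normal_total_reads <= 0 or self.tumor_total_reads <= 0:
            raise ConfigError("read totals must be positive")
        if self.mapability_dispersion < 0:
            raise ConfigError("mapability_dispersion must be >= 0")
        if self.step <= 0 or self.window_size % self.step != 0:
            raise ConfigError("step must be positive and divide window_size")
        mix = self.indel_context_mix
        if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("indel_context_mix proportions must sum to 1")
        self.embedded_cnvs = tuple(self.embedded_cnvs)
        seen: dict[str, list[tuple[int, int]]] = {}
        for seg in self.embedded_cnvs:
            if seg.dosage == 2 or seg.dosage < 0:
                raise ConfigError(f"embedded CNV dosage must be a nonnegative integer != 2: {seg}")
            if not (1 <= seg.start <= seg.end <= self.genome_length):
                raise ConfigError(
                    f"embedded CNV outside genome [1, {self.genome_length}]: "
                    f"{seg.chrom}:{seg.start}-{seg.end}")
            for (s, e) in seen.get(seg.chrom, []):
                if not (seg.end < s or seg.start > e):
                    raise ConfigError(f"embedded CNVs overlap on {seg.chrom}")
            seen.setdefault(seg.chrom, []).append((seg.start, seg.end))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; see report.run_pipeline."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    sv: SvConfig = field(default_factory=SvConfig)
    zygosity: ZygosityConfig = field(default_factory=ZygosityConfig)
    simulation: Optional[SimulationConfig] = None  # generate inputs when set
    variant_path: Optional[Path] = None
    window_path: Optional[Path] = None
    sv_tumor_path: Optional[Path] = None
    sv_normal_path: Optional[Path] = None
    gene_bed: Optional[Path] = None
    output_dir: Path = Path("somaticsieve_out")
    seed: int = 0
    write_timestamp: bool = False
    verbosity: str = "INFO"
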