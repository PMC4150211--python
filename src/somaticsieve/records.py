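"""Core domain types: variants, read-count tracks, CNV segments, SV calls.

Coordinate conventions: variant positions are 1-based (VCF style); window and
interval coordinates are held 0-based half-open internally and converted to
1-based inclusive only in report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import MalformedRecordError

VARIANT_CLASSES = frozenset({"snv", "insertion", "deletion"})

CONSEQUENCES = frozenset({
    "missense", "nonsense", "frameshift", "inframe",
    "splice_donor_acceptor", "synonymous", "noncoding", "other",
})

PANELS = ("HapMap", "1000Genomes", "ESP", "Wellderly")


@dataclass
class VariantRecord:
    """One candidate somatic small variant with the evidence the filters need.

    ``panel_frequencies`` maps population panel name to alternate allele
    frequency; a panel the variant is absent from is simply omitted (treated
    as frequency 0 by the frequency filter). ``context_5p``/``context_3p``
    are flanking reference sequence written 5'->3', so the base of
    ``context_5p`` adjacent to the variant is its *last* character and the
    adjacent base of ``context_3p`` is its *first*.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    tumor_alt_depth: int
    tumor_ref_depth: int
    normal_alt_depth: int
    normal_ref_depth: int
    panel_frequencies: dict[str, float] = field(default_factory=dict)
    consequence: str = "other"
    context_5p: str = ""
    context_3p: str = ""
    gene: str = ""
    protein_change: str = ""
    impact_prediction: str = ""

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise MalformedRecordError(
                f"unknown variant_class {self.variant_class!r} at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise MalformedRecordError(
                f"unknown consequence {self.consequence!r} at {self.chrom}:{self.pos}")
        for name in ("tumor_alt_depth", "tumor_ref_depth",
                     "normal_alt_depth", "normal_ref_depth"):
            if getattr(self, name) < 0:
                raise MalformedRecordError(f"negative {name} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise MalformedRecordError(f"ref == alt at {self.chrom}:{self.pos}")
        for panel, freq in self.panel_frequencies.items():
            if not (0.0 <= freq <= 1.0):
                raise MalformedRecordError(
                    f"panel frequency {panel}={freq} outside [0,1] at {self.chrom}:{self.pos}")
        if self.variant_class == "snv" and len(self.ref) != len(self.alt):
            raise MalformedRecordError(
                f"snv with unequal allele lengths at {self.chrom}:{self.pos}")
        if self.variant_class == "insertion" and not (self.alt not in ("-", "") and
                                                      len(self.indel_sequence()) >= 1):
            raise MalformedRecordError(f"insertion without inserted bases at {self.chrom}:{self.pos}")
        if self.variant_class == "deletion" and not (self.ref not in ("-", "") and
                                                     len(self.indel_sequence()) >= 1):
            raise MalformedRecordError(f"deletion without deleted bases at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        return self.variant_class in ("insertion", "deletion")

    def indel_sequence(self) -> str:
        """The inserted or deleted bases ('' for SNVs).

        Alleles may be given VCF-style (anchored: ref 'A', alt 'AG') or
        bare ('-' for the empty allele, as in 'del G>-').
        """
        if self.variant_class == "insertion":
            alt = self.alt
            if self.ref not in ("-", "") and alt.startswith(self.ref):
                return alt[len(self.ref):]
            return "" if alt == "-" else alt
        if self.variant_class == "deletion":
            ref = self.ref
            if self.alt not in ("-", "") and ref.startswith(self.alt):
                return ref[len(self.alt):]
            return "" if ref == "-" else ref
        return ""


@dataclass
class FilterVerdict:
    """Outcome of the filter cascade for one record."""

    record: VariantRecord
    kept: bool
    failed_rules: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kept != (len(self.failed_rules) == 0):
            raise MalformedRecordError("kept inconsistent with failed_rules")


@dataclass
class WindowTrack:
    """Paired tumor/normal read counts over tiled genomic windows.

    ``windows`` is a DataFrame with columns chrom, start, end (0-based
    half-open), normal_count, tumor_count. Totals are genome-wide mapped-read
    totals; per-window counts never exceed them.
    """

    windows: pd.DataFrame
    normal_total: int
    tumor_total: int

    def __post_init__(self):
        required = {"chrom", "start", "end", "normal_count", "tumor_count"}
        missing = required - set(self.windows.columns)
        if missing:
            raise MalformedRecordError(f"window table missing columns: {sorted(missing)}")
        if self.normal_total <= 0 or self.tumor_total <= 0:
            raise MalformedRecordError("read totals must be positive")
        w = self.windows
        if len(w) and ((w["normal_count"] > self.normal_total).any()
                       or (w["tumor_count"] > self.tumor_total).any()):
            raise MalformedRecordError("per-window count exceeds sample total")

    def __len__(self) -> int:
        return len(self.windows)

    def swapped(self) -> "WindowTrack":
        """Track with tumor and normal roles exchanged (for symmetry checks)."""
        w = self.windows.rename(columns={"normal_count": "tumor_count",
                                         "tumor_count": "normal_count"})
        return WindowTrack(w[["chrom", "start", "end", "normal_count", "tumor_count"]],
                           normal_total=self.tumor_total, tumor_total=self.normal_total)


@dataclass
class CnvSegment:
    """A merged run of significant windows with direction, ratio and dosage."""

    chrom: str
    start: int           # 0-based half-open internally
    end: int
    direction: str       # "gain" | "loss"
    ratio: float
    dosage: int
    min_p: float
    n_windows: int = 0
    genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise MalformedRecordError(f"bad direction {self.direction!r}")
        if self.end <= self.start:
            raise MalformedRecordError("segment end <= start")
        if self.dosage < 0:
            raise MalformedRecordError("negative dosage")

    @property
    def start1(self) -> int:
        """1-based inclusive start for report output."""
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    @property
    def size_kb(self) -> int:
        return (self.end1 - self.start1 + 1) // 1000


@dataclass
class SvCall:
    """One candidate structural variant with two breakpoint intervals.

    ``sv_type`` and ``state`` are pass-through vocabulary from the upstream
    paired-end caller (e.g. 'Inversion'/'Unbal'); breakpoints are 0-based
    half-open (chrom, start, end) tuples.
    """

    sv_type: str
    state: str
    breakpoint1: tuple[str, int, int]
    breakpoint2: tuple[str, int, int]
    support_reads: int
    sample: str  # "tumor" | "normal"
    genes: str = ""

    def __post_init__(self):
        if self.sample not in ("tumor", "normal"):
            raise MalformedRecordError(f"SV call sample must be tumor/normal, got {self.sample!r}")
        if self.support_reads < 0:
            raise MalformedRecordError("negative support_reads")
        for bp in (self.breakpoint1, self.breakpoint2):
            if bp[2] < bp[1]:
                raise MalformedRecordError(f"malformed breakpoint interval {bp}")


@dataclass
class RunSummary:
    """Aggregate counts for one pipeline run; see report.run_pipeline."""

    n_input_variants: int = 0
    n_kept_variants: int = 0
    n_removed_variants: int = 0
    kept_by_consequence: dict[str, int] = field(default_factory=dict)
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_kept_snvs: int = 0
    n_kept_indels: int = 0
    n_cnv_gains: int = 0
    n_cnv_losses: int = 0
    n_sv_input_tumor: int = 0
    n_sv_somatic: int = 0
    n_high_af: int = 0
    loh_status: Optional[str] = None

    def check_consistency(self) -> None:
        assert self.n_input_variants == self.n_kept_variants + self.n_removed_variants, \
            "variant counts do not balance"
        assert self.n_kept_variants == sum(self.kept_by_consequence.values()), \
            "kept-by-class tally does not balance"
        assert self.n_kept_variants == self.n_kept_snvs + self.n_kept_indels, \
            "kept snv/indel split does not balance"
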