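"""Loaders for the in-repo thymoma case reference tables.

The package ships transcriptions of the three result tables from a
tumor/normal genomic study of a cytogenetically normal B3 thymoma: 17
protein-impacting somatic coding mutations, 17 copy-number segments
(16 gains, 1 loss) and 6 somatic structural variants.

The printed tables carry gene, consequence and coordinate information only.
Auxiliary evidence the pipeline operates on but the tables do not print —
read depths (except the DNMT3A site's published 61/62 tumor and 0/41 normal
reads), indel flanking contexts, and per-call SV support counts — is
synthetic: fixed stand-in values chosen to be unremarkable (clean
non-repetitive flanks, depths well above minimums, supports at or above
threshold), marked as such below.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .intervals import GenomeIntervals
from .records import CnvSegment, SvCall, VariantRecord
from .tables import (IMPACT_TO_CONSEQUENCE, parse_span_coordinate,
                     parse_variant_coordinate)

# Synthetic clean flanks shared by all fixture records: GATC cycle (max run
# length 1, never starts/ends with the fixture indel bases G or T adjacency
# conflicts; checked in tests).
_CLEAN_5P = "GATCGATCGATC"
_CLEAN_3P = "ATCGATCGATCG"

# Synthetic depths for records without published counts (tumor_alt, tumor_ref,
# normal_alt, normal_ref); heterozygous-looking tumor evidence, absent normal.
_DEFAULT_DEPTHS = (45, 55, 0, 60)

# Published read counts for the DNMT3A p.G728D site: 61/62 tumor, 0/41 normal.
_DNMT3A_DEPTHS = (61, 1, 0, 41)


def _table_path(name: str):
    return resources.files("somaticsieve.data").joinpath(name)


def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_table_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def coding_mutation_records() -> list[VariantRecord]:
    """The 17 coding-mutation rows as VariantRecord objects."""
    df = load_table("thymoma_coding_mutations.tsv")
    records = []
    for _, row in df.iterrows():
        chrom, pos, vclass, ref, alt = parse_variant_coordinate(row["Coordinates (hg19)"])
        depths = _DNMT3A_DEPTHS if row["Gene"] == "DNMT3A" else _DEFAULT_DEPTHS
        records.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=vclass,
            tumor_alt_depth=depths[0], tumor_ref_depth=depths[1],
            normal_alt_depth=depths[2], normal_ref_depth=depths[3],
            panel_frequencies={},
            consequence=IMPACT_TO_CONSEQUENCE[row["Gene impact"]],
            context_5p=_CLEAN_5P, context_3p=_CLEAN_3P,
            gene=row["Gene"], protein_change=row["Protein location"],
            impact_prediction=row["Prediction of impact"],
        ))
    return records


def cnv_segments() -> list[CnvSegment]:
    """The 17 copy-number rows as CnvSegment objects (ratio back-computed as dosage/2)."""
    df = load_table("thymoma_cnv_segments.tsv")
    segments = []
    for _, row in df.iterrows():
        chrom, start1, end1 = parse_span_coordinate(row["Coordinates"])
        dosage = int(row["Dosage"])
        genes = [] if row["Overlapping genes"] == "None" else [row["Overlapping genes"]]
        segments.append(CnvSegment(
            chrom=chrom, start=start1 - 1, end=end1,
            direction=row["Type"].lower(), ratio=dosage / 2.0,
            dosage=dosage, min_p=0.0, genes=genes,
        ))
    return segments


# Synthetic support counts for the six published SV rows (>= 7 by
# construction, one exactly at the boundary).
_SV_SUPPORTS = (9, 12, 8, 15, 7, 11)


def sv_somatic_calls() -> list[SvCall]:
    """The six structural-variant rows as tumor SvCall objects."""
    df = load_table("thymoma_structural_variants.tsv")
    calls = []
    for i, (_, row) in enumerate(df.iterrows()):
        c1, s1, e1 = parse_span_coordinate(row["Breakpoint 1"])
        c2, s2, e2 = parse_span_coordinate(row["Breakpoint 2"])
        calls.append(SvCall(
            sv_type=row["Type"], state=row["State"],
            breakpoint1=(c1, s1 - 1, e1), breakpoint2=(c2, s2 - 1, e2),
            support_reads=_SV_SUPPORTS[i], sample="tumor",
            genes="" if row["Overlapping genes"] == "None" else row["Overlapping genes"],
        ))
    return calls


def sv_candidate_fixture() -> tuple[list[SvCall], GenomeIntervals]:
    """A synthetic raw SV candidate set around the six reference calls.

    Adds three tumor distractors — one below the 7-read support threshold,
    one matched by a same-type normal call, one with a centromeric
    breakpoint — plus the corresponding normal calls and a synthetic
    centromere mask, so that exactly the six reference calls survive
    threshold + subtraction.
    """
    calls = sv_somatic_calls()
    low_support = SvCall(sv_type="Duplication", state="Bal",
                         breakpoint1=("chr5", 10_000_000, 10_003_000),
                         breakpoint2=("chr5", 10_200_000, 10_203_000),
                         support_reads=6, sample="tumor")
    matched = SvCall(sv_type="Deletion", state="Unbal",
                     breakpoint1=("chr12", 50_000_000, 50_004_000),
                     breakpoint2=("chr12", 50_300_000, 50_304_000),
                     support_reads=10, sample="tumor")
    matched_normal = SvCall(sv_type="Deletion", state="Unbal",
                            breakpoint1=("chr12", 50_000_500, 50_003_500),
                            breakpoint2=("chr12", 50_300_500, 50_303_500),
                            support_reads=4, sample="normal")
    centromeric = SvCall(sv_type="Inversion", state="Unbal",
                         breakpoint1=("chr1", 121_600_000, 121_604_000),
                         breakpoint2=("chr1", 140_000_000, 140_004_000),
                         support_reads=9, sample="tumor")
    weak_normal = SvCall(sv_type="Duplication", state="Bal",
                         breakpoint1=("chr18", 20_000_000, 20_003_000),
                         breakpoint2=("chr18", 20_500_000, 20_503_000),
                         support_reads=2, sample="normal")
    centromeres = GenomeIntervals([("chr1", 121_500_000, 124_500_000)])
    return calls + [low_support, matched, centromeric, matched_normal, weak_normal], centromeres
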