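"""Report-table formatting and parsing.

The three result tables mirror the case-report layout: coding mutations
(Gene / Gene impact / Protein location / Prediction of impact / Coordinates),
copy-number variants (Type / Coordinates / Size (kb) / Dosage / Overlapping
genes) and structural variants (Type / State / Breakpoint 1 / Breakpoint 2 /
Overlapping genes). Positions are printed 1-based inclusive with
space-grouped digits ('470 001-600 000' style, en-dash separator).
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError
from .records import CnvSegment, SvCall, VariantRecord

EN_DASH = "–"

CONSEQUENCE_TO_IMPACT = {
    "missense": "Missense", "nonsense": "Nonsense", "frameshift": "Frameshift",
    "inframe": "In-frame", "splice_donor_acceptor": "Splice site",
    "synonymous": "Synonymous", "noncoding": "Noncoding", "other": "Other",
}
IMPACT_TO_CONSEQUENCE = {v: k for k, v in CONSEQUENCE_TO_IMPACT.items()}


def group_digits(n: int) -> str:
    """1234567 -> '1 234 567' (space-grouped thousands)."""
    return f"{n:,}".replace(",", " ")


def parse_grouped(text: str) -> int:
    return int(text.replace(" ", "").replace(" ", ""))


def variant_coordinate(record: VariantRecord) -> str:
    """'chr20: 31 022 486 del G>-' style coordinate field."""
    token = {"snv": "snp", "deletion": "del", "insertion": "ins"}[record.variant_class]
    return (f"{record.chrom}: {group_digits(record.pos)} {token} "
            f"{record.ref}>{record.alt}")


_VAR_COORD_RE = re.compile(
    r"^(?P<chrom>\S+):\s*(?P<pos>[\d  ]+)\s+(?P<token>snp|del|ins)\s+"
    r"(?P<ref>\S+)>(?P<alt>\S+)$")


def parse_variant_coordinate(text: str) -> tuple[str, int, str, str, str]:
    """Inverse of variant_coordinate; returns (chrom, pos, variant_class, ref, alt)."""
    m = _VAR_COORD_RE.match(text.strip())
    if not m:
        raise FormatError(f"unparseable variant coordinate: {text!r}")
    token_to_class = {"snp": "snv", "del": "deletion", "ins": "insertion"}
    return (m.group("chrom"), parse_grouped(m.group("pos")),
            token_to_class[m.group("token")], m.group("ref"), m.group("alt"))


def span_coordinate(chrom: str, start1: int, end1: int) -> str:
    """'chr1: 470 001-600 000' (1-based inclusive, en-dash)."""
    return f"{chrom}: {group_digits(start1)}{EN_DASH}{group_digits(end1)}"


_SPAN_RE = re.compile(
    r"^(?P<chrom>\S+):\s*(?P<start>[\d  ]+)[–—-]"
    r"(?P<end>[\d  ]+)$")


def parse_span_coordinate(text: str) -> tuple[str, int, int]:
    """Inverse of span_coordinate; returns (chrom, start1, end1)."""
    m = _SPAN_RE.match(text.strip())
    if not m:
        raise FormatError(f"unparseable span coordinate: {text!r}")
    return (m.group("chrom"), parse_grouped(m.group("start")),
            parse_grouped(m.group("end")))


def coding_mutation_table(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [{
        "Gene": r.gene or ".",
        "Gene impact": CONSEQUENCE_TO_IMPACT[r.consequence],
        "Protein location": r.protein_change or ".",
        "Prediction of impact": r.impact_prediction or ".",
        "Coordinates (hg19)": variant_coordinate(r),
    } for r in records]
    return pd.DataFrame(rows, columns=["Gene", "Gene impact", "Protein location",
                                       "Prediction of impact", "Coordinates (hg19)"])


def cnv_table(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    rows = [{
        "Type": seg.direction.capitalize(),
        "Coordinates": span_coordinate(seg.chrom, seg.start1, seg.end1),
        "Size (kb)": seg.size_kb,
        "Dosage": seg.dosage,
        "Overlapping genes": ", ".join(seg.genes) if seg.genes else "None",
    } for seg in segments]
    return pd.DataFrame(rows, columns=["Type", "Coordinates", "Size (kb)",
                                       "Dosage", "Overlapping genes"])


def sv_table(calls: Iterable[SvCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        b1, b2 = c.breakpoint1, c.breakpoint2
        rows.append({
            "Type": c.sv_type,
            "State": c.state,
            "Breakpoint 1": span_coordinate(b1[0], b1[1] + 1, b1[2]),
            "Breakpoint 2": span_coordinate(b2[0], b2[1] + 1, b2[2]),
            "Overlapping genes": c.genes or "None",
        })
    return pd.DataFrame(rows, columns=["Type", "State", "Breakpoint 1",
                                       "Breakpoint 2", "Overlapping genes"])


def write_table(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
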