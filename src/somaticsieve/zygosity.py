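"""Allele fractions, zygosity classification and LOH screening.

The variant allele fraction AF = alt / (alt + ref) drives three screens:

* zygosity classification of somatic mutations in the tumor — a somatic
  mutation at AF near 1 (default >= 0.90 at >= 20x) is in homozygous state,
  an unusual configuration suggesting gene conversion at the locus;
* a scan for somatic mutations above a high-AF threshold (default > 60%);
* a regional loss-of-heterozygosity screen using sites heterozygous in the
  normal (normal AF in [0.35, 0.65] at adequate depth): under LOH the tumor
  loses one parental allele, pushing tumor AF toward 0 or 1 depending on
  phase, so the screen uses the *major-allele* (folded) fraction
  |AF - 0.5| + 0.5, whose median stays near 0.5-0.55 in diploid regions and
  rises toward 1 under allelic imbalance.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Sequence

from .config import ZygosityConfig
from .errors import UndefinedAlleleFractionError
from .records import VariantRecord

ZYGOSITY_LABELS = ("absent", "heterozygous", "high_af", "homozygous", "low_depth")


def allele_fraction(alt_depth: int, ref_depth: int) -> tuple[float, float]:
    """(fraction, percentage) with the percentage rounded half-up to 1 decimal.

    61 alt / 1 ref reads give fraction 0.98387... and percentage 98.4.
    """
    if alt_depth < 0 or ref_depth < 0:
        raise UndefinedAlleleFractionError("negative depth")
    total = alt_depth + ref_depth
    if total == 0:
        raise UndefinedAlleleFractionError("zero total depth")
    frac = alt_depth / total
    pct = float(Decimal(str(100.0 * frac)).quantize(Decimal("0.1"),
                                                    rounding=ROUND_HALF_UP))
    return frac, pct


def format_percentage(pct: float) -> str:
    """Render a percentage the way report tables print it: '98.4%', '0%'."""
    if pct == int(pct):
        return f"{int(pct)}%"
    return f"{pct:.1f}%"


def tumor_af(record: VariantRecord) -> float:
    return allele_fraction(record.tumor_alt_depth, record.tumor_ref_depth)[0]


def normal_af(record: VariantRecord) -> float:
    return allele_fraction(record.normal_alt_depth, record.normal_ref_depth)[0]


def classify_zygosity(record: VariantRecord, config: ZygosityConfig) -> str:
    """One of absent / heterozygous / high_af / homozygous / low_depth (tumor sample).

    Labels partition: depth below min_depth wins; then alt_depth = 0 is
    absent; then AF >= homozygous_af_min is homozygous, AF > high_af_threshold
    is high_af, and anything else (0 < AF <= threshold) is heterozygous.
    """
    total = record.tumor_alt_depth + record.tumor_ref_depth
    if total < config.min_depth:
        return "low_depth"
    if record.tumor_alt_depth == 0:
        return "absent"
    af = tumor_af(record)
    if af >= config.homozygous_af_min:
        return "homozygous"
    if af > config.high_af_threshold:
        return "high_af"
    return "heterozygous"


def scan_high_af(records: Iterable[VariantRecord], config: ZygosityConfig
                 ) -> list[tuple[VariantRecord, float]]:
    """Somatic records with tumor AF strictly above the threshold, AF-descending."""
    hits = []
    for rec in records:
        if rec.tumor_alt_depth + rec.tumor_ref_depth == 0:
            continue
        af = tumor_af(rec)
        if af > config.high_af_threshold:
            hits.append((rec, af))
    hits.sort(key=lambda pair: pair[1], reverse=True)
    return hits


def _in_region(rec: VariantRecord, region: tuple[str, int, int] | None) -> bool:
    if region is None:
        return True
    chrom, start1, end1 = region
    return rec.chrom == chrom and start1 <= rec.pos <= end1


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive)."""
    chrom, _, span = text.partition(":")
    start, _, end = span.partition("-")
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def loh_screen(germline_records: Sequence[VariantRecord],
               region: tuple[str, int, int] | None,
               config: ZygosityConfig) -> dict:
    """Screen a region for loss of heterozygosity.

    Informative sites are those heterozygous in the normal (normal AF inside
    the het band at depth >= min_depth). The decision statistic is the median
    tumor major-allele fraction over informative sites: 'no_loh' when it stays
    at or below ``loh_major_af_max`` (default 0.65, i.e. within +/-0.15 of
    0.5), 'loh_suspected' beyond it, 'uninformative' with fewer than
    ``min_informative_sites`` sites.
    """
    lo, hi = config.het_af_band
    informative = []
    for rec in germline_records:
        if not _in_region(rec, region):
            continue
        n_total = rec.normal_alt_depth + rec.normal_ref_depth
        if n_total < config.min_depth:
            continue
        naf = rec.normal_alt_depth / n_total
        if not (lo <= naf <= hi):
            continue
        t_total = rec.tumor_alt_depth + rec.tumor_ref_depth
        if t_total == 0:
            continue
        informative.append(rec.tumor_alt_depth / t_total)

    if len(informative) < config.min_informative_sites:
        return {"status": "uninformative", "n_informative": len(informative),
                "median_major_af": float("nan")}
    major = [abs(af - 0.5) + 0.5 for af in informative]
    med = median(major)
    status = "loh_suspected" if med > config.loh_major_af_max else "no_loh"
    return {"status": status, "n_informative": len(informative),
            "median_major_af": med}
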