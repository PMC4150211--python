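"""Readers and writers for the pipeline's tab-delimited and VCF formats.

All on-disk table formats are plain UTF-8 TSV. Window tracks are 5-column
BED-like files (0-based half-open) with genome-wide read totals in header
lines; variant tables carry one record per row with panel frequencies packed
as ``panel=freq`` pairs; SV link tables follow the SVDetect-style layout
(type, state, two breakpoint intervals, support, sample).

VCF input is read through cyvcf2; allele depths come from the AD FORMAT
field of the named tumor/normal samples and panel frequencies / consequence
/ flanking context from configurable INFO keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError
from .records import SvCall, VariantRecord, WindowTrack

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_class",
    "tumor_alt_depth", "tumor_ref_depth", "normal_alt_depth", "normal_ref_depth",
    "panel_frequencies", "consequence", "context_5p", "context_3p",
    "gene", "protein_change", "impact_prediction",
]

SV_COLUMNS = [
    "sv_type", "state", "chrom1", "start1", "end1",
    "chrom2", "start2", "end2", "support_reads", "sample", "genes",
]

DEFAULT_INFO_KEYS = {
    "HapMap": "AF_HAPMAP", "1000Genomes": "AF_1000G",
    "ESP": "AF_ESP", "Wellderly": "AF_WELLDERLY",
}


# --------------------------------------------------------------------------
# Window tracks


def write_window_track(track: WindowTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#normal_total={track.normal_total}\n")
        fh.write(f"#tumor_total={track.tumor_total}\n")
        track.windows.to_csv(fh, sep="\t", header=False, index=False,
                             columns=["chrom", "start", "end",
                                      "normal_count", "tumor_count"])


def read_window_track(path: str | Path, totals: str = "header") -> WindowTrack:
    """Read a 5-column window-count file.

    ``totals`` is 'header' (read ``#normal_total=``/``#tumor_total=`` lines)
    or 'sum' (derive totals by summing the window counts — only correct for
    non-overlapping windows covering the genome).
    """
    header_totals: dict[str, int] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, val = line[1:].strip().partition("=")
            if key in ("normal_total", "tumor_total"):
                header_totals[key] = int(val)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "normal_count", "tumor_count"])
    if totals == "header":
        if set(header_totals) != {"normal_total", "tumor_total"}:
            raise FormatError(f"{path}: missing #normal_total/#tumor_total header lines")
        n_tot, t_tot = header_totals["normal_total"], header_totals["tumor_total"]
    elif totals == "sum":
        n_tot = int(df["normal_count"].sum())
        t_tot = int(df["tumor_count"].sum())
    else:
        raise ValueError("totals must be 'header' or 'sum'")
    return WindowTrack(df, normal_total=n_tot, tumor_total=t_tot)


# --------------------------------------------------------------------------
# Variant tables


def _pack_freqs(freqs: dict[str, float]) -> str:
    if not freqs:
        return "."
    return ";".join(f"{k}={v!r}" for k, v in sorted(freqs.items()))


def _unpack_freqs(text: str) -> dict[str, float]:
    if not text or text in (".", "nan"):
        return {}
    out = {}
    for item in str(text).split(";"):
        key, _, val = item.partition("=")
        if not val:
            raise FormatError(f"bad panel frequency field: {text!r}")
        out[key] = float(val)
    return out


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "variant_class": r.variant_class,
            "tumor_alt_depth": r.tumor_alt_depth, "tumor_ref_depth": r.tumor_ref_depth,
            "normal_alt_depth": r.normal_alt_depth, "normal_ref_depth": r.normal_ref_depth,
            "panel_frequencies": _pack_freqs(r.panel_frequencies),
            "consequence": r.consequence,
            "context_5p": r.context_5p or ".", "context_3p": r.context_3p or ".",
            "gene": r.gene or ".", "protein_change": r.protein_change or ".",
            "impact_prediction": r.impact_prediction or ".",
        })
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(VariantRecord(
            chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
            variant_class=row["variant_class"],
            tumor_alt_depth=int(row["tumor_alt_depth"]),
            tumor_ref_depth=int(row["tumor_ref_depth"]),
            normal_alt_depth=int(row["normal_alt_depth"]),
            normal_ref_depth=int(row["normal_ref_depth"]),
            panel_frequencies=_unpack_freqs(row["panel_frequencies"]),
            consequence=row["consequence"],
            context_5p="" if row["context_5p"] == "." else row["context_5p"],
            context_3p="" if row["context_3p"] == "." else row["context_3p"],
            gene="" if row["gene"] == "." else row["gene"],
            protein_change="" if row["protein_change"] == "." else row["protein_change"],
            impact_prediction="" if row["impact_prediction"] == "." else row["impact_prediction"],
        ))
    return records


def read_vcf(path: str | Path, tumor_sample: str, normal_sample: str,
             info_keys: dict[str, str] | None = None,
             consequence_key: str = "CSQ_CLASS",
             context_keys: tuple[str, str] = ("CTX5", "CTX3"),
             gene_key: str = "GENE") -> list[VariantRecord]:
    """Read candidate variants from a VCF with per-sample AD depths.

    ``info_keys`` maps panel name -> INFO key holding its allele frequency
    (defaults to AF_HAPMAP / AF_1000G / AF_ESP / AF_WELLDERLY).
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is slow

    info_keys = dict(DEFAULT_INFO_KEYS if info_keys is None else info_keys)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)
    except ValueError as exc:
        raise FormatError(f"{path}: samples {tumor_sample}/{normal_sample} "
                          f"not found (has {samples})") from exc
    records = []
    for var in vcf:
        if not var.ALT:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) == len(alt) == 1:
            vclass = "snv"
        elif len(alt) > len(ref):
            vclass = "insertion"
        else:
            vclass = "deletion"
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"{path}: AD FORMAT field required")
        freqs = {}
        for panel, key in info_keys.items():
            val = var.INFO.get(key)
            if val is not None:
                freqs[panel] = float(val)
        records.append(VariantRecord(
            chrom=var.CHROM, pos=var.POS, ref=ref, alt=alt, variant_class=vclass,
            tumor_alt_depth=int(ad[t_idx][1]), tumor_ref_depth=int(ad[t_idx][0]),
            normal_alt_depth=int(ad[n_idx][1]), normal_ref_depth=int(ad[n_idx][0]),
            panel_frequencies=freqs,
            consequence=str(var.INFO.get(consequence_key) or "other"),
            context_5p=str(var.INFO.get(context_keys[0]) or ""),
            context_3p=str(var.INFO.get(context_keys[1]) or ""),
            gene=str(var.INFO.get(gene_key) or ""),
        ))
    return records


# --------------------------------------------------------------------------
# SV link tables


def write_sv_table(calls: Iterable[SvCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "sv_type": c.sv_type, "state": c.state,
            "chrom1": c.breakpoint1[0], "start1": c.breakpoint1[1], "end1": c.breakpoint1[2],
            "chrom2": c.breakpoint2[0], "start2": c.breakpoint2[1], "end2": c.breakpoint2[2],
            "support_reads": c.support_reads, "sample": c.sample,
            "genes": c.genes or ".",
        })
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path, sample: str | None = None) -> list[SvCall]:
    """Read an SVDetect-style link table; ``sample`` overrides/supplies the label."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SV_COLUMNS) - set(df.columns) - {"sample", "genes"}
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for _, row in df.iterrows():
        label = sample if sample is not None else row.get("sample", "")
        calls.append(SvCall(
            sv_type=row["sv_type"], state=row["state"],
            breakpoint1=(row["chrom1"], int(row["start1"]), int(row["end1"])),
            breakpoint2=(row["chrom2"], int(row["start2"]), int(row["end2"])),
            support_reads=int(row["support_reads"]), sample=label,
            genes="" if row.get("genes", ".") == "." else row.get("genes", ""),
        ))
    return calls
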