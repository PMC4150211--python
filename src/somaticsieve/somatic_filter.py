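"""Somatic small-variant filtration cascade.

Four pure-predicate rules are applied to every candidate somatic SNV/indel:

``frequency``    remove variants seen at > 0.1% allele frequency in any
                 population panel (HapMap, 1000 Genomes, ESP, Wellderly) —
                 such candidates are almost always germline leak-through;
``segdup``       remove variants inside segmental-duplication regions, which
                 are prone to mismapping artifacts;
``context``      (indels only) remove indels inside simple repeats, indels
                 whose inserted/deleted sequence has an identical adjacent
                 tandem copy, and indels adjacent to homopolymer runs of
                 length >= 5 — the classic indel-artifact contexts;
``consequence``  retain only protein-impacting variants (missense, nonsense,
                 frameshift, in-frame, canonical splice donor/acceptor).

Each rule is independent of the others, so the kept/removed decision does not
depend on rule order; the cascade records every failed rule for auditability.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

from .config import FilterConfig
from .errors import (InconclusiveContextError, MalformedRecordError,
                     WrongVariantClassError)
from .records import CONSEQUENCES, FilterVerdict, VariantRecord

RULE_ORDER = ("frequency", "segdup", "context", "consequence")


def frequency_filter(record: VariantRecord, config: FilterConfig) -> bool:
    """True (pass) unless any panel frequency strictly exceeds the maximum.

    A variant absent from a panel counts as frequency 0 there; the boundary
    value (exactly ``max_panel_frequency``) passes.
    """
    for panel, freq in record.panel_frequencies.items():
        if freq < 0:
            raise MalformedRecordError(f"negative frequency for panel {panel}")
        if freq > config.max_panel_frequency:
            return False
    return True


def segdup_filter(record: VariantRecord, config: FilterConfig) -> bool:
    """True unless the variant position falls in a segmental-duplication interval."""
    return not config.segdup_intervals.contains_point(record.chrom, record.pos - 1)


def _run_length(seq: str) -> int:
    """Length of the run of the first character of ``seq``."""
    if not seq:
        return 0
    base, n = seq[0], 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def indel_context_filter(record: VariantRecord, config: FilterConfig
                         ) -> tuple[bool, Optional[str]]:
    """Apply the indel artifact-context rules; returns (pass, reason).

    ``reason`` names the sub-rule that failed (``simple_repeat``,
    ``identical_repeat`` or ``homopolymer``) or is None on pass.

    Raises WrongVariantClassError for SNVs and InconclusiveContextError when
    flanking sequence is unavailable (the cascade reports such records as
    kept-with-warning, not removed).
    """
    if not record.is_indel:
        raise WrongVariantClassError(
            f"indel context filter applied to {record.variant_class} at "
            f"{record.chrom}:{record.pos}")

    if config.simple_repeat_intervals.contains_point(record.chrom, record.pos - 1):
        return False, "simple_repeat"

    if not record.context_5p and not record.context_3p:
        raise InconclusiveContextError(
            f"no flanking context for indel at {record.chrom}:{record.pos}")

    seq = record.indel_sequence().upper()
    up = record.context_5p.upper()    # 5'->3'; adjacent base is up[-1]
    down = record.context_3p.upper()  # 5'->3'; adjacent base is down[0]

    # Homopolymer runs adjacent to the indel, measured outward from the
    # variant on either flank; checked before the identical-repeat rule so a
    # mononucleotide indel beside a same-base run reports the sharper reason.
    # A mononucleotide indel extends the run it sits in, so its own bases
    # count toward the adjacent run length.
    min_len = config.homopolymer_min_len
    down_run = _run_length(down)
    up_run = _run_length(up[::-1])
    if down_run >= min_len or up_run >= min_len:
        return False, "homopolymer"
    if seq and len(set(seq)) == 1:
        base = seq[0]
        run = len(seq)
        if down and down[0] == base:
            run += down_run
        if up and up[-1] == base:
            run += up_run
        if run >= min_len:
            return False, "homopolymer"

    # Identical adjacent tandem copy of the inserted/deleted sequence.
    if seq and (down.startswith(seq) or up.endswith(seq)):
        return False, "identical_repeat"
    return True, None


def consequence_filter(record: VariantRecord, config: FilterConfig) -> bool:
    """True iff the functional consequence is in the retained set."""
    if record.consequence not in CONSEQUENCES:
        raise MalformedRecordError(f"unknown consequence {record.consequence!r}")
    return record.consequence in config.retained_consequences


def _normal_absence(record: VariantRecord, config: FilterConfig) -> bool:
    total = record.normal_alt_depth + record.normal_ref_depth
    if record.normal_alt_depth == 0:
        return True
    return total > 0 and record.normal_alt_depth / total < config.max_normal_af


def evaluate_record(record: VariantRecord, config: FilterConfig) -> FilterVerdict:
    """Run all rules on one record and collect every failure."""
    failed: list[str] = []
    warnings: list[str] = []

    if not frequency_filter(record, config):
        failed.append("frequency")
    if not segdup_filter(record, config):
        failed.append("segdup")
    if record.is_indel:
        try:
            ok, reason = indel_context_filter(record, config)
            if not ok:
                failed.append(f"context:{reason}")
        except InconclusiveContextError:
            warnings.append("context_inconclusive")
    if not consequence_filter(record, config):
        failed.append("consequence")
    if config.require_normal_absence and not _normal_absence(record, config):
        failed.append("normal_evidence")

    return FilterVerdict(record=record, kept=not failed, failed_rules=failed,
                         warnings=warnings)


def run_filter_cascade(records: Iterable[VariantRecord], config: FilterConfig
                       ) -> tuple[list[FilterVerdict], dict]:
    """Filter a candidate list; returns verdicts plus summary counts.

    The summary reports input/kept/removed totals, kept counts by functional
    consequence class, and removal counts by first failed rule.
    """
    verdicts = [evaluate_record(rec, config) for rec in records]
    kept_by_class = Counter(v.record.consequence for v in verdicts if v.kept)
    removed_by_rule = Counter(v.failed_rules[0] for v in verdicts if not v.kept)
    summary = {
        "n_input": len(verdicts),
        "n_kept": sum(v.kept for v in verdicts),
        "n_removed": sum(not v.kept for v in verdicts),
        "n_warnings": sum(bool(v.warnings) for v in verdicts),
        "kept_by_consequence": dict(kept_by_class),
        "removed_by_first_rule": dict(removed_by_rule),
    }
    return verdicts, summary
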