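"""Structural-variant support filtering.

Raw paired-end SV candidates are filtered in two steps: a support-read
threshold per sample (>= 7 reads in the tumor; the matched-normal call set
is built at >= 3 reads), then somatic selection by subtracting tumor calls
whose breakpoints are matched by a same-type normal call and masking calls
with a breakpoint in centromeric regions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .config import SvConfig
from .errors import MalformedRecordError
from .records import SvCall


def threshold_calls(calls: Iterable[SvCall], config: SvConfig
                    ) -> tuple[list[SvCall], list[SvCall]]:
    """Split calls by sample and apply the per-sample support thresholds."""
    tumor, normal = [], []
    for call in calls:
        if call.sample == "tumor":
            if call.support_reads >= config.tumor_min_support:
                tumor.append(call)
        elif call.sample == "normal":
            if call.support_reads >= config.normal_min_support:
                normal.append(call)
        else:  # pragma: no cover - SvCall validation rejects this earlier
            raise MalformedRecordError(f"unlabeled SV call sample: {call.sample!r}")
    return tumor, normal


def _intervals_overlap(a: tuple[str, int, int], b: tuple[str, int, int],
                       slop: int) -> bool:
    if a[0] != b[0]:
        return False
    return a[1] - slop < b[2] and b[1] < a[2] + slop


def _matched_by_normal(call: SvCall, normal_calls: Sequence[SvCall],
                       config: SvConfig) -> bool:
    slop = config.breakpoint_match_slop
    for nc in normal_calls:
        if config.require_same_type and nc.sv_type != call.sv_type:
            continue
        if (_intervals_overlap(call.breakpoint1, nc.breakpoint1, slop)
                and _intervals_overlap(call.breakpoint2, nc.breakpoint2, slop)):
            return True
    return False


def _centromeric(call: SvCall, config: SvConfig) -> bool:
    cen = config.centromere_intervals
    for chrom, start, end in (call.breakpoint1, call.breakpoint2):
        if cen.overlaps(chrom, start, max(end, start + 1)):
            return True
    return False


def subtract_normal(tumor_calls: Sequence[SvCall], normal_calls: Sequence[SvCall],
                    config: SvConfig) -> list[SvCall]:
    """Somatic selection: drop tumor calls with normal support or centromeric breakpoints.

    A tumor call is removed iff both of its breakpoint intervals overlap
    (within the configured slop) the corresponding breakpoints of some
    same-type normal call, or either breakpoint overlaps a centromere
    interval. Survivors are returned unchanged.
    """
    return [c for c in tumor_calls
            if not _matched_by_normal(c, normal_calls, config)
            and not _centromeric(c, config)]


def filter_sv_calls(calls: Iterable[SvCall], config: SvConfig) -> list[SvCall]:
    """Threshold both samples, then subtract the normal: the somatic SV set."""
    tumor, normal = threshold_calls(calls, config)
    return subtract_normal(tumor, normal, config)
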