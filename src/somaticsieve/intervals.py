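"""Genomic interval sets backed by interval trees.

All intervals are stored 0-based half-open (BED convention). Report-layer
code converts to 1-based inclusive only when printing tables.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .errors import FormatError


class GenomeIntervals:
    """A per-chromosome collection of 0-based half-open intervals.

    Thin wrapper over :class:`intervaltree.IntervalTree` with BED I/O and the
    overlap queries the filters need.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] | None = None,
                 data: Iterable | None = None):
        self._trees: dict[str, IntervalTree] = {}
        if intervals is not None:
            data = list(data) if data is not None else None
            for i, (chrom, start, end) in enumerate(intervals):
                self.add(chrom, start, end, data[i] if data is not None else None)

    def add(self, chrom: str, start: int, end: int, data=None) -> None:
        if end <= start:
            raise FormatError(f"interval end <= start: {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, data)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position falls inside any interval (half-open)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(pos0, pos0 + 1))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval by >= 1 bp."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        """All intervals overlapping [start, end), sorted by position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end))
        return [(iv.begin, iv.end, iv.data) for iv in hits]

    def iter_intervals(self) -> Iterator[tuple[str, int, int, object]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    @classmethod
    def from_bed(cls, path: str | Path | io.TextIOBase, name_as_data: bool = True
                 ) -> "GenomeIntervals":
        """Load a BED3+ file (0-based half-open); column 4, if present, is kept as data."""
        obj = cls()
        if isinstance(path, (str, Path)):
            handle = open(path)
            close = True
        else:
            handle, close = path, False
        try:
            for ln, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"BED line {ln}: fewer than 3 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"BED line {ln}: non-integer coordinates") from exc
                if end < start:
                    raise FormatError(f"BED line {ln}: end < start")
                if end == start:
                    continue  # zero-length feature, nothing to overlap
                data = fields[3] if (name_as_data and len(fields) > 3) else None
                obj.add(fields[0], start, end, data)
        finally:
            if close:
                handle.close()
        return obj

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, data in self.iter_intervals():
                name = "" if data is None else f"\t{data}"
                fh.write(f"{chrom}\t{start}\t{end}{name}\n")


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two half-open intervals on the same chromosome.

    Returns overlap / max(len(a), len(b)); 0.0 when disjoint. A value >= 0.5
    means each interval covers at least half of the other.
    """
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])
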