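"""Genomic intervals and interval arithmetic.

All coordinates inside the package are 0-based half-open, the BED
convention.  VCF positions (1-based) are converted at the I/O boundary
with ``pos_internal = pos_vcf - 1``.  Touching intervals ([0,10) and
[10,20)) do not overlap, but book-ended intervals *merge*, matching the
``bedtools merge`` default.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Nonzero intersection length; half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalIndex:
    """Per-chromosome interval tree supporting half-open overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        idx = len(self._intervals)
        self._intervals.append(iv)
        self._trees[iv.chrom].addi(iv.start, iv.end, idx)

    def __len__(self) -> int:
        return len(self._intervals)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals with nonzero intersection with *query*,
        in insertion order."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = sorted(h.data for h in tree.overlap(query.start, query.end))
        return [self._intervals[i] for i in hits]

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return tree is not None and bool(tree.overlap(query.start, query.end))


def overlap_query(
    query: GenomicInterval, subjects: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Subjects with nonzero intersection with *query* (half-open)."""
    return IntervalIndex(subjects).overlapping(query)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge into sorted disjoint intervals covering the union of bases.

    Book-ended intervals ([0,5) and [5,8)) are merged into one, matching
    the default behaviour of ``bedtools merge``.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # book-ended merges
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_bases(intervals: Sequence[GenomicInterval]) -> int:
    """Number of distinct bases covered by the (possibly overlapping) set."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open, as on disk)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
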