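"""Genomic coordinates and the pairwise overlap engine.

All internal coordinates are 0-based half-open ([start, end), BED-style);
GTF input is converted from 1-based inclusive on read and back on write.
Overlap is strand-blind by default — TE insertions act on genes from
either strand — with an opt-in same-strand filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ContractError

__all__ = [
    "GenomicInterval",
    "OverlapRecord",
    "overlap_length",
    "find_overlaps",
    "natural_chrom_key",
]

_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A named, stranded interval: 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ContractError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ContractError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ContractError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def expanded(self, flank: int, chrom_size: int | None = None) -> "GenomicInterval":
        """Symmetric extension by ``flank`` bp, clipped to [0, chrom_size)."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_size is not None:
            end = min(end, chrom_size)
        return GenomicInterval(self.chrom, start, end, self.strand, self.name)


@dataclass(frozen=True)
class OverlapRecord:
    """One overlapping (query, subject) pair with its overlap width in bp."""

    query: GenomicInterval
    subject: GenomicInterval
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.query.chrom != self.subject.chrom:
            raise ContractError("overlapping intervals must share a chromosome")
        if self.overlap_bp <= 0:
            raise ContractError("overlap_bp must be positive")

    @property
    def query_name(self) -> str:
        return self.query.name

    @property
    def subject_name(self) -> str:
        return self.subject.name


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Width of the intersection in bp; 0 for different chromosomes or
    half-open adjacency."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def natural_chrom_key(chrom: str):
    """Sort key ordering chr2 before chr10 (numeric runs compare as ints)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple((1, int(p)) if p.isdigit() else (0, p) for p in parts if p != "")


def find_overlaps(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    min_bp: int = 1,
    same_strand: bool = False,
) -> list[OverlapRecord]:
    """Every (query, subject) pair overlapping by at least ``min_bp``.

    Uses a per-chromosome interval tree over the subjects, so the result
    is independent of input ordering; pairs are reported once, sorted by
    (chrom, query start, subject start, names).
    """
    if min_bp < 1:
        raise ContractError(f"min_bp must be >= 1, got {min_bp}")
    trees: dict[str, IntervalTree] = {}
    for s in subjects:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s)
    records = []
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            s = hit.data
            if same_strand and q.strand != s.strand:
                continue
            bp = min(q.end, s.end) - max(q.start, s.start)
            if bp >= min_bp:
                records.append(OverlapRecord(q, s, bp))
    records.sort(
        key=lambda r: (
            natural_chrom_key(r.query.chrom),
            r.query.start,
            r.subject.start,
            r.query.name,
            r.subject.name,
        )
    )
    return records
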