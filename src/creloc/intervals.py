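"""Genomic intervals: the shared currency of peaks, drops, association blocks
and CRE nominations.

All intervals are 0-based, half-open ``[start, end)`` — the BED convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally scored."""

    scaffold: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_score(self, score: float) -> "GenomicInterval":
        return GenomicInterval(self.scaffold, self.start, self.end, score)


def sort_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))


def merge_intervals(
    intervals: list[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals; intervals separated by <= ``gap``
    bp are joined.  Scores of merged members are combined by max (None-safe)."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and iv.scaffold == out[-1].scaffold and iv.start - out[-1].end <= gap:
            prev = out[-1]
            scores = [s for s in (prev.score, iv.score) if s is not None]
            out[-1] = GenomicInterval(
                prev.scaffold,
                prev.start,
                max(prev.end, iv.end),
                max(scores) if scores else None,
            )
        else:
            out.append(iv)
    return out


def intersect(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersection of two interval lists (half-open semantics).

    Output is sorted and contains one interval per overlapping input pair,
    so book-ended intervals ([0,50) vs [50,100)) produce nothing.
    """
    out = []
    for ia in sort_intervals(a):
        for ib in b:
            if ia.overlaps(ib):
                out.append(
                    GenomicInterval(
                        ia.scaffold,
                        max(ia.start, ib.start),
                        min(ia.end, ib.end),
                    )
                )
    return sort_intervals(out)
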