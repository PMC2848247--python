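"""Genomic interval algebra shared across the package.

All coordinates are 0-based half-open. Region sets are kept sorted by
(chrom, start); most operations require sorted, non-overlapping input
and preserve that invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicRegion",
    "sort_regions",
    "merge_regions",
    "complement_regions",
    "total_length",
    "overlap_statistics",
]


@dataclass
class GenomicRegion:
    """Half-open interval with a class label and optional score.

    Labels in this package: ``binding``, ``x_specific``, ``consensus``,
    ``HAS``, ``planted``.
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def sort_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))


def merge_regions(
    regions: Iterable[GenomicRegion],
    max_gap: int = 0,
    strict_less: bool = False,
    label: str | None = None,
) -> list[GenomicRegion]:
    """Merge regions on the same chromosome that are close enough.

    With ``strict_less=False`` two regions merge when the gap between them
    is <= max_gap (max_gap=0 merges overlapping-or-abutting regions only).
    With ``strict_less=True`` they merge when gap < max_gap, matching the
    "separated by less than" consensus rule.

    The merged region's score is the max of the merged scores (None if all
    are None).
    """
    out: list[GenomicRegion] = []
    for r in sort_regions(regions):
        if out and out[-1].chrom == r.chrom:
            gap = r.start - out[-1].end
            close = gap < max_gap if strict_less else gap <= max_gap
            if close:
                prev = out[-1]
                scores = [s for s in (prev.score, r.score) if s is not None]
                out[-1] = GenomicRegion(
                    prev.chrom,
                    prev.start,
                    max(prev.end, r.end),
                    label if label is not None else prev.label,
                    max(scores) if scores else None,
                )
                continue
        out.append(
            GenomicRegion(
                r.chrom, r.start, r.end,
                label if label is not None else r.label, r.score,
            )
        )
    return out


def complement_regions(
    regions: Sequence[GenomicRegion], chrom: str, chrom_length: int, label: str = ""
) -> list[GenomicRegion]:
    """Intervals of ``chrom`` not covered by ``regions`` (sorted, non-ovl)."""
    out = []
    pos = 0
    for r in regions:
        if r.chrom != chrom:
            continue
        if r.start > pos:
            out.append(GenomicRegion(chrom, pos, r.start, label))
        pos = max(pos, r.end)
    if pos < chrom_length:
        out.append(GenomicRegion(chrom, pos, chrom_length, label))
    return out


def total_length(regions: Iterable[GenomicRegion]) -> int:
    return sum(len(r) for r in regions)


def overlap_statistics(
    regions_a: Sequence[GenomicRegion], regions_b: Sequence[GenomicRegion]
) -> tuple[int, int, float, float]:
    """Overlap statistics between two sorted region sets.

    Returns ``(n_a_overlapping, n_b_positive, mean_a_per_positive_b,
    fraction_b_positive)`` where overlap means at least one shared base
    pair, computed with a single two-pointer sweep per chromosome.
    """
    a_hit = np.zeros(len(regions_a), dtype=bool)
    b_count = np.zeros(len(regions_b), dtype=int)

    # group indices per chromosome (inputs sorted by (chrom, start))
    def by_chrom(regions):
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(regions):
            groups.setdefault(r.chrom, []).append(i)
        return groups

    ga, gb = by_chrom(regions_a), by_chrom(regions_b)
    for chrom, ia in ga.items():
        ib = gb.get(chrom, [])
        j0 = 0
        for i in ia:
            ra = regions_a[i]
            # advance past b regions that end before ra starts
            while j0 < len(ib) and regions_b[ib[j0]].end <= ra.start:
                j0 += 1
            j = j0
            while j < len(ib) and regions_b[ib[j]].start < ra.end:
                # regions within a set may nest; re-check the right edge
                if regions_b[ib[j]].end > ra.start:
                    a_hit[i] = True
                    b_count[ib[j]] += 1
                j += 1
    n_b_positive = int((b_count > 0).sum())
    mean_per_b = float(b_count[b_count > 0].mean()) if n_b_positive else 0.0
    frac_b = n_b_positive / len(regions_b) if len(regions_b) else 0.0
    return int(a_hit.sum()), n_b_positive, mean_per_b, frac_b
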