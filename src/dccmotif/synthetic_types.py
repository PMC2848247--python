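"""Dataclasses for annotation-level inputs: gene models and aligned
ortholog pairs. Kept in their own module so the statistics modules can
type against them without importing the generators."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """A gene with ordered CDS segments.

    ``cds_segments`` are 0-based half-open genomic intervals ordered
    5'->3' in the gene's reading direction (for minus-strand genes the
    first segment has the highest coordinates).  Total CDS length must
    be divisible by 3.  ``score`` optionally carries a mean binding
    signal used for gene filtering.
    """

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        total = sum(e - s for s, e in self.cds_segments)
        if total % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OrthologPair:
    """A gapless-or-gapped pairwise alignment of a motif site plus flanks.

    ``site_start``/``site_end`` are the site's half-open interval in
    query coordinates (0-based within the aligned query, gaps excluded).
    """

    name: str
    query: str
    subject: str
    site_start: int
    site_end: int
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if len(self.query) != len(self.subject):
            raise ValueError("aligned sequences must have equal length")
        if not (0 <= self.site_start <= self.site_end):
            raise ValueError("invalid site interval")
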