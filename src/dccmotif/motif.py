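"""Positional frequency-matrix construction and genome scanning.

The matrix score of a window is the plain sum, over positions, of the
count of the window's base in that column (no log-odds, no background
model); the maximum score is the sum of the per-column maxima.  Windows
scoring at least a configurable fraction of the maximum (default 90%)
on either strand are hits; overlapping or abutting hits merge into
sites, which is why internally repetitive motifs yield sites longer
than the matrix width.

The package ships the [G(CG)N]4 consensus as a built-in default matrix
(12 columns, weight split equally among the bases each degenerate
symbol allows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiling import encode_sequence
from .intervals import GenomicRegion

__all__ = [
    "FrequencyMatrix",
    "MatrixScanConfig",
    "MotifSite",
    "build_frequency_matrix",
    "max_score",
    "window_score",
    "scan_sequence",
    "pattern_to_matrix",
    "default_matrix",
    "CONSENSUS_PATTERN",
]

BASE_ORDER = "ACGT"
# complement permutation of the A,C,G,T rows
_COMPL = np.array([3, 2, 1, 0])

DEGENERATE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "S": "CG", "N": "ACGT",
}

#: the repetitive consensus: four repeats of G, C-or-G, any base
CONSENSUS_PATTERN = "GSN" * 4


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide counts from n_sequences aligned motifs.

    ``counts`` has shape (4, width), rows in A,C,G,T order; every column
    sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, width)")
        if self.counts.shape[1] < 1:
            raise ValueError("matrix width must be >= 1")
        if not np.allclose(self.counts.sum(axis=0), self.n_sequences):
            raise ValueError("every column must sum to n_sequences")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "FrequencyMatrix":
        return FrequencyMatrix(self.counts[_COMPL][:, ::-1], self.n_sequences)

    def to_tsv(self) -> str:
        lines = []
        for i, base in enumerate(BASE_ORDER):
            vals = "\t".join(f"{v:g}" for v in self.counts[i])
            lines.append(f"{base}\t{vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "FrequencyMatrix":
        rows = {}
        for line in text.strip().splitlines():
            parts = line.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
        counts = np.array([rows[b] for b in BASE_ORDER])
        return cls(counts, int(round(counts.sum(axis=0)[0])))


@dataclass
class MatrixScanConfig:
    cutoff_fraction: float = 0.90
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_fraction <= 1):
            raise ValueError("cutoff_fraction must be in (0, 1]")


@dataclass
class MotifSite:
    """A merged run of qualifying scan windows.

    ``strand`` is '+', '-', or 'merged' when hits on both strands were
    merged into one site; ``score`` is the best window score inside.
    """

    chrom: str
    start: int
    end: int
    strand: str
    score: float

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def as_region(self, label: str = "site") -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end, label, self.score)


def build_frequency_matrix(sequences: list[str]) -> FrequencyMatrix:
    """Count the base at each position across equal-length ACGT strings."""
    if not sequences:
        raise ValueError("need at least one sequence")
    width = len(sequences[0])
    counts = np.zeros((4, width), dtype=np.float64)
    for seq in sequences:
        if len(seq) != width:
            raise ValueError("sequences must all have the same length")
        codes = encode_sequence(seq)
        if (codes < 0).any():
            raise ValueError(f"ambiguous base in {seq!r}")
        counts[codes, np.arange(width)] += 1
    return FrequencyMatrix(counts, len(sequences))


def max_score(matrix: FrequencyMatrix) -> float:
    """Sum over columns of the most frequent nucleotide's count."""
    return float(matrix.counts.max(axis=0).sum())


def window_score(matrix: FrequencyMatrix, window: str) -> float:
    """Sum of counts[pos][window[pos]]; ambiguous bases contribute 0."""
    if len(window) != matrix.width:
        raise ValueError("window length must equal matrix width")
    codes = encode_sequence(window)
    ok = codes >= 0
    return float(matrix.counts[codes[ok], np.nonzero(ok)[0]].sum())


def _scores_one_strand(
    codes: np.ndarray, counts: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    n, width = codes.size, counts.shape[1]
    scores = np.zeros(n - width + 1, dtype=np.float64)
    c = np.where(codes < 0, 0, codes)
    for i in range(width):
        scores += counts[c[i : n - width + 1 + i], i]
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    sequence: str,
    matrix: FrequencyMatrix,
    config: MatrixScanConfig | None = None,
    chrom: str = "seq",
) -> list[MotifSite]:
    """All merged motif sites of ``sequence`` above the score cutoff.

    Minus-strand hits are reported in plus-strand coordinates; windows
    containing ambiguous bases are skipped entirely.
    """
    config = config or MatrixScanConfig()
    width = matrix.width
    if len(sequence) < width:
        return []
    codes = encode_sequence(sequence)
    n = codes.size
    bad = (codes < 0).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[width:] - cs[:-width]) == 0

    cutoff = config.cutoff_fraction * max_score(matrix)
    plus = _scores_one_strand(codes, matrix.counts, valid)
    hit_plus = plus >= cutoff
    if config.both_strands:
        rc = matrix.reverse_complement()
        minus = _scores_one_strand(codes, rc.counts, valid)
        hit_minus = minus >= cutoff
    else:
        minus = np.full_like(plus, -np.inf)
        hit_minus = np.zeros_like(hit_plus)

    positions = np.nonzero(hit_plus | hit_minus)[0]
    sites: list[MotifSite] = []
    for p in positions:
        p = int(p)
        on_plus, on_minus = bool(hit_plus[p]), bool(hit_minus[p])
        best = max(
            plus[p] if on_plus else -np.inf,
            minus[p] if on_minus else -np.inf,
        )
        strand = "merged" if (on_plus and on_minus) else ("+" if on_plus else "-")
        if sites and p <= sites[-1].end:  # overlap or abut -> merge
            prev = sites[-1]
            new_strand = prev.strand if prev.strand == strand else "merged"
            sites[-1] = MotifSite(
                chrom, prev.start, p + width, new_strand,
                max(prev.score, float(best)),
            )
        else:
            sites.append(MotifSite(chrom, p, p + width, strand, float(best)))
    return sites


def pattern_to_matrix(pattern: str) -> FrequencyMatrix:
    """Frequency matrix of a degenerate pattern over {A,C,G,T,S,N}.

    Each column's weight (common denominator 4) is split equally among
    the bases the symbol allows, so any exact pattern match scores the
    matrix maximum.
    """
    counts = np.zeros((4, len(pattern)), dtype=np.float64)
    for j, sym in enumerate(pattern.upper()):
        allowed = DEGENERATE.get(sym)
        if allowed is None:
            raise ValueError(f"unsupported pattern symbol {sym!r}")
        w = 4 / len(allowed)
        for b in allowed:
            counts[BASE_ORDER.index(b), j] = w
    return FrequencyMatrix(counts, 4)


def default_matrix() -> FrequencyMatrix:
    """The built-in [G(CG)N]4 consensus matrix (width 12)."""
    return pattern_to_matrix(CONSENSUS_PATTERN)
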