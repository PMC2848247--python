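"""Degenerate codon classes of the repetitive motif and coding-region
statistics.

Read in the three frames of each strand, the [G(CG)N]4 consensus breaks
into six degenerate codon classes of eight codons each: G(CG)N, (CG)NG,
NG(CG) and, on the reverse complement, N(CG)C, (CG)CN, CN(CG).  The
classes differ strongly in how many distinct amino acids they can
encode (from 2 for G(CG)N up to 8 for (CG)NG), which is the quantity
the analysis contrasts between motif codons inside and outside binding
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .intervals import GenomicRegion
from .motif import DEGENERATE, MotifSite
from .synthetic_types import GeneModel

__all__ = [
    "CodonClassDef",
    "CodonAssignment",
    "expand_codon_class",
    "six_classes",
    "map_sites_to_codons",
    "class_frequency_table",
    "compare_class_proportions",
    "codon_usage_ratio",
    "compound_ratio",
    "pattern_run_frequency",
    "codon_matches_pattern",
    "PATTERN_DISPLAY",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: conventional display names of the six class patterns
PATTERN_DISPLAY = {
    "GSN": "G(CG)N",
    "SNG": "(CG)NG",
    "NGS": "NG(CG)",
    "NSC": "N(CG)C",
    "SCN": "(CG)CN",
    "CNS": "CN(CG)",
}

#: assignment priority for codons matching several classes
#: (observed-frequency order, most common class first)
CLASS_PRIORITY = ("SNG", "CNS", "NSC", "NGS", "GSN", "SCN")


def translate_codon(codon: str) -> str:
    """Three-letter-free one-shot translation; '*' for stop codons."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


@dataclass
class CodonClassDef:
    """A degenerate codon pattern with its expansion.

    ``codons`` enumerates every concrete codon; ``amino_acids`` has one
    entry per codon (a multiset: repeated amino acids are meaningful).
    """

    pattern: str
    codons: tuple[str, ...]
    amino_acids: tuple[str, ...]
    contains_stop: bool = False

    @property
    def display_name(self) -> str:
        return PATTERN_DISPLAY.get(self.pattern, self.pattern)

    @property
    def distinct_amino_acids(self) -> frozenset[str]:
        return frozenset(self.amino_acids)

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


def expand_codon_class(pattern: str) -> CodonClassDef:
    """Enumerate the codons and encoded amino acids of a 3-symbol
    degenerate pattern over {A,C,G,T,S,N} (S = C or G)."""
    if len(pattern) != 3:
        raise ValueError("codon pattern must have exactly 3 symbols")
    choices = []
    for sym in pattern.upper():
        allowed = DEGENERATE.get(sym)
        if allowed is None:
            raise ValueError(f"unsupported pattern symbol {sym!r}")
        choices.append(allowed)
    codons = tuple("".join(c) for c in product(*choices))
    aas = tuple(translate_codon(c) for c in codons)
    return CodonClassDef(pattern.upper(), codons, aas, "*" in aas)


def six_classes() -> list[CodonClassDef]:
    """The six codon classes: three frames of [GSN]n and of its reverse
    complement [NSC]n."""
    return [expand_codon_class(p) for p in ("GSN", "SNG", "NGS", "NSC", "SCN", "CNS")]


def codon_matches_pattern(codon: str, pattern: str) -> bool:
    return len(codon) == len(pattern) and all(
        b in DEGENERATE[s] for b, s in zip(codon.upper(), pattern.upper())
    )


@dataclass
class CodonAssignment:
    """One complete codon emitted by a motif site inside a CDS."""

    site: MotifSite
    gene: str
    codon: str
    codon_class: str | None  # display name of the primary class, or None
    classes: tuple[str, ...]  # display names of every matching class
    frame_offset: int  # codon start relative to site start, mod 3
    genomic_start: int = 0  # lowest genomic coordinate of the codon
    inside_binding: bool = False
    ambiguous_gene: bool = False  # site overlapped several genes


def _cds_positions(gene: GeneModel) -> np.ndarray:
    """Genomic position of every CDS base, in reading (5'->3') order."""
    segs = gene.cds_segments or [(gene.start, gene.end)]
    parts = []
    for s, e in segs:
        arr = np.arange(s, e, dtype=np.int64)
        if gene.strand == "-":
            arr = arr[::-1]
        parts.append(arr)
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def map_sites_to_codons(
    sites: Sequence[MotifSite],
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    binding_regions: Sequence[GenomicRegion] | None = None,
) -> list[CodonAssignment]:
    """Complete in-frame codons covered by motif sites within CDS.

    For every site overlapping a gene's CDS, the codons whose three
    bases all fall inside the site are emitted (in the gene's annotated
    reading frame; minus-strand genes are read on the reverse
    complement).  Partial codons at either edge are discarded.  A site
    overlapping several genes contributes codons to each, flagged
    ambiguous.  ``inside_binding`` marks sites sharing >= 1 bp with a
    binding region.
    """
    binding_regions = binding_regions or []
    out: list[CodonAssignment] = []
    # per-gene CDS maps, grouped by chromosome
    gene_maps = [(g, _cds_positions(g)) for g in genes]

    for site in sites:
        inside = any(
            b.chrom == site.chrom and b.start < site.end and site.start < b.end
            for b in binding_regions
        )
        overlapping = [
            (g, pos) for g, pos in gene_maps
            if g.chrom == site.chrom and g.start < site.end and site.start < g.end
        ]
        ambiguous = len(overlapping) > 1
        seq = genome[site.chrom]
        for gene, pos in overlapping:
            in_site = (pos >= site.start) & (pos < site.end)
            n_codons = pos.size // 3
            for j in range(n_codons):
                trip = slice(3 * j, 3 * j + 3)
                if not in_site[trip].all():
                    continue
                bases = [seq[p] for p in pos[trip]]
                codon = "".join(bases).upper()
                if gene.strand == "-":
                    codon = codon.translate(_COMPLEMENT)
                if any(b not in "ACGT" for b in codon):
                    continue
                matches = tuple(
                    PATTERN_DISPLAY[p]
                    for p in CLASS_PRIORITY
                    if codon_matches_pattern(codon, p)
                )
                first_base = pos[trip.start]
                if gene.strand == "-":
                    offset = (site.end - 1 - int(first_base)) % 3
                else:
                    offset = (int(first_base) - site.start) % 3
                out.append(
                    CodonAssignment(
                        site,
                        gene.name,
                        codon,
                        matches[0] if matches else None,
                        matches,
                        offset,
                        int(pos[trip].min()),
                        inside,
                        ambiguous,
                    )
                )
    return out


def class_frequency_table(assignments: Sequence[CodonAssignment]):
    """Counts (and within-partition percentages) per codon class,
    split inside/outside binding regions."""
    import pandas as pd

    names = [PATTERN_DISPLAY[p] for p in CLASS_PRIORITY] + ["none"]
    counts = {name: {"inside": 0, "outside": 0} for name in names}
    for a in assignments:
        key = a.codon_class if a.codon_class is not None else "none"
        counts[key]["inside" if a.inside_binding else "outside"] += 1
    df = pd.DataFrame(counts).T.loc[names]
    for part in ("inside", "outside"):
        total = df[part].sum()
        df[f"{part}_pct"] = 100.0 * df[part] / total if total else 0.0
    return df


def compare_class_proportions(
    count_in: tuple[int, int], count_out: tuple[int, int]
) -> tuple[float, float, int]:
    """Pearson chi-square (df=1, no continuity correction) comparing a
    class's share between two partitions.

    Arguments are (class hits, total codons) per partition.  Returns
    (statistic, p-value, df); identical proportions give statistic 0.
    """
    (hit_in, tot_in), (hit_out, tot_out) = count_in, count_out
    if tot_in <= 0 or tot_out <= 0:
        raise ValueError("totals must be positive")
    table = np.array(
        [[hit_in, tot_in - hit_in], [hit_out, tot_out - hit_out]], dtype=float
    )
    if (table < 0).any():
        raise ValueError("hits cannot exceed totals")
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn("expected cell count < 1; chi-square may be unreliable")
    if (expected == 0).any():
        return 0.0, 1.0, 1
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, 1


def _codon_counts(cds_set: Sequence[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cds in cds_set:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3].upper()
            if all(b in "ACGT" for b in codon):
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage_ratio(
    cds_set_a: Sequence[str],
    cds_set_b: Sequence[str],
    codon: str,
    pseudocount: float | None = None,
) -> float:
    """Relative-frequency ratio of one codon between two CDS sets."""
    if not cds_set_a or not cds_set_b:
        raise ValueError("both CDS sets must be non-empty")
    ca, cb = _codon_counts(cds_set_a), _codon_counts(cds_set_b)
    codon = codon.upper()
    ta, tb = sum(ca.values()), sum(cb.values())
    nb = cb.get(codon, 0)
    if nb == 0 and pseudocount is None:
        raise ValueError(
            f"codon {codon} absent from set b; pass pseudocount= to regularize"
        )
    fa = ca.get(codon, 0) / ta
    fb = (nb if nb else pseudocount) / tb
    return fa / fb


def compound_ratio(ratio: float, n_codons: int = 6) -> float:
    """Enrichment of a run of ``n_codons`` identical codons implied by a
    single-codon usage ratio (ratio ** n)."""
    return ratio**n_codons


def pattern_run_frequency(
    cds_set: Sequence[str], class_pattern: str, run_length: int = 4
) -> float:
    """Fraction of windows of ``run_length`` consecutive in-frame codons
    that all match the class pattern.

    CDS shorter than ``run_length`` codons contribute no windows.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    total = matches = 0
    for cds in cds_set:
        codons = [
            cds[i : i + 3].upper()
            for i in range(0, len(cds) - len(cds) % 3, 3)
        ]
        n_win = len(codons) - run_length + 1
        for i in range(max(n_win, 0)):
            total += 1
            if all(
                codon_matches_pattern(c, class_pattern)
                for c in codons[i : i + run_length]
            ):
                matches += 1
    return matches / total if total else 0.0
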