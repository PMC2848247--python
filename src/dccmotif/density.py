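"""Motif density, spacing, sliding-window and gene-relative statistics.

Densities are sites per megabase of an interval set, with a standard
error estimated over fixed-length fragments of the set's base pairs
(2 Mb for chromosome-scale input).  A site belongs to an interval when
its midpoint falls inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicRegion
from .motif import MotifSite
from .synthetic_types import GeneModel  # re-exported dataclass, see module

__all__ = [
    "DensityConfig",
    "DensityProfile",
    "Anchor",
    "SpacingSummary",
    "site_density",
    "spacing_distribution",
    "sliding_density_profile",
    "region_centers",
    "random_anchors",
    "gene_relative_positions",
    "uniformity_test",
]


@dataclass
class DensityConfig:
    fragment_length: int = 2_000_000
    window: int = 500
    max_offset: int = 5000
    anchors_per_arm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fragment_length", "window", "max_offset", "anchors_per_arm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class Anchor(NamedTuple):
    """A sliding-window start point.

    ``orientation`` is +1 when increasing coordinates point toward the
    centromere and -1 when they point toward the telomere; it flips the
    sign of profile offsets so that negative offsets always point
    telomere-ward.
    """

    chrom: str
    position: int
    orientation: int = 1


@dataclass
class DensityProfile:
    offsets: np.ndarray
    mean_density: np.ndarray
    n_anchors: np.ndarray


class SpacingSummary(NamedTuple):
    gaps: np.ndarray  # sorted end-to-start distances
    median: float
    fraction_below: float


def _site_centers(sites: Sequence[MotifSite]) -> dict[str, np.ndarray]:
    centers: dict[str, list[int]] = {}
    for s in sites:
        centers.setdefault(s.chrom, []).append(s.center)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in centers.items()}


def site_density(
    sites: Sequence[MotifSite],
    regions: Sequence[GenomicRegion],
    config: DensityConfig | None = None,
) -> tuple[float, float]:
    """Sites/Mb over a region set, with a fragment-based standard error.

    The region set's base pairs are concatenated (coordinate order) and
    partitioned into fragments of ``fragment_length``; the SE is the
    standard error of the per-fragment densities.  Sites are assigned by
    midpoint.  Raises on an empty region set.
    """
    config = config or DensityConfig()
    total_bp = sum(len(r) for r in regions)
    if total_bp == 0:
        raise ValueError("region set covers zero base pairs")
    centers = _site_centers(sites)

    # offset of each in-region site midpoint in the concatenated bp
    offsets: list[int] = []
    cum = 0
    for r in regions:
        c = centers.get(r.chrom)
        if c is not None:
            inside = c[(c >= r.start) & (c < r.end)]
            offsets.extend((cum + (inside - r.start)).tolist())
        cum += len(r)
    n_sites = len(offsets)
    density = n_sites / total_bp * 1e6

    frag = config.fragment_length
    n_frag = int(np.ceil(total_bp / frag))
    frag_counts = np.bincount(
        np.asarray(offsets, dtype=np.int64) // frag if n_sites else
        np.empty(0, dtype=np.int64),
        minlength=n_frag,
    )
    frag_lengths = np.full(n_frag, frag, dtype=np.float64)
    if total_bp % frag:
        frag_lengths[-1] = total_bp % frag
    frag_density = frag_counts / frag_lengths * 1e6
    se = (
        float(frag_density.std(ddof=1) / np.sqrt(n_frag)) if n_frag >= 2 else 0.0
    )
    return float(density), se


def spacing_distribution(
    sites: Sequence[MotifSite], threshold: int = 1000
) -> SpacingSummary:
    """End-to-start distances between consecutive sites, per chromosome.

    Returns sorted gaps, their median, and the fraction below
    ``threshold``; fewer than two sites on every chromosome yields an
    empty distribution.
    """
    by_chrom: dict[str, list[MotifSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    gaps: list[int] = []
    for group in by_chrom.values():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            gaps.append(b.start - a.end)
    arr = np.sort(np.asarray(gaps, dtype=np.int64))
    if arr.size == 0:
        return SpacingSummary(arr, float("nan"), float("nan"))
    return SpacingSummary(
        arr, float(np.median(arr)), float((arr < threshold).mean())
    )


def sliding_density_profile(
    sites: Sequence[MotifSite],
    anchors: Sequence[Anchor],
    config: DensityConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> DensityProfile:
    """Mean motif density in windows slid away from anchor points.

    For each signed offset d in [-max_offset, max_offset], a window of
    ``config.window`` bp is placed downstream (d >= 0: [pos+d, pos+d+w))
    or upstream (d < 0: [pos+d-w, pos+d)) of each anchor after applying
    the anchor's orientation; the profile is the anchor-mean of site
    midpoints per window, scaled to sites/Mb.  Windows extending past a
    chromosome end (when ``chrom_lengths`` is given) are dropped from
    the mean at that offset.
    """
    config = config or DensityConfig()
    w = config.window
    offsets = np.arange(-config.max_offset, config.max_offset + 1, dtype=np.int64)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    centers = _site_centers(sites)
    empty = np.empty(0, dtype=np.int64)
    for anchor in anchors:
        c = centers.get(anchor.chrom, empty)
        eff = offsets * anchor.orientation
        lo = np.where(eff >= 0, anchor.position + eff,
                      anchor.position + eff - w)
        hi = lo + w
        ok = lo >= 0
        if chrom_lengths is not None:
            ok &= hi <= chrom_lengths[anchor.chrom]
        n_in = np.searchsorted(c, hi, side="left") - np.searchsorted(
            c, lo, side="left"
        )
        sums[ok] += n_in[ok] / w * 1e6
        counts[ok] += 1
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return DensityProfile(offsets, mean, counts)


def region_centers(
    regions: Sequence[GenomicRegion],
    orientation: dict[str, int] | int = 1,
) -> list[Anchor]:
    """Center nucleotide of each region as an anchor.

    ``orientation`` may be a single value or a per-chromosome map."""
    def orient(chrom: str) -> int:
        if isinstance(orientation, dict):
            return orientation.get(chrom, 1)
        return orientation

    return [Anchor(r.chrom, r.center, orient(r.chrom)) for r in regions]


def random_anchors(
    chrom_lengths: dict[str, int],
    anchors_per_arm: int,
    seed: int | np.random.Generator = 0,
) -> list[Anchor]:
    """Uniformly sampled anchor positions, ``anchors_per_arm`` per chromosome."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    anchors = []
    for chrom in sorted(chrom_lengths):
        for pos in rng.integers(0, chrom_lengths[chrom], size=anchors_per_arm):
            anchors.append(Anchor(chrom, int(pos), 1))
    return anchors


def gene_relative_positions(
    sites: Sequence[MotifSite],
    genes: Sequence[GeneModel],
    min_gene_length: int = 2000,
    min_signal: float | None = None,
) -> list[float]:
    """Relative position of site midpoints along qualifying genes.

    Genes must be longer than ``min_gene_length`` and contain at least
    one site; with ``min_signal`` set, also carry a score above it
    (mean binding signal from the annotation).  The value is
    (site midpoint - 5' gene end) / gene length, so it runs 5'->3' and
    mirrored placements on opposite strands give identical values.
    """
    centers = _site_centers(sites)
    values: list[float] = []
    empty = np.empty(0, dtype=np.int64)
    for gene in genes:
        length = gene.end - gene.start
        if length <= min_gene_length:
            continue
        if min_signal is not None and (
            gene.score is None or gene.score <= min_signal
        ):
            continue
        c = centers.get(gene.chrom, empty)
        inside = c[(c >= gene.start) & (c < gene.end)]
        for pos in inside:
            if gene.strand == "-":
                values.append(float(gene.end - 1 - pos) / length)
            else:
                values.append(float(pos - gene.start) / length)
    return values


def uniformity_test(
    values: Sequence[float], trim: float = 0.05
) -> tuple[float, float]:
    """One-sample KS test of positional uniformity on a trimmed interval.

    Values within [trim, 1-trim] are rescaled to [0, 1] and tested
    against the uniform distribution (the trim excludes the depleted
    gene extremes).  Requires at least 5 values.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 5:
        raise ValueError("need at least 5 values for the uniformity test")
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    kept = arr[(arr >= trim) & (arr <= 1 - trim)]
    if kept.size < 5:
        raise ValueError("fewer than 5 values remain after trimming")
    rescaled = (kept - trim) / (1 - 2 * trim) if trim else kept
    stat, p = stats.kstest(rescaled, "uniform")
    return float(stat), float(p)
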