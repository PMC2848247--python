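"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the data regime of the original analysis: a "target" chromosome
carrying designated motif-enriched regions over a uniform i.i.d.
background, a comparison chromosome with the outside motif density
only, tiling-array probe tracks (probes every 50-100 nt, elevated
signal inside the designated regions), simple single-CDS gene models,
and pairwise ortholog alignments in which site and flank columns mutate
at separate substitution rates.

Every generator is a pure function of its configuration and seed;
independent streams are derived from the seed per product so that, for
example, the probe track does not change when the gene count does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .intervals import GenomicRegion, complement_regions, sort_regions
from .motif import DEGENERATE, MotifSite
from .synthetic_types import GeneModel, OrthologPair

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "generate_genome_pair",
    "generate_probe_track",
    "generate_gene_models",
    "generate_ortholog_pairs",
]

# per-product RNG stream ids
_STREAM_GENOME = 1
_STREAM_PROBES = 2
_STREAM_GENES = 3
_STREAM_ORTHOLOGS = 4

TARGET_CHROM = "chrT"
BACKGROUND_CHROM = "chrB"


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic inputs.

    Densities are motif instances per Mb; the inside/outside pair
    (1500/600) mirrors the contrast between binding regions and the
    chromosomal background; probe spacing 50-100 nt and region length
    near 4 kb match tiling-array geometry and typical binding-region
    size; substitution rates 0.12/0.15 give the site/flank identity
    contrast of a distant-species comparison.

    The background is i.i.d. with an AT-biased composition
    (gc_fraction 0.30) so that chance matches to the GC-rich consensus
    (~70 sites/Mb at the default 90% scan cutoff) stay an order of
    magnitude below the planted densities and the planted densities
    remain the effective truth; the composition is configurable.
    """

    seed: int = 0
    target_length: int = 400_000
    background_length: int = 400_000
    planted_region_count: int = 10
    planted_region_length: int = 4000
    planted_motif: str = "GSN" * 4
    planted_density_inside: float = 1500.0
    planted_density_outside: float = 600.0
    # regions must sit farther apart than the caller's 1 kb merge rule,
    # otherwise the planted truth is ill-defined under region calling
    min_region_separation: int = 2000
    probe_spacing_min: int = 50
    probe_spacing_max: int = 100
    signal_inside_mean: float = 3.0
    signal_outside_mean: float = 0.0
    signal_sd: float = 0.3
    gene_count: int = 50
    site_sub_rate: float = 0.12
    flank_sub_rate: float = 0.15
    gc_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0 <= self.site_sub_rate < 1 and 0 <= self.flank_sub_rate < 1):
            raise ValueError("substitution rates must be in [0, 1)")
        if self.probe_spacing_min > self.probe_spacing_max:
            raise ValueError("probe_spacing_min > probe_spacing_max")
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.planted_density_inside < 0 or self.planted_density_outside < 0:
            raise ValueError("densities must be >= 0")
        for sym in self.planted_motif:
            if sym.upper() not in DEGENERATE:
                raise ValueError(f"unsupported motif symbol {sym!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticGenome:
    """Generated chromosome pair plus ground truth."""

    target: str
    background: str
    regions: list[GenomicRegion]
    planted_sites: list[GenomicRegion]
    config: SimulationConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {
            TARGET_CHROM: len(self.target),
            BACKGROUND_CHROM: len(self.background),
        }

    def sequences(self) -> dict[str, str]:
        return {TARGET_CHROM: self.target, BACKGROUND_CHROM: self.background}


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator,
    count: int,
    item_length: int,
    domain_length: int,
    separation: int = 0,
    max_tries_per_item: int = 1000,
) -> list[int]:
    """Start positions inside [0, domain_length), pairwise separated by
    at least ``separation`` bp; overlapping draws are redrawn."""
    if count * (item_length + separation) > domain_length + separation:
        raise ValueError(
            f"cannot pack {count} items of {item_length} bp into "
            f"{domain_length} bp"
        )
    placed: list[int] = []
    for _ in range(count):
        for _ in range(max_tries_per_item):
            start = int(rng.integers(0, domain_length - item_length + 1))
            if all(
                start + item_length + separation <= s
                or s + item_length + separation <= start
                for s in placed
            ):
                placed.append(start)
                break
        else:
            raise ValueError("packing failed; domain too crowded")
    return sorted(placed)


def _concrete_motif(rng: np.random.Generator, pattern: str) -> bytes:
    """A concrete instance: each degenerate symbol sampled uniformly
    from the bases it allows."""
    return bytes(
        ord(DEGENERATE[s.upper()][rng.integers(len(DEGENERATE[s.upper()]))])
        for s in pattern
    )


def _implant(
    rng: np.random.Generator,
    seq: np.ndarray,
    intervals: Sequence[tuple[int, int]],
    density_per_mb: float,
    pattern: str,
    chrom: str,
    max_tries_per_site: int = 200,
) -> list[GenomicRegion]:
    """Implant Poisson-distributed motif instances into intervals.

    Instances never overlap each other and lie entirely within one
    interval, keeping the truth density well-defined.
    """
    m = len(pattern)
    sites: list[GenomicRegion] = []
    for lo, hi in intervals:
        span = hi - lo
        if span < m:
            continue
        n = int(rng.poisson(density_per_mb * span / 1e6))
        occupied: list[int] = []
        for _ in range(n):
            for _ in range(max_tries_per_site):
                start = lo + int(rng.integers(0, span - m + 1))
                if all(start + m <= s or s + m <= start for s in occupied):
                    occupied.append(start)
                    inst = _concrete_motif(rng, pattern)
                    seq[start : start + m] = np.frombuffer(inst, dtype="S1")
                    sites.append(
                        GenomicRegion(chrom, start, start + m, "planted")
                    )
                    break
            # a crowded interval silently drops the excess instance;
            # at the default densities this is vanishingly rare
    return sites


def generate_genome_pair(config: SimulationConfig) -> SyntheticGenome:
    """Target chromosome with motif-enriched regions + background chromosome.

    Motif instances are implanted at ``planted_density_inside`` within
    the designated regions and ``planted_density_outside`` elsewhere on
    the target and across the whole background chromosome.
    """
    if config.target_length < 10 * config.planted_region_length:
        raise ValueError("target_length must be >= 10x planted_region_length")
    rng = config.rng(_STREAM_GENOME)
    starts = _place_nonoverlapping(
        rng,
        config.planted_region_count,
        config.planted_region_length,
        config.target_length,
        separation=config.min_region_separation,
    )
    regions = [
        GenomicRegion(
            TARGET_CHROM, s, s + config.planted_region_length, "planted"
        )
        for s in starts
    ]
    target = _random_bases(rng, config.target_length, config.gc_fraction)
    background = _random_bases(rng, config.background_length, config.gc_fraction)

    inside = [(r.start, r.end) for r in regions]
    outside = [
        (r.start, r.end)
        for r in complement_regions(regions, TARGET_CHROM, config.target_length)
    ]
    sites = _implant(
        rng, target, inside, config.planted_density_inside,
        config.planted_motif, TARGET_CHROM,
    )
    sites += _implant(
        rng, target, outside, config.planted_density_outside,
        config.planted_motif, TARGET_CHROM,
    )
    _implant(
        rng, background, [(0, config.background_length)],
        config.planted_density_outside, config.planted_motif, BACKGROUND_CHROM,
    )
    return SyntheticGenome(
        target=target.tobytes().decode("ascii"),
        background=background.tobytes().decode("ascii"),
        regions=regions,
        planted_sites=sort_regions(sites),
        config=config,
    )


def generate_probe_track(
    regions: Sequence[GenomicRegion],
    config: SimulationConfig,
    chrom: str = TARGET_CHROM,
    chrom_length: int | None = None,
) -> list[tuple[str, int, float]]:
    """Tiling-array probe records (chrom, 0-based position, signal).

    Successive probe spacings are uniform in [spacing_min, spacing_max];
    signal is Normal(inside mean, sd) for probes inside a region and
    Normal(outside mean, sd) elsewhere.
    """
    regions = sort_regions(regions)
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("regions must be sorted and non-overlapping")
    if chrom_length is None:
        chrom_length = config.target_length
    rng = config.rng(_STREAM_PROBES)
    starts = np.array([r.start for r in regions if r.chrom == chrom])
    ends = np.array([r.end for r in regions if r.chrom == chrom])
    probes: list[tuple[str, int, float]] = []
    pos = int(rng.integers(config.probe_spacing_min, config.probe_spacing_max + 1))
    while pos < chrom_length:
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = idx >= 0 and pos < ends[idx]
        mean = config.signal_inside_mean if inside else config.signal_outside_mean
        noise = rng.normal(0.0, config.signal_sd) if config.signal_sd > 0 else 0.0
        probes.append((chrom, pos, float(mean + noise)))
        pos += int(
            rng.integers(config.probe_spacing_min, config.probe_spacing_max + 1)
        )
    return probes


def generate_gene_models(
    target_length: int,
    gene_count: int,
    seed: int | np.random.Generator = 0,
    chrom: str = TARGET_CHROM,
    min_length: int = 900,
    max_length: int = 4500,
) -> list[GeneModel]:
    """Non-overlapping single-CDS gene models with random strand.

    Gene lengths are uniform in [min_length, max_length] rounded down to
    a multiple of 3; the CDS spans the whole gene.
    """
    if gene_count < 1:
        raise ValueError("gene_count must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng([seed, _STREAM_GENES])
    )
    lengths = [
        int(rng.integers(min_length, max_length + 1)) // 3 * 3
        for _ in range(gene_count)
    ]
    if sum(lengths) > target_length:
        raise ValueError("cannot pack genes into the chromosome")
    # place longest-first into a shrinking free list for robust packing
    order = sorted(range(gene_count), key=lambda i: -lengths[i])
    placed: list[tuple[int, int]] = []
    for i in order:
        L = lengths[i]
        for _ in range(2000):
            start = int(rng.integers(0, target_length - L + 1))
            if all(start + L <= s or e <= start for s, e in placed):
                placed.append((start, start + L))
                break
        else:
            raise ValueError("gene packing failed; chromosome too crowded")
    placed.sort()
    genes = []
    for idx, (s, e) in enumerate(placed):
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(
            GeneModel(
                name=f"gene{idx + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=s,
                end=e,
                cds_segments=[(s, e)],
            )
        )
    return genes


def generate_ortholog_pairs(
    sites: Sequence[MotifSite | GenomicRegion],
    genome: str,
    flank: int = 100,
    site_rate: float = 0.12,
    flank_rate: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> list[OrthologPair]:
    """Gapless site+/-flank alignments against mutated copies.

    Each column of the mutated copy substitutes, with probability
    ``site_rate`` inside the site and ``flank_rate`` in the flanks, to a
    uniformly chosen different base.  Sites too close to a sequence end
    get truncated flanks, recorded on the pair.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not (0 <= site_rate < 1 and 0 <= flank_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng([seed, _STREAM_ORTHOLOGS])
    )
    pairs: list[OrthologPair] = []
    bases = "ACGT"
    for i, site in enumerate(sites):
        lo = site.start - flank
        hi = site.end + flank
        trunc_left = lo < 0
        trunc_right = hi > len(genome)
        lo, hi = max(lo, 0), min(hi, len(genome))
        query = genome[lo:hi].upper()
        s0, s1 = site.start - lo, site.end - lo
        rates = np.full(len(query), flank_rate)
        rates[s0:s1] = site_rate
        mutate = rng.random(len(query)) < rates
        subject = list(query)
        for j in np.nonzero(mutate)[0]:
            alt = [b for b in bases if b != query[j]]
            subject[j] = alt[int(rng.integers(3))]
        pairs.append(
            OrthologPair(
                name=f"pair{i + 1:05d}",
                query=query,
                subject="".join(subject),
                site_start=s0,
                site_end=s1,
                truncated_left=trunc_left,
                truncated_right=trunc_right,
            )
        )
    return pairs
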