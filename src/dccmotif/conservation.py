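"""Site-versus-flank conservation from pairwise ortholog alignments.

Each motif site is aligned, together with flanking sequence (default
100 nt each side), against its ortholog in a second species.  Aligned
columns are partitioned into site and flank by query coordinate, and a
lower-tail cumulative hypergeometric test asks whether the observed
number of differences inside sites is compatible with the sites sharing
the flanks' mutation rate: with N aligned columns of which K belong to
sites, and n differing columns of which k hit sites, conservation of
the sites shows as P(X <= k) being small under X ~ Hypergeom(N, K, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .synthetic_types import OrthologPair

__all__ = [
    "ConservationConfig",
    "ConservationCounts",
    "partition_alignment",
    "aggregate_counts",
    "identity_percentages",
    "conservation_hypergeometric_test",
]

GAP = "-"


@dataclass
class ConservationConfig:
    """Flank size plus the homology-search thresholds recorded for
    provenance (the homology search itself happens upstream, in any
    aligner; only its thresholds are carried into reports)."""

    flank: int = 100
    blast_evalue_max: float = 1e-3
    blast_min_homology: int = 40

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class ConservationCounts:
    """Aligned-column tallies split into site and flank partitions.

    N_total aligned columns, K_site of them within sites; n_diff
    differing columns, k_site_diff of those within sites.
    """

    N_total: int = 0
    K_site: int = 0
    n_diff: int = 0
    k_site_diff: int = 0

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k_site_diff <= min(self.K_site, self.n_diff)
            and self.K_site <= self.N_total
            and self.n_diff <= self.N_total
        )
        if not ok:
            raise ValueError(f"inconsistent counts {self}")

    def __add__(self, other: "ConservationCounts") -> "ConservationCounts":
        return ConservationCounts(
            self.N_total + other.N_total,
            self.K_site + other.K_site,
            self.n_diff + other.n_diff,
            self.k_site_diff + other.k_site_diff,
        )


def partition_alignment(
    pair: OrthologPair,
    site_start: int | None = None,
    site_end: int | None = None,
) -> ConservationCounts:
    """Column tallies of one aligned pair, split site vs flank.

    Columns map to query coordinates by counting non-gap query
    characters; a column is a difference when its two characters differ
    (a gap against a base counts as a difference, gap-gap columns are
    excluded from the total).  Columns where the query has a gap are
    assigned to the site partition only when the insertion falls
    strictly inside the site.  A site interval outside the aligned span
    simply yields flank-only counts.
    """
    start = pair.site_start if site_start is None else site_start
    end = pair.site_end if site_end is None else site_end
    N = K = n = k = 0
    qpos = 0  # query bases consumed so far
    for a, b in zip(pair.query.upper(), pair.subject.upper()):
        if a == GAP and b == GAP:
            continue
        in_site = (
            start <= qpos < end if a != GAP else start < qpos < end
        )
        N += 1
        diff = a != b
        if in_site:
            K += 1
        if diff:
            n += 1
            if in_site:
                k += 1
        if a != GAP:
            qpos += 1
    return ConservationCounts(N, K, n, k)


def aggregate_counts(
    per_pair: Iterable[ConservationCounts],
) -> ConservationCounts:
    total = ConservationCounts()
    for c in per_pair:
        total = total + c
    return total


def identity_percentages(counts: ConservationCounts) -> tuple[float, float]:
    """Percent identity inside sites and in the flanks.

    site = (K - k)/K * 100; flank = ((N-K) - (n-k))/(N-K) * 100.
    """
    if counts.K_site == 0 or counts.N_total <= counts.K_site:
        raise ValueError("need K_site > 0 and flank columns > 0")
    site = (counts.K_site - counts.k_site_diff) / counts.K_site * 100.0
    flank_cols = counts.N_total - counts.K_site
    flank_diff = counts.n_diff - counts.k_site_diff
    flank = (flank_cols - flank_diff) / flank_cols * 100.0
    return site, flank


def conservation_hypergeometric_test(counts: ConservationCounts) -> float:
    """Lower-tail P(X <= k_site_diff) under the shared-rate null.

    X ~ Hypergeom(population N_total, K_site marked, n_diff drawn);
    evaluated in log space for numerical safety at genome-scale counts.
    """
    logp = stats.hypergeom.logcdf(
        counts.k_site_diff, counts.N_total, counts.K_site, counts.n_diff
    )
    return float(np.exp(logp))
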