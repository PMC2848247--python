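"""DCC binding-region calling from ChIP-chip probe tracks.

A binding region is a maximal run of probes whose signal reaches a
minimum level and whose consecutive positions are no farther apart than
a gap limit (defaults: signal >= 2, gap <= 1 kb, matching tiling arrays
with probes every 50-100 nt and repeat-masked gaps).  Consensus regions
pool the calls of several datasets, merge calls separated by less than a
gap, and drop short leftovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .intervals import (
    GenomicRegion,
    merge_regions,
    overlap_statistics,
    sort_regions,
)

__all__ = [
    "BindingCallConfig",
    "ConsensusConfig",
    "ProbeRecord",
    "call_binding_regions",
    "consensus_regions",
    "overlap_statistics",
]

ProbeRecord = tuple[str, int, float]  # (chrom, 0-based position, signal)


@dataclass
class BindingCallConfig:
    min_signal: float = 2.0
    max_gap: int = 1000

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class ConsensusConfig:
    merge_gap: int = 1000
    min_length: int = 1000

    def __post_init__(self) -> None:
        if self.merge_gap < 0 or self.min_length < 0:
            raise ValueError("merge_gap and min_length must be >= 0")


def call_binding_regions(
    probes: Iterable[ProbeRecord],
    config: BindingCallConfig | None = None,
    label: str = "binding",
) -> list[GenomicRegion]:
    """Runs of significant probes -> binding regions.

    Probes must be sorted by (chrom, position).  A region spans from the
    first to the last probe position of the run, half-open, so a single
    qualifying probe yields a 1 bp region.  Region score = max signal.
    """
    config = config or BindingCallConfig()
    out: list[GenomicRegion] = []
    run: list[ProbeRecord] = []
    prev: ProbeRecord | None = None

    def flush() -> None:
        if run:
            out.append(
                GenomicRegion(
                    run[0][0],
                    run[0][1],
                    run[-1][1] + 1,
                    label,
                    max(p[2] for p in run),
                )
            )
            run.clear()

    for probe in probes:
        chrom, pos, signal = probe
        if prev is not None and (chrom, pos) < (prev[0], prev[1]):
            raise ValueError("probes must be sorted by (chrom, position)")
        prev = probe
        if signal < config.min_signal:
            continue
        if run and (
            chrom != run[-1][0] or pos - run[-1][1] > config.max_gap
        ):
            flush()
        run.append(probe)
    flush()
    return out


def consensus_regions(
    region_sets: Sequence[Sequence[GenomicRegion]],
    config: ConsensusConfig | None = None,
) -> list[GenomicRegion]:
    """Pool region sets, merge regions separated by < merge_gap, keep
    merged regions strictly longer than min_length."""
    config = config or ConsensusConfig()
    pooled = sort_regions(r for rs in region_sets for r in rs)
    merged = merge_regions(
        pooled, max_gap=config.merge_gap, strict_less=True, label="consensus"
    )
    return [r for r in merged if len(r) > config.min_length]
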