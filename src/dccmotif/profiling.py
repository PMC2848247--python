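"""Oligonucleotide profiling: chromosome-specificity of k-mers.

Every position of a target sequence is annotated with the ratio of the
frequency of the k-mer starting there in one source sequence (typically
the X chromosome) over its frequency in a second source (an autosome
arm), corrected for the relative sizes of the two sources.  Ratios of R
adjacent words are averaged into "locus" values; loci span k + R - 1
nucleotides and consecutive loci overlap by k + R - 2.  Loci above a
specificity threshold are merged into X-specific regions.

Words are counted on the given (forward) strand only; windows containing
non-ACGT characters are skipped and produce no locus.  A flag allows
counting both strands of the sources for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicRegion, overlap_statistics, total_length

__all__ = [
    "ProfilingConfig",
    "KmerTable",
    "SpecificityProfile",
    "count_kmers",
    "word_ratio",
    "profile_target",
    "call_specific_regions",
    "cutoff_sweep",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.array(list("ACGT"))


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, -1 for other."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code and validity of every k-window of an encoded sequence."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (codes < 0).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    c = np.where(codes < 0, 0, codes).astype(np.int64)
    w = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        w = (w << 2) | c[i : n - k + 1 + i]
    return w, valid


def encode_word(word: str) -> int:
    codes = encode_sequence(word)
    if (codes < 0).any():
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


def decode_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass
class ProfilingConfig:
    """Parameters of the specificity profile.

    k and R define loci of k + R - 1 nt; ``threshold`` is the minimum
    average ratio for a locus to be called specific; words absent from
    source 2 get the fixed ``pseudocount`` in the denominator.
    """

    k: int = 13
    R: int = 5
    threshold: float = 6.8
    pseudocount: float = 0.5
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.R < 1:
            raise ValueError("k and R must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @property
    def locus_span(self) -> int:
        return self.k + self.R - 1


class KmerTable:
    """Forward-strand k-mer counts of a source sequence.

    ``effective_length`` is the number of counted windows (windows with
    ambiguous bases are skipped and excluded).
    """

    def __init__(self, k: int, counts: dict[int, int], effective_length: int):
        self.k = k
        self._counts = counts
        self.effective_length = effective_length

    def count(self, word: str) -> int:
        if len(word) != self.k:
            raise ValueError(f"word length {len(word)} != k={self.k}")
        return self._counts.get(encode_word(word), 0)

    def count_code(self, code: int) -> int:
        return self._counts.get(code, 0)

    def items(self):
        for code, n in self._counts.items():
            yield decode_word(code, self.k), n

    def __len__(self) -> int:
        return len(self._counts)


def count_kmers(sequence: str, k: int, both_strands: bool = False) -> KmerTable:
    """Count every k-window of ``sequence`` on the forward strand.

    With ``both_strands=True`` the reverse complement's windows are added
    to the same table (sensitivity-analysis option, off by default).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    strands = [sequence]
    if both_strands:
        strands.append(reverse_complement(sequence))
    counts: dict[int, int] = {}
    eff = 0
    for s in strands:
        w, valid = _window_codes(encode_sequence(s), k)
        if w.size == 0:
            continue
        uq, cnt = np.unique(w[valid], return_counts=True)
        eff += int(valid.sum())
        for code, n in zip(uq.tolist(), cnt.tolist()):
            counts[code] = counts.get(code, 0) + n
    return KmerTable(k, counts, eff)


def _size_correction(source1: KmerTable, source2: KmerTable) -> float:
    if source1.effective_length == 0:
        raise ValueError("source 1 has no counted windows")
    return source2.effective_length / source1.effective_length


def word_ratio(
    word: str,
    source1: KmerTable,
    source2: KmerTable,
    config: ProfilingConfig | None = None,
) -> float:
    """Size-corrected frequency ratio of one word between two sources.

    ratio = count1 / max(count2, pseudocount) * (eff2 / eff1).  The word
    must be present in source 1 (profiling only queries words read from
    the target, which is source 1's sequence).
    """
    config = config or ProfilingConfig(k=source1.k)
    c1 = source1.count(word)
    if c1 == 0:
        raise ValueError(f"word {word!r} absent from source 1")
    c2 = source2.count(word)
    return c1 / max(c2, config.pseudocount) * _size_correction(source1, source2)


@dataclass
class SpecificityProfile:
    """Smoothed per-locus specificity ratios along a target sequence.

    ``positions[i]`` is the start of locus i (0-based); its span is
    ``[positions[i], positions[i] + k + R - 1)`` and ``values[i]`` is the
    arithmetic mean of the R word ratios in that span.  Only loci whose
    span is free of ambiguous bases are present.
    """

    target_id: str
    k: int
    R: int
    positions: np.ndarray
    values: np.ndarray
    correction: float
    target_length: int = 0

    @property
    def locus_span(self) -> int:
        return self.k + self.R - 1

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values})


def profile_target(
    target: str,
    source1: KmerTable,
    source2: KmerTable,
    config: ProfilingConfig,
    target_id: str = "target",
) -> SpecificityProfile:
    """Specificity profile of ``target`` from two source k-mer tables."""
    k, R = config.k, config.R
    if source1.k != k or source2.k != k:
        raise ValueError("k-mer tables must be built with config.k")
    corr = _size_correction(source1, source2)
    w, valid = _window_codes(encode_sequence(target), k)
    n_words = w.size
    if n_words < R:
        return SpecificityProfile(
            target_id, k, R,
            np.empty(0, dtype=np.int64), np.empty(0), corr, len(target),
        )
    # per-word ratio (nan on invalid windows)
    uq, inv = np.unique(w, return_inverse=True)
    c1 = np.array([source1.count_code(int(c)) for c in uq], dtype=np.float64)
    c2 = np.array([source2.count_code(int(c)) for c in uq], dtype=np.float64)
    ratios_u = c1 / np.maximum(c2, config.pseudocount) * corr
    ratios = ratios_u[inv]
    if (valid & (c1[inv] == 0)).any():
        raise ValueError("target contains a word absent from source 1")
    ratios[~valid] = np.nan

    # moving mean over R adjacent words where all R are valid
    r0 = np.where(valid, ratios, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(r0)])
    sums = cs[R:] - cs[:-R]
    cv = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    all_valid = (cv[R:] - cv[:-R]) == R
    positions = np.nonzero(all_valid)[0].astype(np.int64)
    values = sums[all_valid] / R
    return SpecificityProfile(target_id, k, R, positions, values, corr, len(target))


def call_specific_regions(
    profile: SpecificityProfile, threshold: float | None = None,
    label: str = "x_specific",
) -> list[GenomicRegion]:
    """Merge threshold-passing loci into specific regions.

    Loci with value >= threshold are kept; loci whose spans overlap or
    abut merge into one region (score = max locus value inside).
    """
    if threshold is None:
        threshold = ProfilingConfig(k=profile.k, R=profile.R).threshold
    span = profile.locus_span
    sel = profile.values >= threshold
    pos = profile.positions[sel]
    val = profile.values[sel]
    if pos.size == 0:
        return []
    # break where the next qualifying locus starts after the current span ends
    breaks = np.nonzero(np.diff(pos) > span)[0] + 1
    out = []
    for chunk_pos, chunk_val in zip(
        np.split(pos, breaks), np.split(val, breaks)
    ):
        out.append(
            GenomicRegion(
                profile.target_id,
                int(chunk_pos[0]),
                int(chunk_pos[-1]) + span,
                label,
                float(chunk_val.max()),
            )
        )
    return out


def cutoff_sweep(
    profile: SpecificityProfile,
    cutoffs: list[float],
    binding_regions: list[GenomicRegion],
    target_length: int | None = None,
) -> pd.DataFrame:
    """Region statistics for a series of specificity cutoffs.

    One row per cutoff: number of specific regions, percent of the target
    covered by them, how many overlap at least one binding region, and
    how many binding regions contain at least one specific region.
    """
    if target_length is None:
        target_length = profile.target_length or (
            int(profile.positions.max()) + profile.locus_span
            if len(profile) else 0
        )
    rows = []
    for cutoff in cutoffs:
        regs = call_specific_regions(profile, cutoff)
        n_overlap, n_binding_pos, mean_per_b, frac_b = overlap_statistics(
            regs, binding_regions
        )
        rows.append(
            {
                "cutoff": cutoff,
                "n_regions": len(regs),
                "pct_target_covered": (
                    100.0 * total_length(regs) / target_length
                    if target_length else 0.0
                ),
                "n_regions_overlapping_binding": n_overlap,
                "n_binding_with_region": n_binding_pos,
                "mean_regions_per_positive_binding": mean_per_b,
                "fraction_binding_positive": frac_b,
            }
        )
    return pd.DataFrame(rows)
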