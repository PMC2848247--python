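"""Codon-class expansion, site-to-codon mapping and usage contrasts."""

from collections import Counter

import numpy as np
import pytest

from dccmotif import (
    GeneModel,
    GenomicRegion,
    MotifSite,
    class_frequency_table,
    codon_usage_ratio,
    compare_class_proportions,
    compound_ratio,
    expand_codon_class,
    map_sites_to_codons,
    pattern_run_frequency,
    six_classes,
)
from dccmotif.codons import codon_matches_pattern, translate_codon
from dccmotif.profiling import reverse_complement

from conftest import random_dna


class TestExpandCodonClass:
    @pytest.mark.parametrize(
        "pattern, expected_aas",
        [
            # amino-acid multisets of the six classes (one-letter code)
            ("SNG", Counter("VAEGLPQR")),  # (CG)NG: 8 distinct
            ("GSN", Counter({"A": 4, "G": 4})),  # G(CG)N: Ala x4, Gly x4
            ("NSC", Counter({"S": 2, "C": 1, "P": 1, "R": 1, "T": 1,
                             "A": 1, "G": 1})),  # N(CG)C: 7 distinct
            ("NGS", Counter({"R": 3, "G": 2, "C": 1, "W": 1, "S": 1})),
            ("SCN", Counter({"P": 4, "A": 4})),
            ("CNS", Counter({"L": 2, "P": 2, "R": 2, "H": 1, "Q": 1})),
        ],
    )
    def test_amino_acid_multisets(self, pattern, expected_aas):
        cls = expand_codon_class(pattern)
        assert len(cls.codons) == 8
        assert Counter(cls.amino_acids) == expected_aas
        assert not cls.contains_stop

    def test_codons_round_trip_their_pattern(self):
        for cls in six_classes():
            for codon in cls.codons:
                assert codon_matches_pattern(codon, cls.pattern)

    def test_degeneracy_product(self):
        cls = expand_codon_class("NNN")
        assert len(cls.codons) == 64
        cls = expand_codon_class("ASS")
        assert len(cls.codons) == 4

    def test_stop_containing_class_is_flagged(self):
        cls = expand_codon_class("TNA")
        assert cls.contains_stop

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            expand_codon_class("GS")
        with pytest.raises(ValueError):
            expand_codon_class("GSX")


class TestSixClasses:
    def test_each_has_eight_codons(self):
        assert [len(c.codons) for c in six_classes()] == [8] * 6

    def test_codon_sets_pairwise_distinct(self):
        sets = [frozenset(c.codons) for c in six_classes()]
        assert len(set(sets)) == 6

    def test_union_counts_48_with_duplicates(self):
        all_codons = [c for cls in six_classes() for c in cls.codons]
        assert len(all_codons) == 48
        assert len(set(all_codons)) < 48  # some codons shared across classes

    def test_distinct_amino_acid_counts(self):
        counts = {
            c.display_name: len(c.distinct_amino_acids) for c in six_classes()
        }
        assert counts == {
            "G(CG)N": 2, "(CG)NG": 8, "NG(CG)": 5,
            "N(CG)C": 7, "(CG)CN": 2, "CN(CG)": 5,
        }


def naive_site_codons(site, gene, genome):
    """Frame-walking oracle: extract the CDS, enumerate its codons, keep
    those whose genomic footprint lies inside the site."""
    segs = gene.cds_segments
    positions = []
    for s, e in segs:
        positions.extend(range(s, e))
    if gene.strand == "-":
        positions = positions[::-1]
    seq = genome[gene.chrom]
    out = []
    for j in range(len(positions) // 3):
        trip = positions[3 * j : 3 * j + 3]
        if all(site.start <= p < site.end for p in trip):
            codon = "".join(seq[p] for p in trip)
            if gene.strand == "-":
                codon = reverse_complement(codon)[::-1]  # complement only
            out.append(codon.upper())
    return out


class TestMapSitesToCodons:
    def test_site_covering_four_inframe_codons(self):
        genome = {"chrX": "T" * 30 + "GCGGCGGCGGCG" + "T" * 30}
        gene = GeneModel("g", "chrX", "+", 30, 42, [(30, 42)])
        site = MotifSite("chrX", 30, 42, "+", 1.0)
        a = map_sites_to_codons([site], [gene], genome)
        assert [x.codon for x in a] == ["GCG"] * 4

    def test_shifted_site_discards_partial_codons(self):
        genome = {"chrX": "T" * 30 + "GCGGCGGCGGCGGCG" + "T" * 30}
        gene = GeneModel("g", "chrX", "+", 30, 45, [(30, 45)])
        site = MotifSite("chrX", 31, 43, "+", 1.0)  # 12 nt, off-frame by 1
        a = map_sites_to_codons([site], [gene], genome)
        assert len(a) == 3

    def test_strand_mirror_symmetry(self, rng):
        """A minus-strand gene built as the reverse complement of a
        plus-strand construction yields the identical class table."""
        core = random_dna(rng, 300)
        genome_p = {"chrX": "A" * 50 + core + "A" * 50}
        gene_p = GeneModel("g", "chrX", "+", 50, 350, [(50, 350)])
        site_p = MotifSite("chrX", 100, 130, "+", 1.0)

        seq_m = reverse_complement(genome_p["chrX"])
        L = len(seq_m)
        genome_m = {"chrX": seq_m}
        gene_m = GeneModel("g", "chrX", "-", L - 350, L - 50, [(L - 350, L - 50)])
        site_m = MotifSite("chrX", L - 130, L - 100, "+", 1.0)

        a_p = map_sites_to_codons([site_p], [gene_p], genome_p)
        a_m = map_sites_to_codons([site_m], [gene_m], genome_m)
        assert [x.codon for x in a_p] == [x.codon for x in a_m]
        assert [x.codon_class for x in a_p] == [x.codon_class for x in a_m]

    def test_matches_frame_walking_oracle(self, rng):
        for _ in range(40):
            L = 600
            seq = random_dna(rng, L)
            start = int(rng.integers(0, 200))
            glen = int(rng.integers(60, 300)) // 3 * 3
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(
                "g", "chrX", strand, start, start + glen,
                [(start, start + glen)],
            )
            s0 = int(rng.integers(0, L - 40))
            site = MotifSite("chrX", s0, s0 + int(rng.integers(12, 40)), "+", 1.0)
            genome = {"chrX": seq}
            got = [a.codon for a in map_sites_to_codons([site], [gene], genome)]
            expected = naive_site_codons(site, gene, genome)
            assert got == expected

    def test_inside_binding_flag(self):
        genome = {"chrX": "GCG" * 40}
        gene = GeneModel("g", "chrX", "+", 0, 120, [(0, 120)])
        sites = [
            MotifSite("chrX", 0, 12, "+", 1.0),
            MotifSite("chrX", 60, 72, "+", 1.0),
        ]
        binding = [GenomicRegion("chrX", 0, 30, "binding")]
        a = map_sites_to_codons([sites[0]], [gene], genome, binding)
        b = map_sites_to_codons([sites[1]], [gene], genome, binding)
        assert all(x.inside_binding for x in a)
        assert not any(x.inside_binding for x in b)

    def test_every_emitted_codon_is_in_frame(self, rng):
        seq = random_dna(rng, 400)
        gene = GeneModel("g", "chrX", "+", 10, 310, [(10, 310)])
        site = MotifSite("chrX", 50, 120, "+", 1.0)
        assignments = map_sites_to_codons([site], [gene], {"chrX": seq})
        assert assignments
        for a in assignments:
            assert (a.genomic_start - 10) % 3 == 0
            assert seq[a.genomic_start : a.genomic_start + 3].upper() == a.codon
            assert 50 <= a.genomic_start and a.genomic_start + 3 <= 120


class TestFrequencyTableAndChi2:
    def test_single_class_table(self):
        genome = {"chrX": "CAG" * 20}  # CAG matches (CG)NG
        gene = GeneModel("g", "chrX", "+", 0, 60, [(0, 60)])
        site = MotifSite("chrX", 0, 60, "+", 1.0)
        table = class_frequency_table(
            map_sites_to_codons([site], [gene], genome)
        )
        assert table.loc["(CG)NG", "outside"] == 20
        assert table.loc["(CG)NG", "outside_pct"] == pytest.approx(100.0)

    def test_empty_table(self):
        table = class_frequency_table([])
        assert table["inside"].sum() == 0 and table["outside"].sum() == 0

    def test_equal_proportions_give_zero_statistic(self):
        chi2, p, df = compare_class_proportions((10, 100), (30, 300))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_hand_computed_diagonal_table(self):
        chi2, p, _ = compare_class_proportions((10, 10), (0, 10))
        assert chi2 == pytest.approx(20.0)

    def test_reported_counts_are_highly_significant(self):
        """(CG)NG share 6185/10701 inside vs 12248/24016 outside binding
        regions is a very strong contrast."""
        chi2, p, _ = compare_class_proportions((6185, 10701), (12248, 24016))
        assert p < 1e-30

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected cell"):
            compare_class_proportions((1, 2), (0, 1))


class TestCodonUsage:
    def test_identical_sets_ratio_one(self):
        cds = ["GCTGGCAAA", "TTTGGC"]
        for codon in ("GCT", "GGC", "AAA"):
            assert codon_usage_ratio(cds, cds, codon) == pytest.approx(1.0)

    def test_pure_set_versus_uniform(self):
        from itertools import product

        uniform = ["".join(c) for c in product("ACGT", repeat=3)]
        ratio = codon_usage_ratio(["GGC"], ["".join(uniform)], "GGC")
        assert ratio == pytest.approx(64.0)

    def test_absent_codon_raises_with_guidance(self):
        with pytest.raises(ValueError, match="pseudocount"):
            codon_usage_ratio(["GGC"], ["AAA"], "GGC")

    def test_compound_ratio(self):
        assert compound_ratio(1.18, 6) == pytest.approx(2.7, abs=0.05)


class TestPatternRunFrequency:
    def test_pure_run(self):
        assert pattern_run_frequency(["CAGCAGCAGCAG"], "SNG", 4) == 1.0

    def test_no_matches(self):
        assert pattern_run_frequency(["AAA" * 10], "SNG", 4) == 0.0

    def test_short_cds_contributes_no_windows(self):
        assert pattern_run_frequency(["CAGCAG"], "SNG", 4) == 0.0

    def test_uniform_codons_match_analytic_rate(self):
        """Under uniform codon usage a window of 4 consecutive codons
        matches an 8-codon class with probability (8/64)^4 ~ 2.44e-4."""
        rng = np.random.default_rng(42)
        from itertools import product

        codons = ["".join(c) for c in product("ACGT", repeat=3)]
        cds_set = [
            "".join(rng.choice(codons, size=2000)) for _ in range(300)
        ]
        freq = pattern_run_frequency(cds_set, "SNG", 4)
        expected = (8 / 64) ** 4
        assert freq == pytest.approx(expected, rel=0.35)
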