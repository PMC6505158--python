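"""Multiset genotype enumeration, parsing and combinatorics."""

from collections import Counter
from fractions import Fraction as F
from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

from polysomic import genotypes as gt


class TestEnumeration:
    @pytest.mark.parametrize(
        "v,h,count",
        [(4, 2, 5), (4, 3, 15), (6, 6, 462), (8, 3, 45), (12, 2, 13)],
    )
    def test_zygote_counts(self, v, h, count):
        got = gt.enumerate_genotypes(v, h)
        assert len(got) == count == comb(v + h - 1, v)

    @pytest.mark.parametrize(
        "v,h,count", [(4, 3, 6), (8, 8, 330), (2, 5, 5), (6, 2, 4)]
    )
    def test_gamete_counts(self, v, h, count):
        got = gt.enumerate_gametes(v, h)
        assert len(got) == count == comb(v // 2 + h - 1, v // 2)

    def test_counts_match_stars_and_bars_over_grid(self):
        for v in (2, 4, 6, 8, 10, 12):
            for h in range(1, 9):
                assert len(gt.enumerate_genotypes(v, h)) == comb(v + h - 1, v)

    def test_lexicographic_and_canonical(self):
        gs = gt.enumerate_genotypes(4, 3)
        assert gs == sorted(gs)
        assert all(g == tuple(sorted(g)) for g in gs)

    @pytest.mark.parametrize("v", [3, 0, -2, 5])
    def test_odd_or_invalid_ploidy_rejected(self, v):
        with pytest.raises(ValueError, match="ploidy"):
            gt.enumerate_genotypes(v, 2)
        with pytest.raises(ValueError, match="ploidy"):
            gt.enumerate_gametes(v, 2)


class TestParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [("AABC", (0, 0, 1, 2)), ("A1,A1,B2", (0, 0, 1)), ("CBA", (0, 1, 2)),
         ("A3,A1", (0, 2))],
    )
    def test_parse(self, text, expected):
        assert gt.parse_genotype(text) == expected

    def test_format_letters_and_long_labels(self):
        assert gt.format_genotype((0, 0, 1, 2)) == "AABC"
        assert gt.format_genotype((0, 27), h=30) == "A1,A28"

    @given(st.lists(st.integers(0, 25), min_size=1, max_size=8))
    def test_round_trip(self, alleles):
        g = gt.canonical(alleles)
        assert gt.parse_genotype(gt.format_genotype(g)) == g

    @pytest.mark.parametrize("bad", ["", "a b", "A0,A1", "1X"])
    def test_bad_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            gt.parse_genotype(bad)


class TestPhenotype:
    @pytest.mark.parametrize(
        "g,ph",
        [("AAAB", "AB"), ("AAAA", "A"), ("ABCD", "ABCD"), ("AABB", "AB")],
    )
    def test_examples(self, g, ph):
        got = gt.genotype_to_phenotype(gt.parse_genotype(g))
        assert gt.format_genotype(got) == ph


class TestGameteSubsets:
    @pytest.mark.parametrize(
        "G,expected",
        [
            ("AAAB", {("AA", "AB"), ("AB", "AA")}),
            ("AABB", {("AA", "BB"), ("AB", "AB"), ("BB", "AA")}),
            ("AAAA", {("AA", "AA")}),
        ],
    )
    def test_examples(self, G, expected):
        got = {
            (gt.format_genotype(s), gt.format_genotype(c))
            for s, c in gt.gamete_subsets(gt.parse_genotype(G))
        }
        assert got == expected

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=8).filter(lambda x: len(x) % 2 == 0))
    def test_complement_reassembles_the_zygote(self, alleles):
        G = gt.canonical(alleles)
        pairs = gt.gamete_subsets(G)
        assert len(pairs) == len({s for s, _ in pairs})  # multiplicity-free
        for sub, compl in pairs:
            assert tuple(sorted(sub + compl)) == G


class TestHWE:
    def test_tetraploid_aabc_coefficient(self):
        p = (F(1, 2), F(3, 10), F(1, 5))
        freq = gt.hwe_frequencies(p, 4)
        assert freq[(0, 0, 1, 2)] == 12 * p[0] ** 2 * p[1] * p[2]

    def test_fixed_allele(self):
        assert gt.hwe_frequencies((1,), 4)[(0, 0, 0, 0)] == 1

    def test_uniform_tetraallelic_full_heterozygote(self):
        freq = gt.hwe_frequencies(gt.uniform_frequencies(4), 4)
        assert freq[(0, 1, 2, 3)] == F(24, 256)

    @pytest.mark.parametrize("p", [(F(1, 2), F(1, 3), F(1, 6)), (F(1), F(0))])
    def test_sums_to_one_exactly(self, p):
        assert sum(gt.hwe_frequencies(p, 6).values()) == 1

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gt.hwe_frequencies((0.5, 0.6), 4)
        with pytest.raises(ValueError):
            gt.hwe_frequencies((F(1, 2), F(-1, 2), F(1)), 4)


class TestMergeAlleles:
    def test_collapse_to_single_allele(self):
        merged = gt.merge_alleles({(0, 0): 0.25, (0, 1): 0.5, (1, 1): 0.25}, {1: 0})
        assert merged == {(0, 0): 1.0}

    def test_identity_mapping(self):
        table = {(0, 0, 1, 1): F(1, 2), (0, 1, 2, 2): F(1, 2)}
        assert gt.merge_alleles(table, {}) == table

    def test_triallelic_to_biallelic_pooling(self):
        # pooling C into B sends AABC and AACC into AABB
        table = gt.hwe_frequencies((F(1, 2), F(1, 4), F(1, 4)), 4)
        merged = gt.merge_alleles(table, {2: 1})
        assert merged[(0, 0, 1, 1)] == (
            table[(0, 0, 1, 1)] + table[(0, 0, 1, 2)] + table[(0, 0, 2, 2)]
        )
        assert sum(merged.values()) == 1
        # merging commutes with HWE at pooled frequencies
        assert merged == gt.hwe_frequencies((F(1, 2), F(1, 2)), 4)

    def test_commutes_with_phenotype_aggregation(self):
        from polysomic.equilibrium import phenotype_frequencies

        table = gt.hwe_frequencies((F(1, 2), F(1, 4), F(1, 4)), 4)
        a = phenotype_frequencies(gt.merge_alleles(table, {2: 1}))
        b_raw = gt.merge_alleles(phenotype_frequencies(table), {2: 1})
        b: dict = {}
        for k, val in b_raw.items():
            key = tuple(sorted(set(k)))
            b[key] = b.get(key, 0) + val
        # pooled phenotype mass agrees however the aggregation is ordered
        assert a == b
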