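"""Crosses, parentage probabilities, goodness-of-fit and alpha estimation."""

from fractions import Fraction as F

import pytest

from polysomic import applications as ap
from polysomic import dr_models as dm
from polysomic.genotypes import enumerate_genotypes, parse_genotype


def _g(text):
    return parse_genotype(text)


def _sym_alpha4(a1):
    return dm.AlphaVector(4, (1 - a1, a1))


class TestCross:
    @pytest.mark.parametrize("a1", [F(0), F(1, 6), F(1, 7), F(1, 4)])
    def test_duplex_selfing_gamete_ratio(self, a1):
        # AABB gametes segregate AA : AB : BB = 1+2a1 : 4-4a1 : 1+2a1 over 6
        d = ap.gamete_distribution(_g("AABB"), _sym_alpha4(a1))
        assert d[_g("AA")] == (1 + 2 * a1) / 6
        assert d[_g("AB")] == (4 - 4 * a1) / 6
        assert d[_g("BB")] == (1 + 2 * a1) / 6

    @pytest.mark.parametrize("a1", [F(0), F(1, 6), F(2, 7)])
    def test_f2_segregation_ratio(self, a1):
        # (1+2a)^2 : 8(1+a-2a^2) : 6(3-4a+4a^2) : 8(1+a-2a^2) : (1+2a)^2
        off = ap.cross(_g("AABB"), _g("AABB"), _sym_alpha4(a1)).offspring
        denom = 36
        assert off[_g("AAAA")] == (1 + 2 * a1) ** 2 / denom
        assert off[_g("AAAB")] == 8 * (1 + a1 - 2 * a1**2) / denom
        assert off[_g("AABB")] == 6 * (3 - 4 * a1 + 4 * a1**2) / denom
        assert off[_g("ABBB")] == off[_g("AAAB")]
        assert off[_g("BBBB")] == off[_g("AAAA")]

    def test_rcs_f2_integer_ratio(self):
        r = ap.cross(_g("AABB"), _g("AABB"), dm.alpha_rcs(4)).ratio()
        assert [c for _, c in r] == [1, 8, 18, 8, 1]

    def test_selfing_monomorphic(self):
        r = ap.cross(_g("AAAA"), _g("AAAA"), dm.alpha_ces(4))
        assert r.offspring == {_g("AAAA"): F(1)}

    def test_ploidy_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ploidy"):
            ap.cross(_g("AABB"), _g("AABBCC"), dm.alpha_rcs(4))


class TestOffspringProbability:
    def test_double_reduction_rescues_excluded_parents(self):
        # ABCD x EFGH can produce AAEE only via double-reduction in both parents
        alpha = dm.alpha_ces(4)
        p = ap.offspring_probability(_g("AAEE"), _g("ABCD"), _g("EFGH"), alpha=alpha)
        assert p == F(1, 576) > 0
        assert (
            ap.offspring_probability(_g("AAEE"), _g("ABCD"), _g("EFGH"), alpha=dm.alpha_rcs(4))
            == 0
        )

    def test_certain_offspring(self):
        assert (
            ap.offspring_probability(_g("AAAA"), _g("AAAA"), _g("AAAA"), alpha=dm.alpha_ces(4))
            == 1
        )

    def test_unknown_mother_uses_population_gametes(self):
        gfg = {_g("AA"): F(1, 4), _g("AB"): F(1, 2), _g("BB"): F(1, 4)}
        alpha = dm.alpha_rcs(4)
        got = ap.offspring_probability(
            _g("AABB"), _g("AABB"), gfg_population=gfg, alpha=alpha
        )
        # father passes AA, AB, BB at 1/6, 4/6, 1/6; mother's complement from gfg
        assert got == F(1, 6) * F(1, 4) + F(4, 6) * F(1, 2) + F(1, 6) * F(1, 4)
        with pytest.raises(ValueError, match="gamete table"):
            ap.offspring_probability(_g("AABB"), _g("AABB"), alpha=alpha)

    @pytest.mark.parametrize("alpha", [dm.alpha_rcs(4), dm.alpha_ces(4)])
    def test_marginalises_to_one_over_all_offspring(self, alpha):
        father, mother = _g("AABC"), _g("ABDD")
        total = sum(
            ap.offspring_probability(G, father, mother, alpha=alpha)
            for G in enumerate_genotypes(4, 4)
        )
        assert total == 1


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        res = ap.equilibrium_gof_test(
            {(0, 0): 10, (0, 1): 20, (1, 1): 10},
            {(0, 0): F(1, 4), (0, 1): F(1, 2), (1, 1): F(1, 4)},
        )
        assert res.chisq == 0 and res.g == 0
        assert res.chisq_p == 1 and res.df == 2

    def test_hand_computed_statistic(self):
        from math import log

        res = ap.equilibrium_gof_test({(0,): 16, (1,): 24}, {(0,): F(1, 2), (1,): F(1, 2)})
        assert res.chisq == pytest.approx(1.6)
        assert res.df == 1
        assert res.g == pytest.approx(2 * (16 * log(16 / 20) + 24 * log(24 / 20)))

    def test_impossible_category_flagged(self):
        res = ap.equilibrium_gof_test({(0,): 5, (1,): 5}, {(0,): F(1)})
        assert res.impossible_category
        assert res.chisq == float("inf") and res.chisq_p == 0

    def test_zero_observed_cells_skipped_in_g(self):
        from math import log

        res = ap.equilibrium_gof_test(
            {(0,): 40}, {(0,): F(1, 2), (1,): F(1, 2)}
        )
        assert res.df == 1
        assert res.g == pytest.approx(2 * 40 * log(2))


class TestEstimateAlpha:
    def test_recovers_ces_rate_from_exact_proportions(self):
        true = dm.alpha_ces(4)
        off = ap.cross(_g("AABB"), _g("AABB"), true).offspring
        est, resid = ap.estimate_alpha(
            {g: float(w) for g, w in off.items()}, _g("AABB"), _g("AABB"), 4
        )
        assert abs(est.alpha[1] - F(1, 6)) < 1e-9
        assert resid < 1e-16

    def test_recovers_octosomic_pes_vector(self):
        true = dm.alpha_pes(8, F(1, 3))
        parent = _g("AABBCCDD")
        off = ap.cross(parent, parent, true).offspring
        est, _ = ap.estimate_alpha({g: float(w) for g, w in off.items()}, parent, parent, 8)
        assert max(abs(a - float(b)) for a, b in zip(est.alpha, true.alpha)) < 1e-8

    def test_rcs_proportions_give_zero_alpha(self):
        off = ap.cross(_g("AABB"), _g("AABB"), dm.alpha_rcs(4)).offspring
        est, _ = ap.estimate_alpha(
            {g: float(w) for g, w in off.items()}, _g("AABB"), _g("AABB"), 4
        )
        assert est.alpha[1] == pytest.approx(0.0, abs=1e-9)

    def test_unidentifiable_cross_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            ap.estimate_alpha({_g("AAAA"): 10}, _g("AAAA"), _g("AAAA"), 4)
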