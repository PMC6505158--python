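"""Meiosis/fertilisation fixed-point iteration and its population-genetic laws."""

from fractions import Fraction as F

import pytest

from polysomic import dr_models as dm
from polysomic import equilibrium as eq
from polysomic.genotypes import hwe_frequencies, parse_genotype, uniform_frequencies

MODELS = [
    ("rcs", dm.alpha_rcs(4)),
    ("prcs", dm.alpha_prcs(4)),
    ("ces", dm.alpha_ces(4)),
    ("pes", dm.alpha_pes(4, F(1, 2))),
]


def _g(text):
    return parse_genotype(text)


class TestSingleSteps:
    def test_meiosis_of_fixed_population(self):
        assert eq.gfg_from_gfz({_g("AAAA"): F(1)}, dm.alpha_ces(4)) == {_g("AA"): F(1)}

    def test_meiosis_of_simplex_zygote_under_rcs(self):
        got = eq.gfg_from_gfz({_g("AAAB"): F(1)}, dm.alpha_rcs(4))
        assert got == {_g("AA"): F(1, 2), _g("AB"): F(1, 2)}

    def test_fertilisation_point_mass(self):
        assert eq.gfz_from_gfg({_g("AA"): F(1)}) == {_g("AAAA"): F(1)}

    def test_fertilisation_convolution(self):
        got = eq.gfz_from_gfg({_g("AA"): F(1, 2), _g("AB"): F(1, 2)})
        assert got == {
            _g("AAAA"): F(1, 4),
            _g("AAAB"): F(1, 2),
            _g("AABB"): F(1, 4),
        }

    def test_identical_parental_tables_reduce_to_single_table_form(self):
        table = {_g("AA"): F(1, 3), _g("AB"): F(1, 3), _g("BB"): F(1, 3)}
        assert eq.gfz_from_gfg(table, dict(table)) == eq.gfz_from_gfg(table)

    def test_phenotype_aggregation(self):
        got = eq.phenotype_frequencies({_g("AAAA"): 0.3, _g("AAAB"): 0.7})
        assert got == {(0,): 0.3, (0, 1): 0.7}

    def test_allele_frequencies_from_tables(self):
        assert eq.allele_frequencies_from({_g("AAAA"): F(1)}) == (F(1),)
        p = (F(1, 2), F(3, 10), F(1, 5))
        assert eq.allele_frequencies_from(hwe_frequencies(p, 4)) == p


class TestFixedPoint:
    def test_rcs_equilibrium_is_hwe_exactly(self):
        p = (F(1, 2), F(1, 3), F(1, 6))
        res = eq.iterate_equilibrium(p, 4, dm.alpha_rcs(4), generations=4, exact=True)
        assert res.gfz == hwe_frequencies(p, 4)
        assert res.converged and res.generations_run == 1

    @pytest.mark.parametrize("name,alpha", MODELS)
    def test_converged_state_is_a_fixed_point(self, name, alpha):
        p = tuple(map(float, uniform_frequencies(4)))
        res = eq.iterate_equilibrium(p, 4, alpha)
        assert res.converged
        again = eq.gfz_from_gfg(eq.gfg_from_gfz(res.gfz, alpha))
        assert max(abs(again[G] - res.gfz[G]) for G in res.gfz) < 1e-10

    @pytest.mark.parametrize("name,alpha", MODELS)
    def test_allele_frequencies_conserved(self, name, alpha):
        p = (0.5, 0.3, 0.2)
        res = eq.iterate_equilibrium(p, 4, alpha)
        got = eq.allele_frequencies_from(res.gfz)
        assert max(abs(a - b) for a, b in zip(got, p)) < 1e-10
        got_g = eq.allele_frequencies_from(res.gfg)
        assert max(abs(a - b) for a, b in zip(got_g, p)) < 1e-10

    def test_non_convergence_is_reported_not_raised(self):
        res = eq.iterate_equilibrium(
            (0.5, 0.5), 4, dm.alpha_ces(4), generations=2, tolerance=1e-30
        )
        assert not res.converged and res.generations_run == 2

    def test_distinct_parental_alphas(self):
        p = (0.5, 0.5)
        res = eq.iterate_equilibrium(p, 4, dm.alpha_ces(4), alpha_paternal=dm.alpha_rcs(4))
        assert res.gfg_paternal is not None
        assert abs(sum(res.gfz.values()) - 1) < 1e-12
        got = eq.allele_frequencies_from(res.gfz)
        assert max(abs(a - b) for a, b in zip(got, p)) < 1e-10


class TestEquilibriumDeductions:
    """Structural laws of the numeric equilibria (merge / ratio / symmetry)."""

    def test_pattern_symmetry_under_uniform_frequencies(self):
        p = tuple(map(float, uniform_frequencies(4)))
        res = eq.iterate_equilibrium(p, 4, dm.alpha_prcs(4))
        assert res.gfz[_g("AAAB")] == pytest.approx(res.gfz[_g("BBBC")], abs=1e-12)
        assert res.gfz[_g("AABB")] == pytest.approx(res.gfz[_g("CCDD")], abs=1e-12)
        assert res.gfg[_g("AB")] == pytest.approx(res.gfg[_g("CD")], abs=1e-12)

    @pytest.mark.parametrize(
        "v,alpha",
        [
            (4, dm.alpha_prcs(4)),
            (4, dm.alpha_ces(4)),
            (4, dm.alpha_pes(4, F(1, 2))),
            (4, dm.alpha_rcs(4)),
            (6, dm.alpha_ces(6)),
            (6, dm.alpha_prcs(6)),
        ],
    )
    def test_merging_alleles_commutes_with_equilibrium(self, v, alpha):
        from polysomic.genotypes import merge_alleles

        p3 = (0.5, 0.3, 0.2)
        res3 = eq.iterate_equilibrium(p3, v, alpha)
        merged = merge_alleles(res3.gfz, {2: 1})
        res2 = eq.iterate_equilibrium((0.5, 0.5), v, alpha)
        for G, val in res2.gfz.items():
            assert merged.get(G, 0.0) == pytest.approx(val, abs=1e-10)

    def test_frequency_ratio_tracks_allele_ratio(self):
        p = (0.5, 0.3, 0.2)
        res = eq.iterate_equilibrium(p, 4, dm.alpha_ces(4))
        ratio = res.gfz[_g("AAAB")] / res.gfz[_g("AAAC")]
        assert ratio == pytest.approx(p[1] / p[2], rel=1e-9)

    @pytest.mark.parametrize("name,alpha", MODELS)
    def test_gamete_homozygote_frequency_matches_inbreeding_f(self, name, alpha):
        from polysomic.inbreeding import equilibrium_F, gamete_f

        p = (0.5, 0.3, 0.2)
        res = eq.iterate_equilibrium(p, 4, alpha)
        lam = dm.lambda_of(alpha)
        f = float(gamete_f(equilibrium_F(lam, 0, 4), lam, 4))
        for k, pk in enumerate(p):
            expected = pk**2 + f * pk * (1 - pk)
            assert res.gfg[(k, k)] == pytest.approx(expected, abs=1e-10)
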