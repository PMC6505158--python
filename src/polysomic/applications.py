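"""Downstream primitives built on gamete transition probabilities.

Covers the standard uses of T(g|G) in polyploid genetics: segregation
ratios of crosses and selfings (mapping populations), the probability that
a parent pair produces a given offspring (parentage analysis), equilibrium
goodness-of-fit tests, and least-squares estimation of the
double-reduction vector alpha from observed segregation data.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from math import comb, lcm, log
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dr_models import AlphaVector
from .genotypes import (
    Genotype,
    canonical,
    check_ploidy,
    enumerate_gametes,
    gamete_subsets,
)
from .transition import transition_probability

__all__ = [
    "CrossResult",
    "GofResult",
    "gamete_distribution",
    "cross",
    "offspring_probability",
    "equilibrium_gof_test",
    "estimate_alpha",
]


def gamete_distribution(G: Sequence[int], alpha: AlphaVector) -> dict[Genotype, object]:
    """Gamete genotype distribution of one zygote under a given alpha."""
    G = canonical(G)
    h = max(G) + 1
    dist = {}
    for g in enumerate_gametes(len(G), h):
        t = transition_probability(G, g, alpha)
        if t:
            dist[g] = t
    return dist


@dataclass(frozen=True)
class CrossResult:
    """Offspring genotype distribution of a cross (or selfing)."""

    parent1: Genotype
    parent2: Genotype
    offspring: dict

    def ratio(self) -> list[tuple[Genotype, int]]:
        """Smallest-integer segregation ratio, available when entries are exact.

        E.g. selfing AABB under RCS yields AAAA:AAAB:AABB:ABBB:BBBB =
        1:8:18:8:1.
        """
        if not all(isinstance(x, (int, Fraction)) for x in self.offspring.values()):
            raise ValueError("integer ratios require exact rational offspring frequencies")
        fracs = {g: Fraction(x) for g, x in self.offspring.items()}
        denom = lcm(*(f.denominator for f in fracs.values()))
        counts = {g: int(f * denom) for g, f in fracs.items()}
        from math import gcd

        g_all = 0
        for c in counts.values():
            g_all = gcd(g_all, c)
        return [(g, c // g_all) for g, c in sorted(counts.items())]


def cross(
    parent1: Sequence[int],
    parent2: Sequence[int],
    alpha1: AlphaVector,
    alpha2: AlphaVector | None = None,
) -> CrossResult:
    """Offspring distribution of parent1 x parent2 (selfing when equal).

    Convolves the two parental gamete distributions; under RCS this gives
    the Mendelian polysomic expectations.
    """
    p1 = canonical(parent1)
    p2 = canonical(parent2)
    if len(p1) != len(p2):
        raise ValueError("parents must share the ploidy level")
    if alpha2 is None:
        alpha2 = alpha1
    d1 = gamete_distribution(p1, alpha1)
    d2 = d1 if (p2 == p1 and alpha2 == alpha1) else gamete_distribution(p2, alpha2)
    offspring: dict[Genotype, object] = defaultdict(lambda: 0)
    for g1, w1 in d1.items():
        for g2, w2 in d2.items():
            G = tuple(sorted(g1 + g2))
            offspring[G] = offspring[G] + w1 * w2
    return CrossResult(parent1=p1, parent2=p2, offspring=dict(offspring))


def offspring_probability(
    G_off: Sequence[int],
    G_father: Sequence[int],
    G_mother: Sequence[int] | None = None,
    gfg_population: Mapping[Genotype, object] | None = None,
    alpha: AlphaVector | None = None,
    alpha_mother: AlphaVector | None = None,
):
    """Probability that the stated parent(s) produce the offspring genotype.

    Sums T(g|father) * T(G_off \\ g | mother) over the distinct v/2
    sub-multisets g of the offspring; when the mother is unknown her term
    is replaced by the population gamete frequency Pr(G_off \\ g).
    Double-reduction can make parents compatible with offspring that naive
    subset logic would exclude (ABCD x EFGH producing AAEE).
    """
    if alpha is None:
        raise ValueError("an alpha vector for the father is required")
    off = canonical(G_off)
    father = canonical(G_father)
    if len(off) != len(father):
        raise ValueError("offspring and parents must share the ploidy level")
    if G_mother is None and gfg_population is None:
        raise ValueError("a population gamete table is required when the mother is unknown")
    mother = canonical(G_mother) if G_mother is not None else None
    if mother is not None and len(mother) != len(off):
        raise ValueError("offspring and parents must share the ploidy level")
    a_m = alpha_mother if alpha_mother is not None else alpha
    total = 0
    for g, compl in gamete_subsets(off):
        t_f = transition_probability(father, g, alpha)
        if not t_f:
            continue
        if mother is not None:
            other = transition_probability(mother, compl, a_m)
        else:
            other = gfg_population.get(compl, 0)
        total = total + t_f * other
    return total


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square and likelihood-ratio (G) goodness-of-fit results."""

    chisq: float
    chisq_p: float
    g: float
    g_p: float
    df: int
    n: int
    impossible_category: bool  # an observed category had zero expectation


def equilibrium_gof_test(
    observed_counts: Mapping[object, int],
    expected: Mapping[object, object],
) -> GofResult:
    """Goodness of fit of observed genotype/phenotype counts to a frequency table.

    chi^2 = sum (O-E)^2/E and G = 2 sum O ln(O/E) over categories with
    positive expectation; df = (#categories with E > 0) - 1.  A non-zero
    count in a zero-expectation category makes both statistics infinite
    and is flagged.  No correction is applied for parameters estimated
    from the same data.
    """
    if any(c < 0 for c in observed_counts.values()):
        raise ValueError("observed counts must be non-negative")
    n = sum(observed_counts.values())
    if n == 0:
        raise ValueError("at least one observation is required")
    categories = [k for k, e in expected.items() if e > 0]
    impossible = any(
        observed_counts.get(k, 0) > 0 and float(expected.get(k, 0)) <= 0.0
        for k in observed_counts
    )
    df = len(categories) - 1
    if impossible:
        return GofResult(float("inf"), 0.0, float("inf"), 0.0, df, n, True)
    chisq = 0.0
    g_stat = 0.0
    for k in categories:
        e = float(expected[k]) * n
        o = observed_counts.get(k, 0)
        chisq += (o - e) ** 2 / e
        if o > 0:
            g_stat += 2.0 * o * log(o / e)
    chisq_p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    g_p = float(stats.chi2.sf(g_stat, df)) if df > 0 else 1.0
    return GofResult(chisq, chisq_p, g_stat, g_p, df, n, False)


def _expected_proportions(parent1, parent2, v, alpha_free, categories):
    # tolerate slightly infeasible probes from the optimiser's line search
    a = np.clip(np.asarray(alpha_free, dtype=float), 0.0, 1.0)
    vec = np.concatenate([[max(1.0 - a.sum(), 0.0)], a])
    vec /= vec.sum()
    alpha = AlphaVector(v, tuple(float(x) for x in vec))
    off = cross(parent1, parent2, alpha).offspring
    return np.array([float(off.get(c, 0.0)) for c in categories])


def estimate_alpha(
    observed_segregation: Mapping[Genotype, int],
    parent1: Sequence[int],
    parent2: Sequence[int],
    v: int,
) -> tuple[AlphaVector, float]:
    """Least-squares estimate of alpha from observed segregation of one cross.

    Minimises sum_G (observed proportion - expected_G(alpha))^2 over the
    simplex alpha_i >= 0, sum alpha_i = 1 (free parameters
    alpha_1..alpha_{v/4}).  Returns the estimate and the residual sum of
    squares.  Crosses whose expected segregation does not depend on alpha
    (e.g. AAAA x AAAA) are rejected as unidentifiable.
    """
    check_ploidy(v)
    p1 = canonical(parent1)
    p2 = canonical(parent2)
    if len(p1) != v or len(p2) != v:
        raise ValueError("parent genotypes must match the stated ploidy")
    d = v // 4
    n = sum(observed_segregation.values())
    if n <= 0:
        raise ValueError("at least one observed offspring is required")

    categories = sorted(
        set(observed_segregation) | set(cross(p1, p2, _interior_alpha(v)).offspring)
    )
    obs = np.array([observed_segregation.get(c, 0) / n for c in categories])

    # identifiability: the expected distribution must move somewhere on the simplex
    base = _expected_proportions(p1, p2, v, [0.0] * d, categories)
    varies = False
    for k in range(d):
        vertex = [0.0] * d
        vertex[k] = 1.0
        if not np.allclose(_expected_proportions(p1, p2, v, vertex, categories), base, atol=1e-15):
            varies = True
            break
    if not varies:
        raise ValueError("alpha unidentifiable from this cross")

    def objective(x):
        return float(np.sum((obs - _expected_proportions(p1, p2, v, x, categories)) ** 2))

    if d == 1:
        res = optimize.minimize_scalar(
            lambda x: objective([x]), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-14},
        )
        x_best = [float(res.x)]
        fun_best = float(res.fun)
    else:
        best = None
        starts = [np.full(d, 1.0 / (2 * (d + 1))), np.full(d, 1e-3), np.full(d, 0.3 / d)]
        for x0 in starts:
            res = optimize.minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * d,
                constraints=[{"type": "ineq", "fun": lambda x: 1.0 - float(np.sum(x))}],
                options={"ftol": 1e-18, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        x_best = [float(x) for x in best.x]
        fun_best = float(best.fun)
    if d >= 1:
        # Gauss-Newton polish on the residual vector; the scalar objective is
        # flat near its root, the vector form converges to machine precision
        ls = optimize.least_squares(
            lambda x: obs - _expected_proportions(p1, p2, v, x, categories),
            np.clip(x_best, 1e-12, 1 - 1e-12),
            bounds=(0.0, 1.0),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        if float(ls.cost) * 2.0 <= fun_best and float(np.sum(ls.x)) <= 1.0 + 1e-12:
            x_best = [float(x) for x in ls.x]
            fun_best = float(ls.cost) * 2.0
    a0 = 1.0 - sum(x_best)
    est = AlphaVector(v, (a0, *x_best))
    return est, fun_best


def _interior_alpha(v: int) -> AlphaVector:
    d = v // 4
    a = 1.0 / (2 * d + 1)
    return AlphaVector(v, (1.0 - d * a * 0.5, *([a * 0.5] * d)))
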