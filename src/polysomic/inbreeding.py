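"""Inbreeding coefficients and heterozygosity under double-reduction.

The inbreeding coefficient of a genotype is the probability that two
alleles sampled from it without replacement are identical-by-descent
(IBD); it is defined for zygotes (F, over C(v,2) allele pairs) and for
gametes (f, over C(v/2,2) pairs).  Double-reduction feeds IBD pairs into
gametes at rate lambda = sum_i i*alpha_i per gamete; inbreeding between
mates enters through the co-ancestry coefficient theta, the probability
that one allele drawn from each mate is IBD.

One generation of reproduction gives the recursion

    F' = [2 lambda + 2 F (C(v/2,2) - lambda) + theta v^2/4] / C(v,2)

whose fixed point is the equilibrium value

    F = (8 lambda + theta v^2) / (8 lambda + v^2),

and the gamete coefficient follows as

    f = [lambda + F (C(v/2,2) - lambda)] / C(v/2,2).

Heterozygosity (probability of sampling two non-identical-by-state
alleles) is H = (1 - F)(1 - sum_k p_k^2) for zygotes and the analogue with
f for gametes — the same identity as Nei's F_IS = (H_S - H_I)/H_S, so
standard F-statistics estimators remain applicable.  The factor
``1 - sum p_k^2`` is the probability that two independent draws from the
allele pool differ in state.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

from .dr_models import AlphaVector, lambda_of
from .genotypes import check_ploidy, validate_allele_frequencies

__all__ = [
    "InbreedingState",
    "equilibrium_F",
    "gamete_f",
    "transition_F",
    "heterozygosity",
    "theta_from_mixture",
    "inbreeding_state",
]


def _check_theta(theta):
    if theta < 0 or theta > 1:
        raise ValueError(f"co-ancestry coefficient theta must lie in [0, 1], got {theta!r}")


def equilibrium_F(lam, theta, v: int):
    """Zygote inbreeding coefficient at equilibrium.

    F = (8 lambda + theta v^2) / (8 lambda + v^2); exact for rational
    inputs.  At theta = 0 and lambda = 0 there is no inbreeding, F = 0.
    """
    check_ploidy(v)
    _check_theta(theta)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    num = 8 * lam + theta * v * v
    den = 8 * lam + v * v
    if isinstance(num, (int, Fraction)) and isinstance(den, (int, Fraction)):
        return Fraction(num, 1) / Fraction(den, 1)
    return num / den


def gamete_f(F, lam, v: int):
    """Gamete inbreeding coefficient f = [lambda + F (C(v/2,2) - lambda)] / C(v/2,2)."""
    check_ploidy(v)
    pairs = comb(v // 2, 2)
    if pairs == 0:
        raise ValueError("gamete has a single allele; f undefined for v = 2")
    num = lam + F * (pairs - lam)
    if isinstance(num, (int, Fraction)):
        return Fraction(num, 1) / pairs
    return num / pairs


def transition_F(F_prev, lam, theta, v: int):
    """One-generation update of the zygote inbreeding coefficient.

    Iterating to a fixed point reproduces :func:`equilibrium_F`; with
    lambda = theta = 0 any initial F decays geometrically to zero.
    """
    check_ploidy(v)
    _check_theta(theta)
    pairs_gamete = comb(v // 2, 2)
    num = 2 * lam + 2 * F_prev * (pairs_gamete - lam) + theta * (v * v // 4)
    den = comb(v, 2)
    if isinstance(num, (int, Fraction)):
        return Fraction(num, 1) / den
    return num / den


def heterozygosity(F_or_f, p: Sequence):
    """H = (1 - F)(1 - sum_k p_k^2): expected heterozygosity discounted by IBD."""
    validate_allele_frequencies(p)
    if F_or_f < 0 or F_or_f > 1:
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    h_exp = 1 - sum(x * x for x in p)
    return (1 - F_or_f) * h_exp


def theta_from_mixture(components: Sequence[tuple]) -> object:
    """Population co-ancestry as a weighted average over relationship classes.

    ``components`` is a sequence of (theta_of_relationship, weight) pairs
    with non-negative weights summing to one (e.g. 90% unrelated matings
    and 10% selfing).
    """
    if not components:
        raise ValueError("at least one relationship class is required")
    weights = [w for _, w in components]
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    total = sum(weights)
    ok = total == 1 if isinstance(total, (int, Fraction)) else abs(total - 1.0) <= 1e-12
    if not ok:
        raise ValueError(f"weights must sum to 1, got {total!r}")
    for th, _ in components:
        _check_theta(th)
    return sum(th * w for th, w in components)


@dataclass(frozen=True)
class InbreedingState:
    """Equilibrium inbreeding summary for one model/ploidy/theta combination."""

    v: int
    lam: object
    theta: object
    F: object
    f: object
    H: object | None = None
    h_gam: object | None = None


def inbreeding_state(alpha: AlphaVector, theta=0, p: Sequence | None = None) -> InbreedingState:
    """Bundle lambda, equilibrium F, f and (given allele frequencies) H.

    ``p`` is optional; without it the heterozygosities are None.
    """
    lam = lambda_of(alpha)
    F = equilibrium_F(lam, theta, alpha.v)
    f = gamete_f(F, lam, alpha.v)
    H = h_gam = None
    if p is not None:
        H = heterozygosity(F, p)
        h_gam = heterozygosity(f, p)
    return InbreedingState(v=alpha.v, lam=lam, theta=theta, F=F, f=f, H=H, h_gam=h_gam)
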