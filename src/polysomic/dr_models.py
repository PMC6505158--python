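"""Double-reduction coefficient vectors for the four segregation models.

Double-reduction is the meiotic event in which fragments of sister
chromatids segregate into the same gamete, so the gamete carries pairs of
identical-by-double-reduction (IBDR) alleles.  A gamete of a zygote of
ploidy ``v`` can carry at most ``floor(v/4)`` such pairs; the vector

    alpha = (alpha_0, alpha_1, ..., alpha_{floor(v/4)})

gives the probability that a gamete carries exactly ``i`` IBDR pairs, with
``sum_i alpha_i = 1``.  The four classical models are:

RCS   random chromosome segregation — no crossover between locus and
      centromere, alpha = (1, 0, ...), genotype frequencies stay at the
      multinomial Hardy-Weinberg values.
PRCS  pure random chromatid segregation — all 2v chromatids segregate
      independently; alpha follows from sampling v/2 chromatids out of 2v.
CES   complete equational segregation — pairing chromatid arms are always
      exchanged; alpha follows from the distribution mu_j of the number of
      intact chromosome pairs entering a secondary oocyte.
PES   partial equational segregation — CES generalised by the single
      chromatid recombination rate r_s, the probability that the allele on
      a chromatid is exchanged with its pairing chromatid.  PES reduces to
      RCS at r_s = 0 and to CES at r_s = 1.

All coefficients are exact `fractions.Fraction` values whenever the inputs
are rational.  The expected number of IBDR pairs per gamete is
``lambda = sum_i i * alpha_i``, with closed forms

    PRCS: v(v-2)/(16v-8)     CES: v(v-2)/(16v-16)    PES: r_s v(v-2)/(16v-16).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

from .genotypes import check_ploidy

MODELS = ("rcs", "prcs", "ces", "pes")

__all__ = [
    "MODELS",
    "AlphaVector",
    "ModelSpec",
    "alpha_rcs",
    "alpha_prcs",
    "mu_ces",
    "alpha_ces",
    "nu_pes",
    "alpha_pes",
    "alpha_for",
    "lambda_of",
    "r_from_rs",
    "rs_from_r",
    "haldane_rs",
]


@dataclass(frozen=True)
class AlphaVector:
    """Probabilities that a gamete carries 0..floor(v/4) IBDR allele pairs."""

    v: int
    alpha: tuple

    def __post_init__(self):
        check_ploidy(self.v)
        expected = self.v // 4 + 1
        alpha = tuple(self.alpha)
        object.__setattr__(self, "alpha", alpha)
        if len(alpha) != expected:
            raise ValueError(
                f"alpha vector for v={self.v} must have {expected} entries, got {len(alpha)}"
            )
        if any(a < 0 or a > 1 for a in alpha):
            raise ValueError("every alpha_i must lie in [0, 1]")
        total = sum(alpha)
        if isinstance(total, (int, Fraction)):
            if total != 1:
                raise ValueError(f"alpha must sum to 1 exactly, got {total}")
        elif abs(total - 1.0) > 1e-9:
            raise ValueError(f"alpha must sum to 1, got {total!r}")

    def __iter__(self):
        return iter(self.alpha)

    def __getitem__(self, i):
        return self.alpha[i]

    def __len__(self):
        return len(self.alpha)

    @property
    def lam(self):
        """Expected number of IBDR allele pairs per gamete, sum_i i*alpha_i."""
        return sum(i * a for i, a in enumerate(self.alpha))


@dataclass(frozen=True)
class ModelSpec:
    """A double-reduction model name plus its parameter (r_s for PES only)."""

    name: str
    rs: Fraction | float | None = None

    def __post_init__(self):
        name = self.name.lower()
        object.__setattr__(self, "name", name)
        if name not in MODELS:
            raise ValueError(f"unknown model {self.name!r}; choose one of {MODELS}")
        if name == "pes":
            if self.rs is None:
                raise ValueError("the PES model requires the single chromatid recombination rate r_s")
            _check_rs(self.rs)
        elif self.rs is not None:
            raise ValueError(f"r_s is only meaningful for the PES model, not {name!r}")

    def alpha(self, v: int) -> AlphaVector:
        return alpha_for(self.name, v, self.rs)


def _check_rs(rs) -> None:
    if rs < 0 or rs > 1:
        raise ValueError(f"r_s must lie in [0, 1], got {rs!r}")
    if rs > Fraction(1, 2):
        warnings.warn(
            "r_s above 0.5 exceeds the biological maximum of the single "
            "chromatid recombination rate; accepted for the algebraic CES limit",
            stacklevel=3,
        )


def alpha_rcs(v: int) -> AlphaVector:
    """RCS: no double-reduction, alpha_0 = 1."""
    check_ploidy(v)
    d = v // 4
    return AlphaVector(v, (Fraction(1),) + (Fraction(0),) * d)


def alpha_prcs(v: int) -> AlphaVector:
    """PRCS coefficients by chromatid sampling.

    alpha_i = C(v, v/2-i) C(v/2-i, i) 2^{v/2-2i} / C(2v, v/2):
    of the v duplicated-allele pairs, i whole pairs and v/2-2i singletons are
    drawn among the C(2v, v/2) equally likely chromatid subsets.
    """
    check_ploidy(v)
    half = v // 2
    denom = comb(2 * v, half)
    alpha = tuple(
        Fraction(comb(v, half - i) * comb(half - i, i) * 2 ** (half - 2 * i), denom)
        for i in range(v // 4 + 1)
    )
    return AlphaVector(v, alpha)


def mu_ces(v: int) -> tuple[Fraction, ...]:
    """Probability mu_j that j intact pairing-chromosome pairs (PCPs) enter a
    secondary oocyte.

    mu_j = 2^{v/2-2j} C(v/2, j) C(v/2-j, v/2-2j) / C(v, v/2) for
    0 <= j <= floor(v/4); the v/2 PCPs of the primary oocyte are split
    uniformly over the C(v, v/2) metaphase-I segregation modes.
    """
    check_ploidy(v)
    half = v // 2
    denom = comb(v, half)
    return tuple(
        Fraction(2 ** (half - 2 * j) * comb(half, j) * comb(half - j, half - 2 * j), denom)
        for j in range(v // 4 + 1)
    )


def alpha_ces(v: int) -> AlphaVector:
    """CES coefficients: alpha_i = sum_{j>=i} 2^{-j} mu_j C(j, i).

    Each of the j intact PCPs in the oocyte independently passes an IBDR
    pair to the gamete with probability 1/2.
    """
    mu = mu_ces(v)
    d = v // 4
    alpha = tuple(
        sum(Fraction(comb(j, i), 2**j) * mu[j] for j in range(i, d + 1)) for i in range(d + 1)
    )
    return AlphaVector(v, alpha)


def nu_pes(v: int, rs) -> tuple:
    """Probability nu_k that a secondary oocyte contains k exchanged PCPs.

    Each intact PCP is exchanged independently with probability r_s, so
    nu_k = sum_{j>=k} mu_j C(j, k) r_s^k (1-r_s)^{j-k}.
    """
    _check_rs(rs)
    if not isinstance(rs, float):
        rs = Fraction(rs)
    mu = mu_ces(v)
    d = v // 4
    one = 1 - rs
    return tuple(
        sum(mu[j] * comb(j, k) * rs**k * one ** (j - k) for j in range(k, d + 1))
        for k in range(d + 1)
    )


def alpha_pes(v: int, rs) -> AlphaVector:
    """PES coefficients: alpha_i = sum_{k>=i} 2^{-k} nu_k C(k, i).

    Only exchanged PCPs can deliver IBDR pairs; each does so with
    probability 1/2 independently.  Exact when r_s is rational.
    """
    nu = nu_pes(v, rs)
    d = v // 4
    alpha = tuple(
        sum(nu[k] * comb(k, i) * Fraction(1, 2**k) for k in range(i, d + 1)) for i in range(d + 1)
    )
    return AlphaVector(v, alpha)


def alpha_for(model: str, v: int, rs=None) -> AlphaVector:
    """Dispatch on the model name (rcs | prcs | ces | pes)."""
    model = model.lower()
    if model == "rcs":
        return alpha_rcs(v)
    if model == "prcs":
        return alpha_prcs(v)
    if model == "ces":
        return alpha_ces(v)
    if model == "pes":
        if rs is None:
            raise ValueError("the PES model requires r_s")
        return alpha_pes(v, rs)
    raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")


def lambda_of(alpha: AlphaVector):
    """Expected number of IBDR allele pairs per gamete."""
    return alpha.lam


def r_from_rs(rs, v: int):
    """Recombination fraction r = 1 - (1 - r_s)^{v/2}.

    With v/2 pairing chromosome pairs the recombination fraction saturates
    at 1 - 0.5^{v/2} when r_s = 0.5 (0.75 for autotetraploids).
    """
    check_ploidy(v)
    if rs < 0 or rs > 1:
        raise ValueError(f"r_s must lie in [0, 1], got {rs!r}")
    return 1 - (1 - rs) ** (v // 2)


def rs_from_r(r, v: int) -> float:
    """Inverse of :func:`r_from_rs`; round-trips within 1e-12."""
    check_ploidy(v)
    if r < 0 or r > 1:
        raise ValueError(f"recombination fraction r must lie in [0, 1], got {r!r}")
    return 1.0 - (1.0 - r) ** (2.0 / v)


def haldane_rs(d) -> float:
    """Haldane's mapping function r_s = (1 - exp(-2 d / 100)) / 2.

    ``d`` is the locus-centromere map distance in centimorgans; r_s
    approaches its maximum 0.5 as d grows.
    """
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))
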