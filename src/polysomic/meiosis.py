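"""Mechanistic meiosis enumeration — an independent oracle for the models.

This module re-derives gamete distributions and double-reduction vectors
by enumerating the meiotic mechanics directly, without the closed forms of
:mod:`polysomic.dr_models` or :mod:`polysomic.transition`:

* chromosomes pair into v/2 bivalents at the locus (all perfect matchings
  equally likely),
* each pairing exchanges chromatid arms at the locus with probability r_s
  (always for CES, never for RCS),
* chromosomes segregate into a secondary oocyte uniformly over the
  C(v, v/2) metaphase-I splits,
* each chromosome passes one of its two chromatids into the gamete
  (anaphase II), independently with probability 1/2,
* under PRCS all 2v chromatids instead segregate independently, so the
  gamete is a uniform draw of v/2 of them.

All randomness is replaced by exact rational weighting over the finite
configuration space, so agreement with the closed forms is exact and
seed-free.  Double-reduction is detected mechanically: it has occurred
whenever two sister chromatid copies of one parental allele end up in the
same gamete.

The argument order of ``G`` assigns allele copies to chromosomes; the
resulting distributions are invariant to that assignment.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from fractions import Fraction
from itertools import combinations, product
from math import comb
from typing import Sequence

from .dr_models import AlphaVector, ModelSpec
from .genotypes import check_ploidy

__all__ = ["oracle_mu", "oracle_alpha", "oracle_gamete_distribution"]

_MAX_ORACLE_PLOIDY = 8


def _perfect_matchings(items: tuple):
    if not items:
        yield ()
        return
    first = items[0]
    for k in range(1, len(items)):
        pair = (first, items[k])
        rest = items[1:k] + items[k + 1 :]
        for m in _perfect_matchings(rest):
            yield (pair,) + m


def _normalise_model(model, rs):
    if isinstance(model, ModelSpec):
        return model.name, model.rs
    name = str(model).lower()
    if name == "pes":
        if rs is None:
            raise ValueError("the PES model requires r_s")
    elif rs is not None:
        raise ValueError(f"r_s is only meaningful for PES, not {name!r}")
    return name, rs


def oracle_mu(v: int) -> tuple[Fraction, ...]:
    """mu_j by brute force: count intact bivalents over all metaphase-I splits.

    Fixes one pairing of the v chromosomes and enumerates the C(v, v/2)
    ways to fill a secondary oocyte, tallying how many pairs arrive intact.
    """
    check_ploidy(v)
    if v > 12:
        raise ValueError("oracle enumeration supports v <= 12; use mu_ces instead")
    half = v // 2
    pairs = [(2 * i, 2 * i + 1) for i in range(half)]
    tally = [0] * (v // 4 + 1)
    for split in combinations(range(v), half):
        inside = set(split)
        j = sum(1 for x, y in pairs if x in inside and y in inside)
        tally[j] += 1
    denom = comb(v, half)
    return tuple(Fraction(t, denom) for t in tally)


def _prcs_distribution(G: Sequence[int]):
    """Uniform draw of v/2 chromatids out of the 2v duplicated copies."""
    v = len(G)
    half = v // 2
    chromatids = [a for a in G for _ in range(2)]
    counts: Counter = Counter()
    for idx in combinations(range(2 * v), half):
        counts[tuple(sorted(chromatids[i] for i in idx))] += 1
    denom = comb(2 * v, half)
    return {g: Fraction(c, denom) for g, c in counts.items()}


def _rcs_distribution(G: Sequence[int]):
    """Uniform draw of v/2 whole chromosomes; no double-reduction possible."""
    v = len(G)
    half = v // 2
    counts: Counter = Counter()
    for idx in combinations(range(v), half):
        counts[tuple(sorted(G[i] for i in idx))] += 1
    denom = comb(v, half)
    return {g: Fraction(c, denom) for g, c in counts.items()}


def _ces_pes_distribution(G: Sequence[int], rs: Fraction):
    """Full enumeration of pairings x exchange masks x splits x chromatid picks."""
    v = len(G)
    half = v // 2
    matchings = list(_perfect_matchings(tuple(range(v))))
    splits = list(combinations(range(v), half))
    # integer tallies per number of exchanged pairings; the r_s weight is
    # applied once per class to keep the Fraction arithmetic off the hot loop
    counts_by_e: dict[int, Counter] = defaultdict(Counter)
    weight_by_e = [rs**e * (1 - rs) ** (half - e) for e in range(half + 1)]
    for matching in matchings:
        for mask in product((0, 1), repeat=half):
            e = sum(mask)
            if not weight_by_e[e]:
                continue
            chromatids = [None] * v
            for (x, y), exchanged in zip(matching, mask):
                if exchanged:
                    chromatids[x] = chromatids[y] = (G[x], G[y])
                else:
                    chromatids[x] = (G[x], G[x])
                    chromatids[y] = (G[y], G[y])
            tally = counts_by_e[e]
            for split in splits:
                options = [chromatids[c] for c in split]
                for choice in product(*options):
                    tally[tuple(sorted(choice))] += 1
    denom = len(matchings) * comb(v, half) * 2**half
    dist: dict[tuple, Fraction] = defaultdict(Fraction)
    for e, tally in counts_by_e.items():
        weight = rs**e * (1 - rs) ** (half - e)
        if not weight:
            continue
        for g, c in tally.items():
            dist[g] += weight * Fraction(c, denom)
    return {g: w for g, w in dist.items() if w}


def oracle_gamete_distribution(G: Sequence[int], model, rs=None) -> dict[tuple, Fraction]:
    """Exact gamete genotype distribution of one zygote by pure enumeration."""
    name, rs = _normalise_model(model, rs)
    v = len(G)
    check_ploidy(v)
    if v > _MAX_ORACLE_PLOIDY:
        raise ValueError(
            f"oracle enumeration supports v <= {_MAX_ORACLE_PLOIDY}; "
            "use the closed-form transition probabilities for larger ploidies"
        )
    if name == "rcs":
        return _rcs_distribution(G)
    if name == "prcs":
        return _prcs_distribution(G)
    if name == "ces":
        return _ces_pes_distribution(G, Fraction(1))
    rs = Fraction(rs)
    if rs < 0 or rs > 1:
        raise ValueError(f"r_s must lie in [0, 1], got {rs!r}")
    return _ces_pes_distribution(G, rs)


def oracle_alpha(v: int, model, rs=None) -> AlphaVector:
    """Double-reduction vector tallied from a fully heterozygous zygote.

    With v distinct allele copies, every repeated allele in a gamete can
    only have arisen from two sister chromatids, so the number of IBDR
    pairs is the number of repeats.  Matches the closed forms exactly.
    """
    check_ploidy(v)
    dist = oracle_gamete_distribution(tuple(range(v)), model, rs)
    half = v // 2
    alpha = [Fraction(0)] * (v // 4 + 1)
    for g, w in dist.items():
        alpha[half - len(set(g))] += w
    return AlphaVector(v, tuple(alpha))
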