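"""Transitional probability from zygote genotypes to gamete genotypes.

The central quantity is T(g|G): the probability that meiosis in a zygote of
genotype G (ploidy v) yields a gamete of genotype g (v/2 alleles), under a
given double-reduction vector alpha.  Writing n_k and m_k for the copy
numbers of allele k in G and g, and j_k for the number of IBDR pairs of
allele k in the gamete,

    T(g|G) = sum_i alpha_i / [C(v,i) C(v-i, v/2-2i)]
             * sum_{j_1+...+j_h = i} prod_k C(n_k, j_k) C(n_k-j_k, m_k-2j_k)

where each j_k is restricted to max(0, m_k-n_k) <= j_k <= min(n_k, m_k/2).
Every allele copy of G is duplicated during meiosis; j_k whole duplicated
pairs and m_k-2j_k single copies of allele k are packed into the gamete.
When the bounds leave no feasible j the probability is zero (for example a
gamete allele absent from the zygote).

The RCS and PRCS models admit direct sampling formulas which this module
also provides; they agree exactly with the weighted sum at the
corresponding alpha vectors.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np

from .dr_models import AlphaVector, alpha_prcs, alpha_rcs
from .genotypes import (
    Genotype,
    allele_counts,
    canonical,
    check_ploidy,
    enumerate_gametes,
    enumerate_genotypes,
)

__all__ = [
    "transition_probability",
    "transition_rcs",
    "transition_prcs",
    "TransitionMatrix",
]


def _check_pair(G, g):
    G = canonical(G)
    g = canonical(g)
    v = len(G)
    check_ploidy(v)
    if 2 * len(g) != v:
        raise ValueError(
            f"gamete size {len(g)} must be half the zygote ploidy {v}"
        )
    return G, g, v


def _composition_sum(bounds: list[tuple[int, int]], weights: list, i: int) -> int:
    """Sum over bounded compositions (j_1..j_h) of i of prod_k weights[k][j_k]."""

    # depth-first with remaining-capacity pruning; bounds are tight so the
    # search space stays tiny even for decasomic matrices
    total = 0
    n_alleles = len(bounds)
    lo_suffix = [0] * (n_alleles + 1)
    hi_suffix = [0] * (n_alleles + 1)
    for k in range(n_alleles - 1, -1, -1):
        lo_suffix[k] = lo_suffix[k + 1] + bounds[k][0]
        hi_suffix[k] = hi_suffix[k + 1] + bounds[k][1]

    def rec(k: int, remaining: int, acc: int):
        nonlocal total
        if k == n_alleles:
            if remaining == 0:
                total += acc
            return
        if remaining < lo_suffix[k] or remaining > hi_suffix[k]:
            return
        lo, hi = bounds[k]
        w = weights[k]
        for j in range(lo, min(hi, remaining) + 1):
            wj = w[j - lo]
            if wj:
                rec(k + 1, remaining - j, acc * wj)

    rec(0, i, 1)
    return total


def transition_probability(G: Sequence[int], g: Sequence[int], alpha: AlphaVector):
    """T(g|G) under an arbitrary double-reduction vector alpha.

    Exact (`Fraction`) when alpha is rational; returns 0 for gametes the
    zygote cannot produce (empty inner sum), including alleles absent
    from G.
    """
    G, g, v = _check_pair(G, g)
    if alpha.v != v:
        raise ValueError(f"alpha vector is for ploidy {alpha.v}, zygote has ploidy {v}")
    half = v // 2
    ncnt = Counter(G)
    mcnt = Counter(g)

    alleles = sorted(set(ncnt) | set(mcnt))
    bounds = []
    weights = []
    lo_total = 0
    hi_total = 0
    for k in alleles:
        n = ncnt.get(k, 0)
        m = mcnt.get(k, 0)
        lo = max(0, m - n)
        hi = min(n, m // 2)
        if lo > hi:
            return 0 * alpha.alpha[0]
        bounds.append((lo, hi))
        weights.append([comb(n, j) * comb(n - j, m - 2 * j) for j in range(lo, hi + 1)])
        lo_total += lo
        hi_total += hi

    total = 0
    for i, a in enumerate(alpha.alpha):
        if not a or i < lo_total or i > hi_total or half - 2 * i < 0:
            continue
        s = _composition_sum(bounds, weights, i)
        if s:
            denom = comb(v, i) * comb(v - i, half - 2 * i)
            if isinstance(a, Fraction):
                total += a * Fraction(s, denom)
            else:
                total += a * s / denom
    return total


def transition_rcs(G: Sequence[int], g: Sequence[int]):
    """T(g|G) under RCS: sampling v/2 of the v chromosomes,

    T = prod_k C(n_k, m_k) / C(v, v/2).
    """
    G, g, v = _check_pair(G, g)
    ncnt = Counter(G)
    num = 1
    for k, m in Counter(g).items():
        num *= comb(ncnt.get(k, 0), m)
        if num == 0:
            return Fraction(0)
    return Fraction(num, comb(v, v // 2))


def transition_prcs(G: Sequence[int], g: Sequence[int]):
    """T(g|G) under PRCS: sampling v/2 of the 2v chromatids,

    T = prod_k C(2 n_k, m_k) / C(2v, v/2).
    """
    G, g, v = _check_pair(G, g)
    ncnt = Counter(G)
    num = 1
    for k, m in Counter(g).items():
        num *= comb(2 * ncnt.get(k, 0), m)
        if num == 0:
            return Fraction(0)
    return Fraction(num, comb(2 * v, v // 2))


class TransitionMatrix:
    """Row-stochastic matrix T(g|G) over the canonical genotype enumerations.

    Rows are indexed by :func:`enumerate_genotypes`(v, h) and columns by
    :func:`enumerate_gametes`(v, h).  Rows are computed once per *dosage
    pattern* (the sorted copy-number vector) and transferred to all zygotes
    sharing the pattern by allele relabelling — T is invariant under
    permutations of allele labels — which keeps octosomic matrices with
    many alleles cheap.

    Entries are exact rationals in ``exact`` mode (sparse row dicts) and
    a dense float ``numpy`` array otherwise.
    """

    def __init__(
        self,
        v: int,
        h: int,
        alpha: AlphaVector,
        exact: bool = False,
        max_cells: int = 20_000_000,
    ):
        check_ploidy(v)
        if alpha.v != v:
            raise ValueError(f"alpha vector is for ploidy {alpha.v}, matrix requested for {v}")
        self.v = v
        self.h = h
        self.alpha = alpha
        self.exact = exact
        self.zygotes = enumerate_genotypes(v, h)
        self.gametes = enumerate_gametes(v, h)
        n_cells = len(self.zygotes) * len(self.gametes)
        if n_cells > max_cells:
            raise ValueError(
                f"transition matrix would hold {n_cells} cells, above the cap of "
                f"{max_cells}; raise max_cells explicitly to proceed"
            )
        self.zygote_index = {G: i for i, G in enumerate(self.zygotes)}
        self.gamete_index = {g: i for i, g in enumerate(self.gametes)}
        self._rows: list[dict] = []
        self._array: np.ndarray | None = None
        self._build()

    def _pattern_row(self, pattern_counts, cache):
        row = cache.get(pattern_counts)
        if row is None:
            pattern_G = tuple(
                a for a, n in enumerate(pattern_counts) for _ in range(n)
            )
            row = {}
            for g in self.gametes:
                t = transition_probability(pattern_G, g, self.alpha)
                if t:
                    row[g] = t
            cache[pattern_counts] = row
        return row

    def _build(self):
        h = self.h
        cache: dict[tuple, dict] = {}
        for G in self.zygotes:
            n = allele_counts(G, h)
            order = sorted(range(h), key=lambda k: (-n[k], k))
            pattern_counts = tuple(n[a] for a in order)
            prow = self._pattern_row(pattern_counts, cache)
            row = {
                tuple(sorted(order[r] for r in pg)): t for pg, t in prow.items()
            }
            self._rows.append(row)

    def row(self, G: Sequence[int]) -> dict:
        """Sparse gamete distribution of one zygote as {gamete: probability}."""
        return dict(self._rows[self.zygote_index[canonical(G)]])

    def probability(self, G: Sequence[int], g: Sequence[int]):
        return self._rows[self.zygote_index[canonical(G)]].get(canonical(g), 0)

    @property
    def array(self) -> np.ndarray:
        """Dense float matrix, shape (n_zygotes, n_gametes)."""
        if self._array is None:
            A = np.zeros((len(self.zygotes), len(self.gametes)))
            gidx = self.gamete_index
            for i, row in enumerate(self._rows):
                for g, t in row.items():
                    A[i, gidx[g]] = float(t)
            self._array = A
        return self._array


def transition_matrix(v: int, h: int, alpha: AlphaVector, **kwargs) -> TransitionMatrix:
    """Convenience constructor mirroring :class:`TransitionMatrix`."""
    return TransitionMatrix(v, h, alpha, **kwargs)
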