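"""Equilibrium genotype frequencies under random mating with double-reduction.

An infinite random-mating population is represented by its zygote genotype
frequency table (GFZ).  One generation is the composition of two linear
maps:

meiosis        Pr(g) = sum_G Pr(G) T(g|G)        (gamete table, GFG)
fertilisation  Pr(G) = sum_{g in distinct v/2-subsets of G}
                         Pr_egg(g) Pr_sperm(G \\ g)

Iterating from the Hardy-Weinberg multinomial start converges to the
equilibrium distorted by double-reduction; under RCS the HWE table is
already the fixed point.  Allele frequencies are conserved exactly by both
maps (meiosis is unbiased and there is no selection, mutation or
migration), which is checked on every run.

Maternal and paternal meioses may use different alpha vectors; the
fertilisation sum over all distinct sub-multisets is symmetric under the
complement involution, so the zygote table is well defined without extra
symmetrisation.

The default iteration is in floats with a dense precomputed transition
matrix; an exact rational mode is available for small (v, h), where every
finite-generation table is rational.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .dr_models import AlphaVector
from .genotypes import (
    Genotype,
    check_ploidy,
    enumerate_gametes,
    enumerate_genotypes,
    gamete_subsets,
    genotype_to_phenotype,
    hwe_frequencies,
    validate_allele_frequencies,
)
from .transition import TransitionMatrix

__all__ = [
    "EquilibriumResult",
    "gfg_from_gfz",
    "gfz_from_gfg",
    "phenotype_frequencies",
    "allele_frequencies_from",
    "iterate_equilibrium",
]


def _infer_h(freq: Mapping[Genotype, object]) -> int:
    return max(max(g) for g in freq) + 1


def _is_rational_table(freq: Mapping[Genotype, object]) -> bool:
    return all(isinstance(x, (int, Fraction)) for x in freq.values())


def gfg_from_gfz(
    gfz: Mapping[Genotype, object],
    alpha: AlphaVector,
    matrix: TransitionMatrix | None = None,
) -> dict[Genotype, object]:
    """One round of meiosis: gamete table from a zygote table.

    Pr(g) = sum_G Pr(G) T(g|G); mass-conserving.  A prebuilt
    :class:`TransitionMatrix` may be passed to avoid recomputation.
    """
    sizes = {len(G) for G in gfz}
    if len(sizes) != 1:
        raise ValueError("zygote table mixes ploidies")
    (v,) = sizes
    if v != alpha.v:
        raise ValueError(f"zygote table has ploidy {v} but alpha is for {alpha.v}")
    h = _infer_h(gfz)
    if matrix is None:
        matrix = TransitionMatrix(v, h, alpha, exact=_is_rational_table(gfz))
    out: dict[Genotype, object] = defaultdict(lambda: 0)
    for G, w in gfz.items():
        if not w:
            continue
        for g, t in matrix.row(G).items():
            out[g] = out[g] + w * t
    return dict(out)


def gfz_from_gfg(
    gfg_maternal: Mapping[Genotype, object],
    gfg_paternal: Mapping[Genotype, object] | None = None,
) -> dict[Genotype, object]:
    """Random fertilisation: zygote table from egg (and sperm) gamete tables.

    Equivalent to convolving the two gamete distributions: each zygote G
    collects Pr_egg(g) * Pr_sperm(G \\ g) over its distinct sub-multisets.
    """
    if gfg_paternal is None:
        gfg_paternal = gfg_maternal
    sizes = {len(g) for g in gfg_maternal} | {len(g) for g in gfg_paternal}
    if len(sizes) != 1:
        raise ValueError("gamete tables mix ploidies")
    out: dict[Genotype, object] = defaultdict(lambda: 0)
    for g1, w1 in gfg_maternal.items():
        if not w1:
            continue
        for g2, w2 in gfg_paternal.items():
            if not w2:
                continue
            G = tuple(sorted(g1 + g2))
            out[G] = out[G] + w1 * w2
    return dict(out)


def phenotype_frequencies(freq: Mapping[Genotype, object]) -> dict[tuple, object]:
    """Aggregate a genotype table by phenotype (set of distinct alleles)."""
    out: dict[tuple, object] = defaultdict(lambda: 0)
    for g, w in freq.items():
        ph = genotype_to_phenotype(g)
        out[ph] = out[ph] + w
    return dict(out)


def allele_frequencies_from(freq: Mapping[Genotype, object], h: int | None = None):
    """Allele frequencies implied by a genotype table: p_k = sum_G Pr(G) n_k/|G|."""
    if h is None:
        h = _infer_h(freq)
    acc = [0] * h
    rational = _is_rational_table(freq)
    for g, w in freq.items():
        size = len(g)
        for a in g:
            if rational:
                acc[a] = acc[a] + Fraction(w, 1) / size
            else:
                acc[a] = acc[a] + w / size
    return tuple(acc)


@dataclass
class EquilibriumResult:
    """Converged (or budget-exhausted) population state.

    gfg/gfz are genotype tables of gametes and zygotes; pfg/pfz their
    phenotype aggregations.  With distinct parental alpha vectors ``gfg``
    is the egg table and ``gfg_paternal`` the sperm table.
    """

    v: int
    h: int
    gfg: dict
    gfz: dict
    pfg: dict
    pfz: dict
    generations_run: int
    converged: bool
    max_abs_change: float
    gfg_paternal: dict | None = None


def iterate_equilibrium(
    p: Sequence,
    v: int,
    alpha: AlphaVector,
    alpha_paternal: AlphaVector | None = None,
    generations: int = 100,
    tolerance: float = 1e-12,
    exact: bool = False,
    max_cells: int = 20_000_000,
) -> EquilibriumResult:
    """Iterate meiosis and fertilisation from the HWE start.

    Runs at most ``generations`` cycles (default 100), stopping early when
    the L-infinity change of the zygote table drops below ``tolerance``.
    Non-convergence within the budget is reported via ``converged=False``,
    not an exception.
    """
    check_ploidy(v)
    validate_allele_frequencies(p)
    if alpha.v != v:
        raise ValueError(f"alpha vector is for ploidy {alpha.v}, population has {v}")
    if alpha_paternal is not None and alpha_paternal.v != v:
        raise ValueError("maternal and paternal alpha vectors must share the ploidy")
    h = len(p)
    if exact:
        return _iterate_exact(p, v, h, alpha, alpha_paternal, generations, tolerance, max_cells)
    return _iterate_float(p, v, h, alpha, alpha_paternal, generations, tolerance, max_cells)


def _fertilisation_arrays(zygotes, gamete_index):
    Z, E, S = [], [], []
    for zi, G in enumerate(zygotes):
        for sub, compl in gamete_subsets(G):
            Z.append(zi)
            E.append(gamete_index[sub])
            S.append(gamete_index[compl])
    return np.asarray(Z), np.asarray(E), np.asarray(S)


def _check_conservation(p, gfz, h):
    recovered = allele_frequencies_from(gfz, h)
    for pk, rk in zip(p, recovered):
        if abs(float(pk) - float(rk)) > 1e-10:
            raise RuntimeError(
                "allele frequencies drifted during iteration "
                f"(input {float(pk)!r}, recovered {float(rk)!r})"
            )


def _iterate_float(p, v, h, alpha, alpha_paternal, generations, tolerance, max_cells):
    zygotes = enumerate_genotypes(v, h)
    gametes = enumerate_gametes(v, h)
    gidx = {g: i for i, g in enumerate(gametes)}
    T_m = TransitionMatrix(v, h, alpha, max_cells=max_cells).array
    if alpha_paternal is None or alpha_paternal == alpha:
        T_p = T_m
        two_sexes = False
    else:
        T_p = TransitionMatrix(v, h, alpha_paternal, max_cells=max_cells).array
        two_sexes = True
    Z, E, S = _fertilisation_arrays(zygotes, gidx)

    hwe = hwe_frequencies(p, v)
    gfz = np.array([float(hwe[G]) for G in zygotes])
    gfg_m = gfz @ T_m
    gfg_p = gfg_m
    gens = 0
    diff = np.inf
    nz = len(zygotes)
    for gens in range(1, generations + 1):
        gfg_m = gfz @ T_m
        gfg_p = gfz @ T_p if two_sexes else gfg_m
        new = np.bincount(Z, weights=gfg_m[E] * gfg_p[S], minlength=nz)
        # the fertilisation map is quadratic, so a float mass deficit of
        # order eps would square every generation; renormalise to unit mass
        new /= new.sum()
        diff = float(np.max(np.abs(new - gfz)))
        gfz = new
        if diff < tolerance:
            break
    gfz_d = {G: float(x) for G, x in zip(zygotes, gfz)}
    gfg_d = {g: float(x) for g, x in zip(gametes, gfg_m)}
    _check_conservation(p, gfz_d, h)
    result = EquilibriumResult(
        v=v,
        h=h,
        gfg=gfg_d,
        gfz=gfz_d,
        pfg=phenotype_frequencies(gfg_d),
        pfz=phenotype_frequencies(gfz_d),
        generations_run=gens,
        converged=diff < tolerance,
        max_abs_change=diff,
        gfg_paternal={g: float(x) for g, x in zip(gametes, gfg_p)} if two_sexes else None,
    )
    return result


def _iterate_exact(p, v, h, alpha, alpha_paternal, generations, tolerance, max_cells):
    if not all(isinstance(x, (int, Fraction)) for x in p):
        raise ValueError("exact iteration requires rational allele frequencies")
    zygotes = enumerate_genotypes(v, h)
    subsets = {G: gamete_subsets(G) for G in zygotes}
    T_m = TransitionMatrix(v, h, alpha, exact=True, max_cells=max_cells)
    if alpha_paternal is None or alpha_paternal == alpha:
        T_p = T_m
        two_sexes = False
    else:
        T_p = TransitionMatrix(v, h, alpha_paternal, exact=True, max_cells=max_cells)
        two_sexes = True

    gfz = hwe_frequencies(p, v)
    gfg_m: dict = {}
    gfg_p: dict = {}
    gens = 0
    diff = float("inf")
    for gens in range(1, generations + 1):
        gfg_m = gfg_from_gfz(gfz, alpha, matrix=T_m)
        gfg_p = gfg_from_gfz(gfz, alpha_paternal, matrix=T_p) if two_sexes else gfg_m
        new = {}
        for G in zygotes:
            acc = Fraction(0)
            for sub, compl in subsets[G]:
                acc += Fraction(gfg_m.get(sub, 0)) * Fraction(gfg_p.get(compl, 0))
            new[G] = acc
        diff = max(abs(float(new[G] - Fraction(gfz.get(G, 0)))) for G in zygotes)
        gfz = new
        if diff < tolerance:
            break
    _check_conservation(p, gfz, h)
    return EquilibriumResult(
        v=v,
        h=h,
        gfg=gfg_m,
        gfz=gfz,
        pfg=phenotype_frequencies(gfg_m),
        pfz=phenotype_frequencies(gfz),
        generations_run=gens,
        converged=diff < tolerance,
        max_abs_change=diff,
        gfg_paternal=gfg_p if two_sexes else None,
    )
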