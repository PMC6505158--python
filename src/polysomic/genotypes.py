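"""Multiset genotypes, phenotypes and their combinatorics.

In polysomic inheritance an individual of ploidy ``v`` carries ``v`` allele
copies at a locus and its gametes carry ``v/2``.  A genotype is therefore a
*multiset* of alleles.  Throughout this package a genotype is represented as
a sorted (non-decreasing) tuple of 0-based allele indices — the canonical
form — so equality, hashing and enumeration order are all deterministic.
The display layer maps index 0 to ``A``, 1 to ``B`` and so on (``A1..An``
when more than 26 alleles are in play).

A *phenotype* is the set of distinct alleles observable in an individual
when allele dosage is unknown (electrophoretic band patterns): the
tetraploid genotypes AAAB, AABB and ABBB all display the phenotype AB.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from fractions import Fraction
from itertools import combinations, combinations_with_replacement
from math import comb, factorial
from typing import Iterable, Mapping, Sequence

Genotype = tuple  # sorted tuple of 0-based allele indices

_LONG_LABEL = re.compile(r"^A(\d+)$")

__all__ = [
    "Genotype",
    "check_ploidy",
    "canonical",
    "parse_genotype",
    "format_genotype",
    "allele_counts",
    "enumerate_genotypes",
    "enumerate_gametes",
    "genotype_to_phenotype",
    "gamete_subsets",
    "hwe_frequencies",
    "merge_alleles",
    "uniform_frequencies",
    "validate_allele_frequencies",
]


def check_ploidy(v: int) -> None:
    """Reject odd or non-positive ploidy.

    Organisms with odd ploidy cannot produce balanced euploid gametes and
    are outside the scope of every model in this package.
    """
    if not isinstance(v, int) or v < 2 or v % 2 != 0:
        raise ValueError(f"odd/invalid ploidy: {v!r} (ploidy must be a positive even integer)")


def canonical(alleles: Iterable[int]) -> Genotype:
    """Return the canonical (sorted) tuple form of a multiset of alleles."""
    g = tuple(sorted(int(a) for a in alleles))
    if not g:
        raise ValueError("a genotype must contain at least one allele")
    if g[0] < 0:
        raise ValueError("allele indices must be non-negative")
    return g


def _letter_index(label: str) -> int:
    head = label[0]
    if "A" <= head <= "Z" and (len(label) == 1 or label[1:].isdigit()):
        return ord(head) - ord("A")
    raise ValueError(f"unrecognised allele label {label!r}")


def parse_genotype(text: str) -> Genotype:
    """Parse a genotype string such as ``"AABC"`` or ``"A1,A1,B2"``.

    Two syntaxes are accepted: concatenated single letters (A-Z), and
    comma-separated labels.  In the comma-separated form, labels that are
    all of the shape ``A<k>`` address the k-th allele directly (the display
    form used when more than 26 alleles are in play); otherwise the leading
    letter names the allele and any trailing digits are a variant tag
    (``B2`` is allele B).
    """
    text = text.strip()
    if not text:
        raise ValueError("empty genotype string")
    if "," in text:
        labels = [lab.strip() for lab in text.split(",")]
        if all(_LONG_LABEL.match(lab) for lab in labels):
            return canonical(int(lab[1:]) - 1 for lab in labels)
        return canonical(_letter_index(lab) for lab in labels)
    return canonical(_letter_index(c) for c in text)


def format_genotype(g: Sequence[int], h: int | None = None) -> str:
    """Render a genotype in display form (``AABC``, or ``A1,A1,A3`` for h > 26)."""
    if h is None:
        h = max(g) + 1
    if h <= 26:
        return "".join(chr(ord("A") + a) for a in g)
    return ",".join(f"A{a + 1}" for a in g)


def allele_counts(g: Sequence[int], h: int) -> tuple[int, ...]:
    """Dosage vector: number of copies of each of the ``h`` alleles in ``g``."""
    n = [0] * h
    for a in g:
        if a >= h:
            raise ValueError(f"allele index {a} out of range for h={h}")
        n[a] += 1
    return tuple(n)


def enumerate_genotypes(v: int, h: int) -> list[Genotype]:
    """All C(v+h-1, v) zygote genotypes of ploidy ``v`` over ``h`` alleles.

    Returned in lexicographic order of the canonical tuples; this order
    indexes the rows of transition matrices and frequency vectors.
    """
    check_ploidy(v)
    if h < 1:
        raise ValueError("the number of alleles h must be at least 1")
    return list(combinations_with_replacement(range(h), v))


def enumerate_gametes(v: int, h: int) -> list[Genotype]:
    """All C(v/2+h-1, v/2) gamete genotypes for zygote ploidy ``v``."""
    check_ploidy(v)
    if h < 1:
        raise ValueError("the number of alleles h must be at least 1")
    return list(combinations_with_replacement(range(h), v // 2))


def genotype_to_phenotype(g: Sequence[int]) -> tuple[int, ...]:
    """Distinct alleles of a genotype, sorted (the observable band pattern)."""
    return tuple(sorted(set(g)))


def gamete_subsets(G: Sequence[int]) -> list[tuple[Genotype, Genotype]]:
    """All distinct sub-multisets of ``G`` of size ``v/2`` with their complements.

    For G = AAAB the distinct 2-subsets are {A,A} and {A,B}, paired with the
    complementary multisets {A,B} and {A,A}.  Each distinct subset appears
    exactly once (multiplicity-free), and ``sub + complement == G`` as
    multisets for every returned pair.
    """
    G = canonical(G)
    v = len(G)
    check_ploidy(v)
    half = v // 2
    seen: dict[Genotype, Genotype] = {}
    for idx in combinations(range(v), half):
        sub = tuple(G[i] for i in idx)
        if sub in seen:
            continue
        idxset = set(idx)
        seen[sub] = tuple(G[i] for i in range(v) if i not in idxset)
    return sorted(seen.items())


def validate_allele_frequencies(p: Sequence) -> None:
    """Check that allele frequencies are non-negative and sum to one.

    Rational input must sum to 1 exactly; float input within 1e-12.
    Zero-frequency alleles are permitted.
    """
    if len(p) < 1:
        raise ValueError("at least one allele frequency is required")
    if any(x < 0 for x in p):
        raise ValueError("allele frequencies must be non-negative")
    total = sum(p)
    if isinstance(total, (int, Fraction)):
        if total != 1:
            raise ValueError(f"allele frequencies must sum to 1 exactly, got {total}")
    elif abs(total - 1.0) > 1e-12:
        raise ValueError(f"allele frequencies must sum to 1 (within 1e-12), got {total!r}")


def uniform_frequencies(h: int) -> tuple[Fraction, ...]:
    """Equifrequent alleles: p_k = 1/h as exact rationals."""
    if h < 1:
        raise ValueError("h must be positive")
    return (Fraction(1, h),) * h


def hwe_frequencies(p: Sequence, v: int) -> dict[Genotype, object]:
    """Multinomial (Hardy-Weinberg) zygote genotype frequencies.

    Under random chromosome segregation the v allele copies of a zygote are
    independent draws from the allele pool, so

        Pr(G) = v! / (n_1! ... n_h!) * prod_k p_k^{n_k},

    e.g. the tetraploid genotype AABC has frequency 12 p_A^2 p_B p_C.
    Exact when ``p`` holds rationals.
    """
    check_ploidy(v)
    validate_allele_frequencies(p)
    h = len(p)
    out: dict[Genotype, object] = {}
    fact_v = factorial(v)
    for G in enumerate_genotypes(v, h):
        n = allele_counts(G, h)
        coef = fact_v
        for nk in n:
            coef //= factorial(nk)
        prob = coef
        for pk, nk in zip(p, n):
            if nk:
                prob = prob * pk**nk
        out[G] = prob if not isinstance(prob, int) else prob * 1
    return out


def merge_alleles(freq: Mapping[Genotype, object], mapping: Mapping[int, int]) -> dict[Genotype, object]:
    """Pool alleles of a frequency table according to ``mapping``.

    Alleles absent from ``mapping`` map to themselves.  The frequency of a
    merged genotype is the sum over its pre-images, so total mass is
    preserved.  This models a locus observed at a coarser allelic
    resolution, e.g. two alleles sharing an electromorph.
    """
    out: dict[Genotype, object] = defaultdict(lambda: 0)
    for g, val in freq.items():
        ng = tuple(sorted(mapping.get(a, a) for a in g))
        out[ng] = out[ng] + val
    return dict(out)


def multiset_difference(G: Sequence[int], g: Sequence[int]) -> Genotype:
    """Multiset difference G \\ g; raises if g is not a sub-multiset of G."""
    c = Counter(G)
    c.subtract(Counter(g))
    if any(x < 0 for x in c.values()):
        raise ValueError(f"{g!r} is not a sub-multiset of {G!r}")
    return canonical(c.elements())
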