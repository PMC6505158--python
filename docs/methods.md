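# Methods

## Scope and assumptions

The package models a single autosomal locus in an organism with fully
polysomic inheritance at an even ploidy `v` (odd ploidies are rejected:
they cannot form balanced euploid gametes). The population model is the
idealised one under which equilibrium frequencies are meaningful: infinite
size, random mating, non-overlapping generations, no selection, mutation
or migration, equal double-reduction parameters in the two sexes unless
distinct maternal/paternal alpha vectors are supplied explicitly.
Chromosomes are assumed to form multivalents; bivalent/univalent mixtures
and segmental allopolyploidy (disomic–polysomic mosaics) are out of scope,
as is any symbolic closed-form solution of the equilibrium — equilibria
here are numeric fixed points.

Genotypes are multisets, represented as sorted tuples of 0-based allele
indices; enumeration order is lexicographic on these tuples and indexes
every matrix and table. Phenotypes are allele sets (dosage unobserved).
Display uses letters `A…Z`, switching to `A1…An` beyond 26 alleles.

## Double-reduction models

A gamete of a `v`-ploid zygote carries at most `⌊v/4⌋` IBDR pairs.
Each model is reduced to its alpha vector:

| model | α derivation | λ = Σ i·α_i |
|-------|--------------|-------------|
| RCS   | α₀ = 1 | 0 |
| PRCS  | sampling v/2 chromatids from 2v | v(v−2)/(16v−8) |
| CES   | μ_j (intact pairings per oocyte), each passes an IBDR pair w.p. ½ | v(v−2)/(16v−16) |
| PES   | CES with each pairing exchanged w.p. r_s | r_s·v(v−2)/(16v−16) |

All α computations use exact `fractions.Fraction` arithmetic; floats
appear only in the fixed-point iteration and presentation layers. The
λ closed forms above are asserted exactly in the tests for v = 4…12.

`r_s` is accepted on `[0, 1]` although 0.5 is the biological maximum (a
locus infinitely far from the centromere); values above 0.5 trigger a
warning rather than an error because the algebraic limit PES(1) = CES is
useful for testing. `v = 2` is accepted everywhere and degenerates to
disomic HWE (α = (1,)). Map distances convert to `r_s` through Haldane's
function only; no other mapping function is provided.

## Transition probability

`T(g|G)` enumerates bounded compositions `(j_1…j_h)` of the IBDR pair
count `i`, with per-allele bounds `max(0, m_k−n_k) ≤ j_k ≤ min(n_k,
⌊m_k/2⌋)` taken directly from the combinatorial constraints; infeasible
bounds short-circuit to probability zero (in particular, gamete alleles
absent from the zygote give 0, never an error — callers iterate over all
gametes). The RCS and PRCS sampling formulas are implemented separately
and agree with the weighted sum exactly; this equivalence is a test, not
an implementation shortcut.

Transition matrices are row-stochastic over the canonical enumerations.
Rows are computed once per dosage pattern (the sorted copy-number vector
of the zygote) and transferred to all zygotes sharing that pattern by
permuting allele labels — `T` is invariant under relabelling, which the
suite checks property-style. This makes the octosomic 6435 × 330 matrix
(v = 8, h = 8) a ~1 s computation instead of millions of weighted-sum
evaluations. A configurable cell cap (default 2·10⁷) guards memory.

## Equilibrium iteration

One generation is meiosis (`Pr(g) = Σ_G Pr(G) T(g|G)`) followed by random
fertilisation (`Pr(G) = Σ Pr_egg(g) Pr_sperm(G∖g)` over the distinct
`v/2`-sub-multisets `g` of `G`). With distinct maternal and paternal
alpha vectors no extra symmetrisation is needed: the complement map is an
involution on the distinct sub-multisets, so the sum is already symmetric
in the two tables and mass-conserving.

Numerical choices:

- Default budget 100 generations with early stop when the L∞ change of
  the zygote table falls below 1e−12; in practice all models converge in
  ~20 generations at v = 4 and ~25 at v = 8. Non-convergence sets a flag
  instead of raising.
- The float path renormalises the zygote table to unit mass each
  generation. The exact map conserves mass, but fertilisation is
  quadratic in the table, so an O(ε) float deficit squares every
  generation and would annihilate the table after ~40 generations;
  renormalisation removes exactly that artefact.
- Allele-frequency conservation (`p_k = Σ_G Pr(G) n_k/v` unchanged from
  the input) is verified to 1e−10 after every run and raised on failure —
  it is the cheapest global detector of transition-matrix defects.
- An exact rational mode is available (intended for small `v`, `h`); each
  finite generation is then an exact rational table. It is what the
  RCS-equilibrium-equals-HWE identity is asserted against, exactly.
- Fertilisation is vectorised as a `bincount` over precomputed
  (zygote, egg, sperm) index triples; the transition matrix is built once
  per (v, h, α).

Problem sizes used by the validation suite and the acceptance script:
v = 4 and v = 6 with h = v everywhere, and v = 8 with h = 8 (6435
zygotes × 330 gametes) for the octosomic equilibrium rows — a few seconds
per model. Decasomic equilibria run through the same code path but are
not part of the default suite.

## Inbreeding and heterozygosity

`λ` feeds the recursion `F′ = [2λ + 2F(C(v/2,2)−λ) + θv²/4]/C(v,2)`,
whose fixed point `F = (8λ+θv²)/(8λ+v²)` and the gamete coefficient
`f = [λ + F(C(v/2,2)−λ)]/C(v/2,2)` are implemented directly; the suite
verifies fixed-point consistency and the geometric decay of `F` when
λ = θ = 0. `θ` is a user-supplied scalar (0 for an outcrossed
population), optionally assembled as a weighted average over relationship
classes; relationship-specific derivations of θ are not reproduced.

Heterozygosity is implemented as `H = (1−F)(1−Σ_k p_k²)`: the second
factor is the probability that two independent draws from the allele pool
differ in state, which is the only reading consistent with defining
heterozygosity as "two non-IBS alleles sampled without replacement" and
with the Nei-style identity `F_IS = (H_S−H_I)/H_S` (asserted in the
tests). Printed-table comparisons round half-up to four decimals, the
convention of the published tables (relevant at the exact tie
f = 5/32 = 0.15625 → 0.1563).

## The meiosis oracle

The oracle is enumerative, not Monte Carlo: pairings (all perfect
matchings of the v chromosomes), exchange masks (weighted
`r_s^e(1−r_s)^{…}`), metaphase-I splits (`C(v, v/2)`), and anaphase-II
chromatid picks (`2^{v/2}`) are enumerated with exact rational weights,
so oracle-versus-closed-form equality is exact and seed-free. Allele
copies are tracked per chromatid, so an IBDR pair is detected
mechanically (two sister chromatids in one gamete) rather than inferred.
Integer tallies are grouped by the number of exchanged pairings so the
rational weights touch each class once, keeping the octosomic PES
enumeration (~1.9·10⁶ configurations) under a second. Enumeration is
guarded at v ≤ 8 (v ≤ 12 for μ); beyond that the closed forms are the
only practical route. The exchange geometry is deliberately minimal: one
potential exchange event per pairing at probability r_s, no intra-arm
position model and no chiasma interference — the same abstraction the
PES derivation itself uses.

What oracle agreement does and does not show: it validates the
combinatorial derivations (α, T) against an independent mechanical model
of the *same* idealised meiosis; it says nothing about organisms whose
meioses violate the multivalent assumption.

## Applications

- `cross` convolves two parental gamete distributions; exact rational
  output admits smallest-integer segregation ratios.
- `offspring_probability` sums `T(g|father)·T(G∖g|mother)` over distinct
  sub-multisets (population gamete frequencies replace the mother term
  when she is unknown). As with fertilisation, the involution on subsets
  makes the expression symmetric in the parents without double counting.
- Goodness of fit: Pearson χ² and the likelihood-ratio G statistic with
  `df = (#categories with E>0) − 1` against the χ² upper tail;
  zero-observed cells contribute 0 to G, a positive count in a
  zero-expectation category flags an infinite statistic. No df correction
  is applied for parameters estimated from the same data — documented
  limitation, left to the user.
- `estimate_alpha` minimises the squared distance between observed and
  expected segregation proportions over the α simplex: bounded Brent for
  one free parameter, SLSQP from several starts for more, then a bounded
  Gauss–Newton (`least_squares`) polish — the scalar objective is
  extremely flat near its root and the polish is what reaches machine
  precision on exact proportions. Crosses whose expected segregation is
  α-independent are rejected as unidentifiable (detected by probing the
  simplex vertices).

## Known limitations

- Equilibria are numeric fixed points; no symbolic genotype-frequency
  expressions are produced.
- The iteration scales as (number of zygotes) × (number of gametes);
  dodecasomic loci with many alleles exceed the default cell cap by
  design and need explicit overrides and patience.
- Estimating `F` from observed genotype data, EM allele-frequency
  estimation from phenotypes, linkage machinery beyond the single-locus
  tests, and full parentage pipelines are out of scope; the package
  supplies the probability primitives such methods need.
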