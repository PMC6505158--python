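"""Double-reduction coefficients for every model across ploidy levels.

Builds the alpha vector (probabilities of 0, 1, ... pairs of
identical-by-double-reduction alleles per gamete) for each segregation
model, plus the expected IBDR pair count lambda.  alpha_1 is the classical
"double-reduction rate": 0 under RCS, 1/7 under PRCS and 1/6 under CES for
autotetraploids.
"""

from fractions import Fraction

from polysomic import alpha_for, lambda_of

for v in (4, 6, 8):
    print(f"ploidy v = {v}")
    for model, rs in [("rcs", None), ("prcs", None), ("ces", None), ("pes", Fraction(1, 2))]:
        a = alpha_for(model, v, rs)
        label = model if rs is None else f"{model}(rs={rs})"
        alphas = ", ".join(f"alpha_{i}={x}" for i, x in enumerate(a.alpha))
        print(f"  {label:<12} {alphas}   lambda={lambda_of(a)}")
    print()
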