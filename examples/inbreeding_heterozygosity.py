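"""How double-reduction mimics inbreeding, by model and ploidy level.

Prints the equilibrium inbreeding coefficients of zygotes (F) and gametes
(f) in an outcrossed population (theta = 0), and the zygote heterozygosity
for four equifrequent alleles.  F falls with ploidy within a model and
peaks at 1/13 ~ 0.0769 for tetrasomic CES.
"""

from fractions import Fraction

from polysomic import alpha_for, inbreeding_state, uniform_frequencies

p = uniform_frequencies(4)
print(f"{'model':<12}{'v':>4}{'lambda':>10}{'F':>10}{'f':>10}{'H':>10}")
for model, rs in [("prcs", None), ("ces", None), ("pes", Fraction(1, 2))]:
    for v in (4, 6, 8, 10, 12):
        st = inbreeding_state(alpha_for(model, v, rs), p=p)
        label = model if rs is None else f"{model}(.5)"
        print(
            f"{label:<12}{v:>4}{float(st.lam):>10.4f}{float(st.F):>10.4f}"
            f"{float(st.f):>10.4f}{float(st.H):>10.4f}"
        )
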