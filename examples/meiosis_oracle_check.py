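"""Cross-check the closed-form theory against brute-force meiosis enumeration.

The oracle enumerates chromosome pairings, chromatid-arm exchanges,
metaphase-I splits and anaphase-II chromatid picks with exact rational
weights, and tallies gametes mechanically.  Its distributions must equal
the weighted-sum transition probability exactly — no tolerance involved.
"""

from fractions import Fraction

from polysomic import alpha_for, format_genotype, gamete_distribution, oracle_alpha, oracle_gamete_distribution, parse_genotype

G = parse_genotype("AAABBC")
for model, rs in [("prcs", None), ("ces", None), ("pes", Fraction(1, 2))]:
    mech = oracle_gamete_distribution(G, model, rs)
    closed = gamete_distribution(G, alpha_for(model, 6, rs))
    label = model if rs is None else f"{model}(rs={rs})"
    print(f"{label}: oracle == closed form for AAABBC? {mech == closed}")

a_mech = oracle_alpha(8, "ces")
a_closed = alpha_for("ces", 8)
print(f"octosomic CES alpha by enumeration: {a_mech.alpha} (match: {a_mech.alpha == a_closed.alpha})")
dist = oracle_gamete_distribution(parse_genotype("ABCD"), "prcs")
print(f"PRCS ABCD -> AA (pure double-reduction gamete): {dist[parse_genotype('AA')]}")
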