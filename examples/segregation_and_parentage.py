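"""Segregation ratios in crosses and double-reduction in parentage analysis.

Selfing the duplex tetraploid AABB gives the classical F2 ratio
1:8:18:8:1 without double-reduction; under CES the ratio shifts to
4:20:33:20:4.  Double-reduction also lets ABCD x EFGH produce an AAEE
offspring, which a naive exclusion rule would call impossible.
"""

from polysomic import alpha_ces, alpha_rcs, cross, format_genotype, offspring_probability, parse_genotype

AABB = parse_genotype("AABB")
for name, alpha in [("RCS", alpha_rcs(4)), ("CES", alpha_ces(4))]:
    ratio = cross(AABB, AABB, alpha).ratio()
    pretty = " : ".join(f"{format_genotype(g)} {c}" for g, c in ratio)
    print(f"AABB selfed under {name}: {pretty}")

off, dad, mom = parse_genotype("AAEE"), parse_genotype("ABCD"), parse_genotype("EFGH")
for name, alpha in [("RCS", alpha_rcs(4)), ("CES", alpha_ces(4))]:
    pr = offspring_probability(off, dad, mom, alpha=alpha)
    print(f"Pr(offspring AAEE | ABCD x EFGH, {name}) = {pr}")
print("Under RCS the parent pair is (wrongly) excluded; CES explains the")
print("offspring through one double-reduction event in each parent.")
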