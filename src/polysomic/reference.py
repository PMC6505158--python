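"""Frozen reference values for the validation suite and the `fixtures` command.

These are the standard published benchmark quantities for the
double-reduction models from tetrasomic through dodecasomic inheritance:
exact alpha fractions, equilibrium inbreeding coefficients at theta = 0
(rounded to four decimals, PES evaluated at r_s = 0.5), the symbolic
octosomic biallelic transition table, and equilibrium gamete/phenotype
frequencies for uniform allele frequencies with h = v (exact fractions for
the tetrasomic cases, five-significant-digit decimals otherwise).

Nothing in this module is computed by the package; the test suite compares
the package's output against these constants.
"""

from fractions import Fraction as F

# -- alpha coefficients (alpha_1, alpha_2, ...) ------------------------------

PRCS_ALPHA = {
    4: (F(1, 7),),
    6: (F(3, 11),),
    8: (F(24, 65), F(1, 65)),
    10: (F(140, 323), F(15, 323)),
    12: (F(1440, 3059), F(270, 3059), F(5, 3059)),
}

CES_ALPHA = {
    4: (F(1, 6),),
    6: (F(3, 10),),
    8: (F(27, 70), F(3, 140)),
    10: (F(55, 126), F(5, 84)),
    12: (F(285, 616), F(65, 616), F(5, 1848)),
}

# PES alpha_1 is linear in r_s for v = 4, 6: alpha_1 = PES_ALPHA1_SLOPE[v] * r_s
PES_ALPHA1_SLOPE = {4: F(1, 6), 6: F(3, 10)}

# -- equilibrium inbreeding coefficients at theta = 0 ------------------------
# (model, v) -> (F, f) rounded to 4 decimals; PES evaluated at r_s = 1/2

INBREEDING_DECIMALS = {
    ("prcs", 4): (0.0667, 0.2000),
    ("prcs", 6): (0.0571, 0.1429),
    ("prcs", 8): (0.0476, 0.1111),
    ("prcs", 10): (0.0404, 0.0909),
    ("prcs", 12): (0.0350, 0.0769),
    ("ces", 4): (0.0769, 0.2308),
    ("ces", 6): (0.0625, 0.1563),
    ("ces", 8): (0.0508, 0.1186),
    ("ces", 10): (0.0426, 0.0957),
    ("ces", 12): (0.0365, 0.0803),
    ("pes", 4): (0.0400, 0.1200),
    ("pes", 6): (0.0323, 0.0806),
    ("pes", 8): (0.0261, 0.0609),
    ("pes", 10): (0.0217, 0.0489),
    ("pes", 12): (0.0186, 0.0409),
}

# exact counterparts for PRCS/CES (F, f)
INBREEDING_FRACTIONS = {
    ("prcs", 4): (F(1, 15), F(1, 5)),
    ("prcs", 6): (F(2, 35), F(1, 7)),
    ("prcs", 8): (F(1, 21), F(1, 9)),
    ("prcs", 10): (F(4, 99), F(1, 11)),
    ("prcs", 12): (F(5, 143), F(1, 13)),
    ("ces", 4): (F(1, 13), F(3, 13)),
    ("ces", 6): (F(1, 16), F(5, 32)),
    ("ces", 8): (F(3, 59), F(7, 59)),
    ("ces", 10): (F(2, 47), F(9, 94)),
    ("ces", 12): (F(5, 137), F(11, 137)),
}

# -- octosomic biallelic transition table ------------------------------------
# zygote string -> (divisor, {gamete string: (c0, c1, c2)}) meaning
# T(g|G) = (c0 alpha_0 + c1 alpha_1 + c2 alpha_2) / divisor

OCTOSOMIC_BIALLELIC_TABLE = {
    "AAAAAAAA": (1, {"AAAA": (1, 1, 1)}),
    "AAAAAAAB": (8, {"AAAA": (4, 5, 6), "AAAB": (4, 2, 0), "AABB": (0, 1, 2)}),
    "AAAAAABB": (
        28,
        {
            "AAAA": (6, 10, 15),
            "AAAB": (16, 10, 0),
            "AABB": (6, 6, 12),
            "ABBB": (0, 2, 0),
            "BBBB": (0, 0, 1),
        },
    ),
    "AAAAABBB": (
        56,
        {
            "AAAA": (4, 10, 20),
            "AAAB": (24, 20, 0),
            "AABB": (24, 15, 30),
            "ABBB": (4, 10, 0),
            "BBBB": (0, 1, 6),
        },
    ),
    "AAAABBBB": (
        70,
        {
            "AAAA": (1, 5, 15),
            "AAAB": (16, 20, 0),
            "AABB": (36, 20, 40),
            "ABBB": (16, 20, 0),
            "BBBB": (1, 5, 15),
        },
    ),
    "AAABBBBB": (
        56,
        {
            "AAAA": (0, 1, 6),
            "AAAB": (4, 10, 0),
            "AABB": (24, 15, 30),
            "ABBB": (24, 20, 0),
            "BBBB": (4, 10, 20),
        },
    ),
    "AABBBBBB": (
        28,
        {
            "AAAA": (0, 0, 1),
            "AAAB": (0, 2, 0),
            "AABB": (6, 6, 12),
            "ABBB": (16, 10, 0),
            "BBBB": (6, 10, 15),
        },
    ),
    "ABBBBBBB": (8, {"AABB": (0, 1, 2), "ABBB": (4, 2, 0), "BBBB": (4, 5, 6)}),
    "BBBBBBBB": (1, {"BBBB": (1, 1, 1)}),
}

# -- equilibrium gamete frequencies (uniform p, h = v) ------------------------
# (v, gamete string, model) -> value; tetrasomic entries are exact fractions,
# the rest five-significant-digit decimals.  PES at r_s = 1/2.

GAMETE_EQUILIBRIUM = {
    (4, "AA", "prcs"): F(1, 10),
    (4, "AB", "prcs"): F(1, 10),
    (4, "AA", "ces"): F(11, 104),
    (4, "AB", "ces"): F(5, 52),
    (4, "AA", "pes"): F(17, 200),
    (4, "AB", "pes"): F(11, 100),
    (6, "AAA", "prcs"): 1.6106e-2,
    (6, "AAB", "prcs"): 1.8908e-2,
    (6, "ABC", "prcs"): 1.6807e-2,
    (6, "AAA", "ces"): 1.7347e-2,
    (6, "AAB", "ces"): 1.9279e-2,
    (6, "ABC", "ces"): 1.5877e-2,
    (6, "AAA", "pes"): 1.0720e-2,
    (6, "AAB", "pes"): 1.6955e-2,
    (6, "ABC", "pes"): 2.1351e-2,
    (8, "AAAA", "prcs"): 2.3549e-3,
    (8, "AAAB", "prcs"): 2.8786e-3,
    (8, "AABB", "prcs"): 3.6414e-3,
    (8, "AABC", "prcs"): 3.1713e-3,
    (8, "ABCD", "prcs"): 2.6461e-3,
    (8, "ABCD", "ces"): 2.4917e-3,
    (8, "ABCD", "pes"): 3.9370e-3,
}

# exact fractions for the hexasomic PRCS column (reduced forms)
GAMETE_EQUILIBRIUM_FRACTIONS_V6_PRCS = {
    "AAA": F(23, 1428),
    "AAB": F(9, 476),
    "ABC": F(2, 119),
}

# -- equilibrium zygote phenotype frequencies (uniform p, h = v) --------------
# (v, phenotype string, model) -> value; PES at r_s = 1/2

PHENOTYPE_EQUILIBRIUM = {
    (4, "A", "prcs"): F(1, 100),
    (4, "AB", "prcs"): F(7, 100),
    (4, "ABC", "prcs"): F(3, 25),
    (4, "ABCD", "prcs"): F(3, 50),
    (4, "A", "ces"): F(121, 10816),
    (4, "AB", "ces"): F(391, 5408),
    (4, "ABC", "ces"): F(315, 2704),
    (4, "ABCD", "ces"): F(75, 1352),
    (4, "A", "pes"): F(289, 40000),
    (4, "AB", "pes"): F(1279, 20000),
    (4, "ABC", "pes"): F(1287, 10000),
    (4, "ABCD", "pes"): F(363, 5000),
    (6, "ABCDEF", "ces"): F(19845, 3936256),
}
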