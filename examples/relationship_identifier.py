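"""Classify every pairwise genetic relationship in a pedigree.

Three deterministic metrics code each pair: meiotic distance (MD),
generation depth difference (GDD), and genetic relationship type (GRT:
direct / full / half / NA).  (3, 1, full) is an avuncular pair,
(2, 0, half) a half-sibling pair, and so on.
"""

import pedforge as pf

ped = pf.Pedigree()
for iid, sex in [("GF", "M"), ("GM", "F"), ("A", "F"), ("B", "M"),
                 ("SA", "M"), ("SB", "F"), ("X", "F"),
                 ("C", "M"), ("D", "F"), ("E", "F"), ("H", "M")]:
    ped.add_individual(iid, sex=sex)
for p, c in [("GF", "A"), ("GM", "A"), ("GF", "B"), ("GM", "B"),
             ("A", "C"), ("SA", "C"), ("A", "D"), ("SA", "D"),
             ("B", "E"), ("SB", "E"), ("SA", "H"), ("X", "H")]:
    ped.add_edge(p, c)

table = pf.classify_all_pairs(ped)
print(table[table.grt != "NA"].to_string(index=False))
print()
print("label inventory:", table.label.value_counts().to_dict())
# C-E are first cousins (MD 4, GDD 0, full); C-H are half-siblings
# through the shared father SA (MD 2, GDD 0, half).
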