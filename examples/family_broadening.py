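"""Extend a pedigree's breadth by giving married-in founders families.

Every non-root founder (a spouse who married into the family) gets a
simulated pedigree of their own grafted on, which creates aunts/uncles
and — most visibly — first cousins for their descendants.
"""

import numpy as np

import pedforge as pf
from pedforge.validation import simulate_census_family

ped, rng = simulate_census_family(52, num_generations=4, lo=40, hi=120)
model = pf.SibshipModel.default()

before = pf.cousin_counts(pf.classify_all_pairs(ped))
out = pf.broaden_family(ped, model, pf.SimConfig(num_generations=4), rng)
after = pf.cousin_counts(pf.classify_pairs_between(out, ped.individuals, out.individuals))

print(f"family broadened from {len(ped)} to {len(out)} individuals")
gained = [i for i in ped.individuals if after.get(i, 0) > before.get(i, 0)]
print(f"{len(gained)}/{len(ped)} original individuals gained first cousins")
totals = (sum(before.values()) // 2, sum(after.values()) // 2)
print(f"first-cousin pairs involving original members: {totals[0]} -> {totals[1]}")
# Root founders and the oldest generation cannot gain cousins; everyone
# descending from a married-in spouse typically does.
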