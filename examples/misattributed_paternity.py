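"""Simulate misattributed-paternity (MAP) events on a pedigree.

Each individual with both parents recorded undergoes a MAP event with
probability p; the recorded father is then replaced either by an
existing male of his generation (possibly creating consanguinity) or by
a new outside male.  Replicate counts follow Binomial(n_eligible, p).
"""

import numpy as np

import pedforge as pf
from pedforge.validation import simulate_census_family

ped, rng = simulate_census_family(46, num_generations=4, lo=40, hi=60)
eligible = pf.eligible_for_map(ped)
print(f"family of {len(ped)}; {len(eligible)} individuals eligible for MAP")

for p in (0.01, 0.05, 0.10):
    counts = [len(pf.simulate_map(ped, pf.MapConfig(p, p_within=0.5), rng)[1])
              for _ in range(1000)]
    print(f"p={p:.2f}: mean events over 1000 replicates = {np.mean(counts):.2f} "
          f"(expected n*p = {len(eligible) * p:.2f})")

# A single high-rate run, showing the rewired edges:
out, events = pf.simulate_map(ped, pf.MapConfig(0.10, p_within=0.5), rng)
for ev in events:
    print(f"  child {ev.child_id}: father {ev.old_father_id} -> {ev.new_father_id} ({ev.source})")
print(f"pedigree still a valid DAG: {pf.validate(out).ok}")
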