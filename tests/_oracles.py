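"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive relationship metrics and kinship from first
principles (exhaustive path enumeration, single-locus Monte-Carlo gene
drop) rather than calling the library's own algorithms.
"""

import itertools

import numpy as np


def all_ancestor_path_lengths(graph, node):
    """All ancestors of ``node`` with the set of *all* upward path
    lengths, by exhaustive recursion (not BFS)."""
    lengths = {node: {0}}

    def walk(current, dist):
        for parent in graph.predecessors(current):
            lengths.setdefault(parent, set()).add(dist + 1)
            walk(parent, dist + 1)

    walk(node, 0)
    return lengths


def brute_force_relationship(graph, a, b):
    """(md, gdd, grt) computed by enumerating every ancestor path."""
    la = all_ancestor_path_lengths(graph, a)
    lb = all_ancestor_path_lengths(graph, b)
    if a == b:
        return 0, 0, "direct"
    if b in la:
        d = min(la[b])
        return d, d, "direct"
    if a in lb:
        d = min(lb[a])
        return d, d, "direct"
    common = la.keys() & lb.keys()
    if not common:
        return None, None, "NA"
    sums = {c: min(la[c]) + min(lb[c]) for c in common}
    md = min(sums.values())
    mrcas = [c for c, s in sums.items() if s == md]
    gdd = min(abs(min(la[c]) - min(lb[c])) for c in mrcas)
    grt = "full" if len(mrcas) >= 2 else "half"
    return md, gdd, grt


def monte_carlo_kinship(ped, a, b, rng, n_reps=2000):
    """Kinship by repeated single-locus gene drops of unique founder alleles.

    Each rep drops two uniquely labelled alleles per founder down the
    pedigree; the kinship estimate is the average probability that one
    allele drawn from each individual matches.
    """
    order = sorted(ped.individuals, key=lambda i: (ped.tick(i) or 0, i))
    total = 0.0
    for _ in range(n_reps):
        alleles = {}
        counter = itertools.count()
        for iid in order:
            parents = ped.parents(iid)
            if not parents:
                alleles[iid] = (next(counter), next(counter))
            else:
                gamete = []
                for p in parents:
                    gamete.append(alleles[p][rng.integers(2)])
                if len(gamete) == 1:  # missing parent: unique allele
                    gamete.append(next(counter))
                alleles[iid] = tuple(gamete)
        aa, bb = alleles[a], alleles[b]
        total += sum(aa[i] == bb[j] for i in (0, 1) for j in (0, 1)) / 4.0
    return total / n_reps
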