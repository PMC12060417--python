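import numpy as np
import pytest
from hypothesis import settings

import pedforge as pf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio():
    """Father P, mother M, daughter C."""
    ped = pf.Pedigree()
    ped.add_individual("P", sex=pf.MALE, tick=1)
    ped.add_individual("M", sex=pf.FEMALE, tick=1)
    ped.add_individual("C", sex=pf.FEMALE, tick=2)
    ped.add_edge("P", "C")
    ped.add_edge("M", "C")
    return ped


@pytest.fixture
def three_generations():
    """Two grandparents, two full-sib parents' families and a cousin pair.

    Layout: GF x GM -> A, B (full siblings); A x SA -> C, D; B x SB -> E.
    C-D are siblings, C-E first cousins, B-C avuncular, GF-C grandparent.
    H is a half-sibling of C and D through father SA with outside mother X.
    """
    ped = pf.Pedigree()
    founders = [("GF", pf.MALE), ("GM", pf.FEMALE), ("SA", pf.MALE), ("SB", pf.FEMALE), ("X", pf.FEMALE)]
    for iid, sex in founders:
        ped.add_individual(iid, sex=sex)
    for iid, sex in [("A", pf.FEMALE), ("B", pf.MALE), ("C", pf.MALE), ("D", pf.FEMALE), ("E", pf.FEMALE), ("H", pf.MALE)]:
        ped.add_individual(iid, sex=sex)
    for p, c in [("GF", "A"), ("GM", "A"), ("GF", "B"), ("GM", "B"),
                 ("A", "C"), ("SA", "C"), ("A", "D"), ("SA", "D"),
                 ("B", "E"), ("SB", "E"), ("SA", "H"), ("X", "H")]:
        ped.add_edge(p, c)
    for iid, tick in pf.assign_generation_ticks(ped).items():
        ped.set_tick(iid, tick)
    return ped


def random_pedigree(rng, n_generations=3, mean=2.0, sd=1.0):
    model = pf.SibshipModel.from_rows([(1, mean, sd)])
    return pf.simulate_pedigree(pf.SimConfig(num_generations=n_generations), model, rng)


def census_family(seed, num_generations=5, lo=80, hi=400):
    """A census-model family whose size falls in the desk-scale window.

    Consecutive child seeds are tried until the simulated family lands in
    [lo, hi]; returns (pedigree, rng) with the rng ready for downstream
    draws.
    """
    model = pf.SibshipModel.default()
    for child_seed in np.random.SeedSequence(seed).spawn(1000):
        rng = np.random.default_rng(child_seed)
        ped = pf.simulate_pedigree(pf.SimConfig(num_generations=num_generations), model, rng)
        if lo <= len(ped) <= hi:
            return ped, rng
    raise RuntimeError("no family of the requested size in 1000 attempts")
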