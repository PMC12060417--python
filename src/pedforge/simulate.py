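"""Forward simulation of pedigree structures.

Simulation starts from a single root founder couple at generation tick 1.
Every couple whose tick is below the requested number of generations
draws a sibship size from the :class:`~pedforge.sibship.SibshipModel` and
produces that many children at the next tick.  Each child's sex is a
Bernoulli draw; each child is immediately paired with a newly created,
unrelated spouse of the complementary sex at the same tick (an explicit
founder marrying into the family), and the recursion continues depth
first until the last generation.

Draw order per couple is fixed so runs are reproducible from one seed:
sibship size first, then child sexes left to right.  Spouse sexes are
deterministic complements and consume no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FEMALE, MALE, Pedigree, complement_sex


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation parameters.

    ``num_generations`` bounds the maximum generation tick produced;
    ``sex_probability`` is the probability that a Bernoulli sex draw
    yields a male (sperm-producing, "XY") individual.
    """

    num_generations: int
    sex_probability: float = 0.5
    min_sibship: int = 0

    def __post_init__(self) -> None:
        if self.num_generations < 1:
            raise ValueError("num_generations must be >= 1")
        if not 0.0 <= self.sex_probability <= 1.0:
            raise ValueError("sex_probability must be in [0, 1]")


def _draw_sex(rng: np.random.Generator, p_male: float) -> str:
    return MALE if rng.random() < p_male else FEMALE


def simulate_pedigree(
    config: SimConfig,
    model,
    rng: np.random.Generator,
    start_id: int = 1,
) -> Pedigree:
    """Simulate one family pedigree; sexes and ticks are set on every node.

    Ids are consecutive integers starting at ``start_id``.
    """
    ped = Pedigree()
    next_id = start_id

    def new_individual(sex: str, tick: int) -> str:
        nonlocal next_id
        iid = ped.add_individual(next_id, sex=sex, tick=tick)
        next_id += 1
        return iid

    sex_a = _draw_sex(rng, config.sex_probability)
    root_a = new_individual(sex_a, 1)
    root_b = new_individual(complement_sex(sex_a), 1)

    # Depth-first over couples; stack holds (parent_a, parent_b, tick).
    stack = [(root_a, root_b, 1)]
    from .sibship import draw_sibship_size

    while stack:
        pa, pb, tick = stack.pop()
        if tick >= config.num_generations:
            continue
        n_children = draw_sibship_size(model, tick, rng, min_size=config.min_sibship)
        couples = []
        for _ in range(n_children):
            child_sex = _draw_sex(rng, config.sex_probability)
            child = new_individual(child_sex, tick + 1)
            ped.add_edge(pa, child)
            ped.add_edge(pb, child)
            spouse = new_individual(complement_sex(child_sex), tick + 1)
            couples.append((child, spouse, tick + 1))
        # Reverse so the leftmost child's branch is explored first.
        stack.extend(reversed(couples))

    return ped
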