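"""Structural perturbations of existing pedigrees.

Two post-hoc events are modelled:

* misattributed paternity (MAP): for each individual whose two genetic
  parents are recorded, the recorded father is, with a small per-child
  probability, not the genetic father; the paternal edge is rewired
  either to an existing male of the father's generation (possibly
  introducing consanguinity) or to a newly created outside male;
* family broadening (FB): every founder who married into the family
  (a non-root founder) is given a simulated family of their own, grafted
  onto the pedigree, which adds aunts/uncles and cousins for their
  descendants.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pedigree import MALE, Pedigree, _natural_key
from .simulate import SimConfig, simulate_pedigree


@dataclass(frozen=True)
class MapConfig:
    """MAP probabilities: per-eligible-child event rate and the
    probability that the replacement father comes from within the family."""

    p_map: float
    p_within: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_map", self.p_map), ("p_within", self.p_within)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class MapEvent:
    child_id: str
    old_father_id: str
    new_father_id: str
    source: str  # "within_family" | "new_individual"


def eligible_for_map(ped: Pedigree) -> list[str]:
    """Individuals with both genetic parents present in the pedigree."""
    return [i for i in ped.individuals if len(ped.parents(i)) == 2]


def simulate_map(
    ped: Pedigree, cfg: MapConfig, rng: np.random.Generator
) -> tuple[Pedigree, list[MapEvent]]:
    """Apply MAP events in a single pass over eligible children.

    For each eligible child independently, a Bernoulli(p_map) draw decides
    whether a MAP occurs; on an event, Bernoulli(p_within) decides whether
    the new father is sampled uniformly from existing males at the
    replaced father's generation tick (excluding him), falling back to a
    new outside male when that pool is empty.  The within-family pool is
    the input pedigree's males, not fathers created earlier in the pass.
    """
    out = ped.copy()
    events: list[MapEvent] = []
    next_id = ped.max_numeric_id() + 1

    males_by_tick: dict[int | None, list[str]] = {}
    for i in ped.individuals:
        if ped.sex(i) == MALE:
            males_by_tick.setdefault(ped.tick(i), []).append(i)

    for child in eligible_for_map(ped):
        if rng.random() >= cfg.p_map:
            continue
        parents = ped.parents(child)
        fathers = [p for p in parents if ped.sex(p) == MALE]
        if len(fathers) != 1:
            continue  # father not identifiable; nothing to rewire
        old_father = fathers[0]
        tick = ped.tick(old_father)

        new_father = None
        source = "new_individual"
        if rng.random() < cfg.p_within:
            pool = [m for m in males_by_tick.get(tick, []) if m != old_father]
            if pool:
                new_father = pool[int(rng.integers(len(pool)))]
                source = "within_family"
        if new_father is None:
            new_father = out.add_individual(next_id, sex=MALE, tick=tick)
            next_id += 1

        out.graph.remove_edge(old_father, child)
        out.add_edge(new_father, child)
        events.append(MapEvent(child, old_father, str(new_father), source))

    return out, events


def non_root_founders(ped: Pedigree) -> list[str]:
    """Founders who married into the family: no ancestors, tick above the
    pedigree's minimum tick."""
    ticks = [t for t in ped.ticks().values() if t is not None]
    if not ticks:
        return []
    min_tick = min(ticks)
    return [f for f in ped.founders() if ped.tick(f) is not None and ped.tick(f) > min_tick]


def broaden_family(
    ped: Pedigree,
    model,
    cfg: SimConfig,
    rng: np.random.Generator,
    max_retries: int = 25,
) -> Pedigree:
    """Graft a simulated pedigree onto each non-root founder.

    For each non-root founder ``f`` at tick ``t``, a fresh pedigree is
    simulated to depth ``t + 1`` and ``f`` is identified with a same-sex,
    same-tick descendant in it, so ``f`` gains parents, siblings and
    nephews/nieces — and ``f``'s descendants gain cousins.  The stand-in's
    own simulated descendants (and spouses left without children) are
    pruned before grafting so ``f`` keeps only their real family.  New ids
    are assigned incrementally above the running maximum.
    """
    out = ped.copy()
    next_id = ped.max_numeric_id() + 1

    for founder in sorted(non_root_founders(ped), key=_natural_key):
        f_tick = ped.tick(founder)
        f_sex = ped.sex(founder)
        graft = None
        for _ in range(max_retries):
            candidate_graft = simulate_pedigree(
                SimConfig(num_generations=f_tick + 1, sex_probability=cfg.sex_probability,
                          min_sibship=cfg.min_sibship),
                model, rng, start_id=1,
            )
            candidates = [
                i for i in candidate_graft.individuals
                if candidate_graft.tick(i) == f_tick
                and candidate_graft.sex(i) == f_sex
                and len(candidate_graft.parents(i)) == 2
            ]
            if candidates:
                graft = candidate_graft
                stand_in = candidates[int(rng.integers(len(candidates)))]
                break
        if graft is None:
            raise RuntimeError(
                f"family broadening: no same-sex tick-{f_tick} graft candidate "
                f"for founder {founder} after {max_retries} attempts"
            )

        # Prune the stand-in's simulated descendants, then any individual
        # the pruning isolated (typically spouses without children).
        doomed = nx.descendants(graft.graph, stand_in)
        graft.graph.remove_nodes_from(doomed)
        isolated = [i for i in graft.graph if graft.graph.degree(i) == 0 and i != stand_in]
        graft.graph.remove_nodes_from(isolated)

        relabel = {}
        for i in graft.individuals:
            relabel[i] = founder if i == stand_in else str(next_id)
            if i != stand_in:
                next_id += 1

        for i in graft.individuals:
            if i != stand_in:
                out.add_individual(relabel[i], sex=graft.sex(i), tick=graft.tick(i))
        for p, c in graft.edges:
            out.add_edge(relabel[p], relabel[c])

    return out
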