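"""Founder identification and generation-tick assignment.

Arbitrary input pedigrees may be incomplete (individuals with a single
recorded parent) and consanguineous (several paths to a root founder).
Before genomes can be dropped down a pedigree every individual needs two
parents and a generation tick that strictly follows both parents'.

* explicit founders: individuals present in the pedigree with no known
  ancestors;
* implicit founders: synthetic parents created for individuals with only
  one known parent (id-prefixed ``imp_`` so they can be excluded from
  genotype output downstream);
* root founders: the explicit founders the rest of the family descends
  from; they anchor the tick scale at 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .pedigree import UNKNOWN, Pedigree, PedigreeError, _natural_key, complement_sex

log = logging.getLogger(__name__)

IMPLICIT_PREFIX = "imp_"


@dataclass
class FounderSet:
    root_founders: set[str] = field(default_factory=set)
    explicit_founders: set[str] = field(default_factory=set)
    implicit_founders: set[str] = field(default_factory=set)

    @property
    def all_founders(self) -> set[str]:
        return self.explicit_founders | self.implicit_founders


def _root_founders(ped: Pedigree) -> list[str]:
    """Explicit founders with the maximal descendant set anchor the family."""
    founders = ped.founders()
    if not founders:
        return []
    counts = {f: len(nx.descendants(ped.graph, f)) for f in founders}
    best = max(counts.values())
    return sorted((f for f, c in counts.items() if c == best), key=_natural_key)


def assign_generation_ticks(ped: Pedigree) -> dict[str, int]:
    """Assign a generation tick to every individual.

    Root founders get tick 1 and descendants are placed by shortest
    directed path from any root.  Individuals not descended from a root
    (married-in spouses, and their ancestors if recorded) are placed by
    offset from an already-placed co-parent, parent or child; conflicting
    offsets take the maximum induced tick.  A final fixpoint pass raises
    any child to at least one past its latest parent, which handles
    consanguinity and cross-generation mating; ticks are then shifted so
    the minimum is 1.
    """
    g = ped.graph
    if not nx.is_directed_acyclic_graph(g):
        raise PedigreeError("cannot assign generation ticks to a cyclic pedigree")
    if g.number_of_nodes() == 0:
        return {}

    ticks: dict[str, int] = {}
    roots = _root_founders(ped)
    for node, dist in nx.multi_source_dijkstra_path_length(g, set(roots)).items():
        ticks[node] = 1 + int(dist)

    # Offset placement for individuals not reached from the roots.
    changed = True
    while changed:
        changed = False
        for node in g:
            if node in ticks:
                continue
            candidates = []
            for child in g.successors(node):
                for co_parent in g.predecessors(child):
                    if co_parent != node and co_parent in ticks:
                        candidates.append(ticks[co_parent])
                if child in ticks:
                    candidates.append(ticks[child] - 1)
            for parent in g.predecessors(node):
                if parent in ticks:
                    candidates.append(ticks[parent] + 1)
            if candidates:
                ticks[node] = max(candidates)
                changed = True

    # Structurally unreachable individuals (isolated spouses, disconnected
    # components): keep a recorded tick when the profile supplies one,
    # otherwise start a local scale at tick 1.
    unplaced = [n for n in g if n not in ticks]
    if unplaced:
        recorded = [n for n in unplaced if ped.tick(n) is not None]
        for node in recorded:
            ticks[node] = ped.tick(node)
        rest = [n for n in unplaced if n not in ticks]
        if rest:
            log.warning("%d individuals not connected to a root founder; assigning local ticks", len(rest))
            sub = g.subgraph(rest)
            for node in nx.topological_sort(sub):
                parents = list(sub.predecessors(node))
                ticks[node] = 1 + max((ticks[p] for p in parents), default=0)

    # Fixpoint repair: children strictly after every parent.
    for node in nx.topological_sort(g):
        parent_ticks = [ticks[p] for p in g.predecessors(node)]
        if parent_ticks:
            ticks[node] = max(ticks[node], max(parent_ticks) + 1)

    shift = 1 - min(ticks.values())
    if shift:
        ticks = {n: t + shift for n, t in ticks.items()}
    return ticks


def resolve_founders(ped: Pedigree) -> tuple[Pedigree, FounderSet]:
    """Complete a pedigree: create implicit founders, assign ticks.

    Returns a copy in which every non-founder has exactly two parents and
    every node carries a tick and a ``founder_class`` attribute, plus the
    founder partition.  Resolving an already-complete pedigree is a
    no-op apart from the attribute refresh.
    """
    completed = ped.copy()
    explicit = set(ped.founders())
    implicit: set[str] = set()

    counter = itertools.count(1)
    existing = set(completed.graph.nodes)
    for iid in ped.individuals:
        parents = ped.parents(iid)
        if len(parents) == 1:
            known = parents[0]
            imp_id = f"{IMPLICIT_PREFIX}{next(counter)}"
            while imp_id in existing:
                imp_id = f"{IMPLICIT_PREFIX}{next(counter)}"
            existing.add(imp_id)
            sex = complement_sex(ped.sex(known))
            completed.add_individual(imp_id, sex=sex)
            completed.add_edge(imp_id, iid)
            implicit.add(imp_id)

    ticks = assign_generation_ticks(completed)
    for iid, tick in ticks.items():
        completed.set_tick(iid, tick)

    roots = {f for f in _root_founders(completed) if f in explicit}
    founder_set = FounderSet(root_founders=roots, explicit_founders=explicit, implicit_founders=implicit)
    for iid in completed.individuals:
        if iid in implicit:
            cls = "implicit"
        elif iid in roots:
            cls = "root"
        elif iid in explicit:
            cls = "explicit"
        else:
            cls = "descendant"
        completed.graph.nodes[iid]["founder_class"] = cls
    return completed, founder_set


def export_slim_pedigree(ped: Pedigree, ticks: dict[str, int] | None, path) -> None:
    """Write the generation-ordered pedigree dialect [Gen IID P1 P2].

    Rows sort ascending by generation then id; founders carry P1=P2=0 at
    their own tick, so a forward simulator can create individuals in the
    order the file lists them.
    """
    if ticks is None:
        ticks = {i: ped.tick(i) for i in ped.individuals}
    missing = [i for i in ped.individuals if ticks.get(i) is None]
    if missing:
        raise PedigreeError(f"generation ticks missing for {missing[:5]}...")
    rows = []
    for iid in sorted(ped.individuals, key=lambda i: (ticks[i], _natural_key(i))):
        parents = ped.parents(iid)
        p1 = parents[0] if len(parents) >= 1 else "0"
        p2 = parents[1] if len(parents) >= 2 else "0"
        rows.append(f"{ticks[iid]} {iid} {p1} {p2}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_slim_pedigree(path) -> Pedigree:
    """Read the [Gen IID P1 P2] dialect back into a pedigree with ticks."""
    ped = Pedigree()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedigreeError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            gen, iid, p1, p2 = fields
            ped.add_individual(iid, tick=int(gen))
            for parent in (p1, p2):
                if parent != "0":
                    ped.add_edge(parent, iid)
    return ped
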