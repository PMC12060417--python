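"""Directed-acyclic-graph pedigree model.

A pedigree is a directed graph in which nodes are individuals and an edge
``parent -> child`` records genetic transmission.  Because an individual
cannot be their own genetic ancestor, a well-formed pedigree is acyclic.
Each node carries a profile: sex (``"F"``/``"M"``/``"U"``) and, once
assigned, a positive integer generation tick (root founders sit at tick 1,
their children at tick 2, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

FEMALE = "F"
MALE = "M"
UNKNOWN = "U"

SEXES = (FEMALE, MALE, UNKNOWN)


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unparsable files."""


def complement_sex(sex: str) -> str:
    if sex == FEMALE:
        return MALE
    if sex == MALE:
        return FEMALE
    return UNKNOWN


def _natural_key(iid: str):
    """Sort numeric ids numerically, everything else lexically."""
    s = str(iid)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class ValidationReport:
    """Outcome of structural validation: ``ok`` iff no violations."""

    violations: list[tuple[str, tuple]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, rule: str, *ids) -> None:
        self.violations.append((rule, tuple(ids)))


class Pedigree:
    """A family pedigree backed by a :class:`networkx.DiGraph`.

    Node attributes: ``sex`` (one of ``F``, ``M``, ``U``), ``tick``
    (positive int or ``None``), and optionally ``fid`` (family id carried
    through from .ped input) and ``founder_class``.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_individual(self, iid, sex: str = UNKNOWN, tick: int | None = None, **attrs) -> str:
        iid = str(iid)
        if sex not in SEXES:
            raise PedigreeError(f"invalid sex code {sex!r} for {iid}")
        if tick is not None and tick < 1:
            raise PedigreeError(f"generation tick must be >= 1, got {tick} for {iid}")
        if iid in self.graph:
            node = self.graph.nodes[iid]
            if sex != UNKNOWN:
                node["sex"] = sex
            if tick is not None:
                node["tick"] = tick
            node.update(attrs)
        else:
            self.graph.add_node(iid, sex=sex, tick=tick, **attrs)
        return iid

    def add_edge(self, parent, child) -> None:
        parent, child = str(parent), str(child)
        for iid in (parent, child):
            if iid not in self.graph:
                self.add_individual(iid)
        self.graph.add_edge(parent, child)

    def copy(self) -> "Pedigree":
        out = Pedigree()
        out.graph = self.graph.copy()
        return out

    # -- queries ------------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return sorted(self.graph.nodes, key=_natural_key)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, iid) -> bool:
        return str(iid) in self.graph

    def parents(self, iid) -> tuple[str, ...]:
        """Parents of ``iid``, father (male) first when sexes are known."""
        ps = list(self.graph.predecessors(str(iid)))
        ps.sort(key=lambda p: (0 if self.sex(p) == MALE else 1, _natural_key(p)))
        return tuple(ps)

    def children(self, iid) -> list[str]:
        return sorted(self.graph.successors(str(iid)), key=_natural_key)

    def sex(self, iid) -> str:
        return self.graph.nodes[str(iid)].get("sex", UNKNOWN)

    def tick(self, iid) -> int | None:
        return self.graph.nodes[str(iid)].get("tick")

    def set_tick(self, iid, tick: int) -> None:
        if tick < 1:
            raise PedigreeError(f"generation tick must be >= 1, got {tick}")
        self.graph.nodes[str(iid)]["tick"] = int(tick)

    def founders(self) -> list[str]:
        """Explicit founders: individuals with no known ancestors."""
        return sorted((i for i in self.graph if self.graph.in_degree(i) == 0), key=_natural_key)

    def max_numeric_id(self) -> int:
        nums = [int(i) for i in self.graph if str(i).isdigit()]
        return max(nums, default=0)

    def ticks(self) -> dict[str, int | None]:
        return {i: self.tick(i) for i in self.individuals}


def validate(ped: Pedigree) -> ValidationReport:
    """Structural validation of a pedigree.

    Checks acyclicity, the two-genetic-parent bound, complementary sexes
    of co-parents, and generation-tick ordering along edges.  Failures are
    reported, not raised.
    """
    report = ValidationReport()
    g = ped.graph

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.add("cycle", *[e[0] for e in cycle])

    for child in g:
        parents = list(g.predecessors(child))
        if len(parents) > 2:
            report.add("parent_count", child, *parents)
        if len(parents) == 2:
            s0, s1 = ped.sex(parents[0]), ped.sex(parents[1])
            if UNKNOWN not in (s0, s1) and s0 == s1:
                report.add("same_sex_parents", child, *parents)

    for parent, child in g.edges:
        tp, tc = ped.tick(parent), ped.tick(child)
        if tp is not None and tc is not None and not tp < tc:
            report.add("tick_order", parent, child)
        if (tp is not None and tp < 1) or (tc is not None and tc < 1):
            report.add("tick_range", parent, child)

    return report
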