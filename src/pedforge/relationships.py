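"""Deterministic classification of pairwise genetic relationships.

Three metrics code every ordered pair of individuals in a pedigree:

* meiotic distance (MD): the number of meioses separating the pair — the
  directed path length for ancestor–descendant ("direct") pairs,
  otherwise the minimum over common ancestors of the summed distances
  from each individual to that ancestor (an avuncular pair has MD 3,
  half-siblings MD 2, full first cousins MD 4);
* generation depth difference (GDD): the directed path length for direct
  pairs, otherwise the absolute difference of the two distances to the
  most recent common ancestor;
* genetic relationship type (GRT): ``direct`` when one individual is an
  ancestor of the other, ``full``/``half`` when the pair connects
  through two/one most-recent common ancestors, ``NA`` when no genetic
  path exists (e.g. a married couple).

Paths run through parent→child edges only, so spouse links never create
a genetic relationship.  For non-inbred pairs the kinship coefficient
follows directly: phi = (#MRCA routes) * (1/2)^(MD+1).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import pandas as pd

from .pedigree import Pedigree, _natural_key

NA = "NA"

_ORDINAL = {1: "1st", 2: "2nd", 3: "3rd"}
_REMOVED = {1: "once", 2: "twice"}


@dataclass(frozen=True)
class RelationshipRecord:
    id_a: str
    id_b: str
    md: int | None
    gdd: int | None
    grt: str
    label: str


def ancestor_distances(ped: Pedigree, iid: str) -> dict[str, int]:
    """Minimum meiosis count from ``iid`` to each of its ancestors
    (including itself at distance 0), by BFS up the parent edges."""
    g = ped.graph
    iid = str(iid)
    dist = {iid: 0}
    queue = deque([iid])
    while queue:
        node = queue.popleft()
        for parent in g.predecessors(node):
            if parent not in dist:
                dist[parent] = dist[node] + 1
                queue.append(parent)
    return dist


def _classify(da: dict[str, int], db: dict[str, int], a: str, b: str):
    """Shared core returning (md, gdd, grt) from two ancestor maps."""
    if a == b:
        return 0, 0, "direct"
    if b in da:
        return da[b], da[b], "direct"
    if a in db:
        return db[a], db[a], "direct"
    common = da.keys() & db.keys()
    if not common:
        return None, None, NA
    md = min(da[c] + db[c] for c in common)
    mrcas = [c for c in common if da[c] + db[c] == md]
    gdd = min(abs(da[c] - db[c]) for c in mrcas)
    grt = "full" if len(mrcas) >= 2 else "half"
    return md, gdd, grt


def meiotic_distance(ped: Pedigree, a, b) -> int | None:
    md, _, _ = _classify(ancestor_distances(ped, a), ancestor_distances(ped, b), str(a), str(b))
    return md


def generation_depth_difference(ped: Pedigree, a, b) -> int | None:
    _, gdd, _ = _classify(ancestor_distances(ped, a), ancestor_distances(ped, b), str(a), str(b))
    return gdd


def relationship_type(ped: Pedigree, a, b) -> str:
    _, _, grt = _classify(ancestor_distances(ped, a), ancestor_distances(ped, b), str(a), str(b))
    return grt


def relationship_label(md: int | None, gdd: int | None, grt: str) -> str:
    """Canonical genealogical name for an (MD, GDD, GRT) triple.

    Covers direct lines and collateral relationships out to 3rd cousins
    twice removed; anything deeper is reported as ``distant (MD=k)``.
    """
    if grt == NA or md is None:
        return "unrelated"
    if grt == "direct":
        if md == 0:
            return "self"
        if md == 1:
            return "parent-child"
        if md == 2:
            return "grandparent"
        return "great-" * (md - 2) + "grandparent"
    # Collateral: meioses up to the MRCA from the closer (m) individual,
    # removal r; sibling/avuncular lines at m == 1, cousins at m >= 2.
    half = "half-" if grt == "half" else ""
    m = (md - gdd) // 2
    r = gdd
    if m == 1:
        if r == 0:
            return f"{half}sibling"
        if r == 1:
            return f"{half}avuncular"
        return half + "great-" * (r - 1) + "avuncular"
    degree = m - 1
    if degree > 3 or r > 2:
        return f"distant (MD={md})"
    name = f"{half}{_ORDINAL[degree]} cousin"
    if r:
        name += f" {_REMOVED[r]} removed"
    return name


def classify_pair(ped: Pedigree, a, b) -> RelationshipRecord:
    a, b = str(a), str(b)
    md, gdd, grt = _classify(ancestor_distances(ped, a), ancestor_distances(ped, b), a, b)
    return RelationshipRecord(a, b, md, gdd, grt, relationship_label(md, gdd, grt))


def classify_all_pairs(ped: Pedigree, ids=None) -> pd.DataFrame:
    """One record per unordered pair: columns id_a, id_b, md, gdd, grt, label."""
    ids = sorted((str(i) for i in (ids if ids is not None else ped.individuals)), key=_natural_key)
    anc = {i: ancestor_distances(ped, i) for i in ids}
    rows = []
    for idx, a in enumerate(ids):
        for b in ids[idx + 1:]:
            md, gdd, grt = _classify(anc[a], anc[b], a, b)
            rows.append((a, b, md, gdd, grt, relationship_label(md, gdd, grt)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "md", "gdd", "grt", "label"])


def classify_pairs_between(ped: Pedigree, ids_a, ids_b) -> pd.DataFrame:
    """Records for unordered pairs with one member in ``ids_a`` and the
    other in ``ids_b`` (useful after broadening, when only the original
    individuals' relationships are of interest)."""
    ids_a = sorted({str(i) for i in ids_a}, key=_natural_key)
    ids_b = sorted({str(i) for i in ids_b}, key=_natural_key)
    anc = {i: ancestor_distances(ped, i) for i in set(ids_a) | set(ids_b)}
    seen = set()
    rows = []
    for a in ids_a:
        for b in ids_b:
            if a == b:
                continue
            key = (a, b) if _natural_key(a) <= _natural_key(b) else (b, a)
            if key in seen:
                continue
            seen.add(key)
            md, gdd, grt = _classify(anc[key[0]], anc[key[1]], *key)
            rows.append((*key, md, gdd, grt, relationship_label(md, gdd, grt)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "md", "gdd", "grt", "label"])


def cousin_counts(pairs: pd.DataFrame, labels=("1st cousin", "half-1st cousin")) -> dict[str, int]:
    """Per-individual count of relationships with one of the given
    labels (defaults to first cousins of either type)."""
    counts: dict[str, int] = {}
    mask = pairs["label"].isin(labels)
    for row in pairs[mask].itertuples(index=False):
        counts[row.id_a] = counts.get(row.id_a, 0) + 1
        counts[row.id_b] = counts.get(row.id_b, 0) + 1
    return counts
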