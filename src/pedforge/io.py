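"""Readers and writers for the pedigree file dialects.

Two on-disk dialects are supported:

* traditional 6-column ``.ped``/``.fam``: whitespace-delimited
  ``[FID IID P1 P2 Sex Phenotype]`` rows, missing parents encoded ``0``,
  sex coded in the PLINK convention (1 = male, 2 = female, 0 = unknown);
* two-column edge list ``.nx``: one ``parent child`` pair per line.

A companion profile CSV (columns ``id, sex, generation_tick``) carries the
per-individual metadata that the edge-list dialect cannot.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .pedigree import FEMALE, MALE, UNKNOWN, Pedigree, PedigreeError, _natural_key

log = logging.getLogger(__name__)

_SEX_FROM_PED = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_TO_PED = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".ped", ".fam"):
        return "ped"
    if suffix == ".nx":
        return "nx"
    raise PedigreeError(f"cannot infer pedigree format from {path!r}; pass format explicitly")


def read_pedigree(path, format: str | None = None) -> Pedigree:
    """Read a pedigree from ``path`` in the ``ped`` or ``nx`` dialect."""
    fmt = format or _infer_format(path)
    if fmt == "ped":
        ped = _read_ped(path)
    elif fmt == "nx":
        ped = _read_nx(path)
    else:
        raise PedigreeError(f"unknown pedigree format {fmt!r}")
    if not nx.is_directed_acyclic_graph(ped.graph):
        cycle = nx.find_cycle(ped.graph)
        raise PedigreeError(f"pedigree in {path} contains an ancestry cycle: {cycle}")
    return ped


def _read_ped(path) -> Pedigree:
    ped = Pedigree()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fid, iid, p1, p2, sex, _pheno = fields[:6]
            if sex not in _SEX_FROM_PED:
                raise PedigreeError(f"{path}:{lineno}: unrecognized sex code {sex!r}")
            ped.add_individual(iid, sex=_SEX_FROM_PED[sex], fid=fid)
            for parent in (p1, p2):
                if parent != "0":
                    ped.add_edge(parent, iid)
    return ped


def _read_nx(path) -> Pedigree:
    ped = Pedigree()
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2:
                raise PedigreeError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            parent, child = fields
            if (parent, child) in seen:
                log.warning("%s:%d: duplicate edge %s -> %s collapsed", path, lineno, parent, child)
                continue
            seen.add((parent, child))
            ped.add_edge(parent, child)
    return ped


def write_pedigree(ped: Pedigree, path, format: str | None = None, fid: str = "FAM1") -> None:
    """Write a pedigree in the ``ped`` or ``nx`` dialect.

    ``.ped`` output emits sex as 1=male/2=female/0=unknown and phenotype
    as 0; individuals read from a multi-family .ped keep their original
    FID, simulated ones get ``fid``.
    """
    fmt = format or _infer_format(path)
    if fmt == "ped":
        lines = []
        for iid in ped.individuals:
            parents = ped.parents(iid)
            p1 = parents[0] if len(parents) >= 1 else "0"
            p2 = parents[1] if len(parents) >= 2 else "0"
            row_fid = ped.graph.nodes[iid].get("fid", fid)
            lines.append(f"{row_fid} {iid} {p1} {p2} {_SEX_TO_PED[ped.sex(iid)]} 0")
    elif fmt == "nx":
        lines = [f"{p} {c}" for p, c in sorted(ped.edges, key=lambda e: (_natural_key(e[0]), _natural_key(e[1])))]
    else:
        raise PedigreeError(f"unknown pedigree format {fmt!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_profile(ped: Pedigree, path) -> None:
    """Write the companion profile CSV (id, sex, generation_tick)."""
    rows = [
        {"id": iid, "sex": ped.sex(iid), "generation_tick": ped.tick(iid)}
        for iid in ped.individuals
    ]
    pd.DataFrame(rows, columns=["id", "sex", "generation_tick"]).to_csv(path, index=False)


def read_profile(ped: Pedigree, path) -> Pedigree:
    """Attach sexes and generation ticks from a profile CSV to ``ped``."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "sex", "generation_tick"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"profile {path} must have columns {sorted(required)}")
    for row in df.itertuples(index=False):
        sex = str(row.sex) if pd.notna(row.sex) else UNKNOWN
        tick = int(row.generation_tick) if pd.notna(row.generation_tick) else None
        ped.add_individual(row.id, sex=sex, tick=tick)
    return ped
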