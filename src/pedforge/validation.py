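"""Canonical validation experiments at desk scale.

These helpers bundle the package's standard self-validation run: simulate
a five-generation census-model family, drop synthetic founder genomes
down it with a constant per-bp recombination rate of 1e-6 and mutation
rate of 1e-7, and compare robust genotype-based kinship estimates with
pedigree expectations.

The desk-scale defaults — a family of 80-400 individuals, a 30 Mb
chromosome, a 25,000-site uniform-spectrum founder panel — keep one run
in seconds while giving ~30 crossovers per meiosis, enough recombination
that realized IBD proportions concentrate around their expectations for
collateral relatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founders import resolve_founders
from .genomes import GenomeParams, assign_founder_genomes, drop_genomes, generate_synthetic_founders
from .kinship import kinship_report
from .pedigree import Pedigree
from .sibship import SibshipModel
from .simulate import SimConfig, simulate_pedigree

SEQUENCE_LENGTH = 30_000_000
N_PANEL_SITES = 25_000
MUTATION_RATE = 1e-7
RECOMBINATION_RATE = 1e-6


def simulate_census_family(
    seed: int | np.random.SeedSequence,
    num_generations: int = 5,
    lo: int = 80,
    hi: int = 400,
) -> tuple[Pedigree, np.random.Generator]:
    """Simulate a census-model family whose size lands in [lo, hi].

    Family size under the census sibship model is heavy-tailed (a
    childless root couple terminates the run immediately), so consecutive
    child seeds are tried until the realized family falls in the window.
    Returns the pedigree and the generator, ready for downstream draws.
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    model = SibshipModel.default()
    for child_seed in seed_seq.spawn(1000):
        rng = np.random.default_rng(child_seed)
        ped = simulate_pedigree(SimConfig(num_generations=num_generations), model, rng)
        if lo <= len(ped) <= hi:
            return ped, rng
    raise RuntimeError("no family of the requested size in 1000 attempts")


@dataclass
class KinshipValidationRun:
    """One simulated family with gene-dropped genomes and its kinship table."""

    pedigree: Pedigree
    genome_set: object
    table: pd.DataFrame
    summary: dict

    @property
    def family_size(self) -> int:
        return len(self.pedigree)

    def label_table(self) -> pd.DataFrame:
        rows = [{"label": lab, **stats} for lab, stats in self.summary["per_label"].items()]
        return pd.DataFrame(rows).sort_values("expected", ascending=False).reset_index(drop=True)


def run_kinship_validation(
    seed: int | np.random.SeedSequence,
    num_generations: int = 5,
    lo: int = 80,
    hi: int = 400,
    n_sites: int = N_PANEL_SITES,
    length: int = SEQUENCE_LENGTH,
    mutation_rate: float = MUTATION_RATE,
    recombination_rate: float = RECOMBINATION_RATE,
) -> KinshipValidationRun:
    """Simulate one family, gene-drop genomes, and report kinship."""
    ped, rng = simulate_census_family(seed, num_generations=num_generations, lo=lo, hi=hi)
    completed, founder_set = resolve_founders(ped)
    panel = generate_synthetic_founders(len(founder_set.all_founders), n_sites, length, rng)
    assignment = assign_founder_genomes(sorted(founder_set.all_founders), panel.samples, rng)
    params = GenomeParams(length, mutation_rate=mutation_rate, recombination_rate=recombination_rate)
    gs = drop_genomes(completed, None, assignment, panel, params, rng)
    table, summary = kinship_report(completed, gs)
    return KinshipValidationRun(completed, gs, table, summary)


def parent_child_band_fraction(table: pd.DataFrame, low: float = 0.24, high: float = 0.26) -> float:
    """Fraction of parent-child robust estimates inside [low, high]."""
    pc = table[table["label"] == "parent-child"]["observed_phi"]
    if len(pc) == 0:
        return float("nan")
    return float(((pc >= low) & (pc <= high)).mean())
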