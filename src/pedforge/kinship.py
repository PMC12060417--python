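"""Pedigree-expected and genotype-estimated kinship.

The kinship coefficient phi(a, b) is the probability that an allele
drawn at random from ``a`` is identical by descent with an allele drawn
at random from ``b``.  Two routes to it are provided:

* the classical recursion on a completed pedigree — phi(a, a) =
  (1 + F_a) / 2 with the inbreeding coefficient F_a equal to the kinship
  of a's parents, and for a non-ancestor pair phi(a, b) =
  [phi(father_a, b) + phi(mother_a, b)] / 2 recursing on the individual
  with the larger generation tick (parent-child 1/4, full siblings 1/4,
  first cousins 1/16, second cousins 1/64, ...);
* the robust genotype-based estimator (within-family, allele-frequency
  free): phi_hat = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa^(a) + N_Aa^(b)), where
  N_Aa,Aa counts sites at which both individuals are heterozygous,
  N_AA,aa counts opposite homozygotes, and N_Aa^(i) counts heterozygous
  sites in individual i.  It concentrates near 0.25 for parent-offspring
  pairs and near 0 for unrelated pairs.

``kinship_report`` joins the two with the relationship labels into an
observed-versus-expected validation table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .founders import assign_generation_ticks
from .pedigree import Pedigree
from .relationships import classify_all_pairs


class KinshipCalculator:
    """Memoized expected-kinship recursion over one completed pedigree."""

    def __init__(self, ped: Pedigree) -> None:
        self.ped = ped
        ticks = {i: ped.tick(i) for i in ped.individuals}
        if any(t is None for t in ticks.values()):
            ticks = assign_generation_ticks(ped)
        self.ticks = ticks
        self._parents = {i: ped.parents(i) for i in ped.individuals}
        self._memo: dict[tuple[str, str], float] = {}

    def inbreeding(self, a) -> float:
        """F_a: the kinship coefficient of a's parents (0 for founders)."""
        parents = self._parents[str(a)]
        if len(parents) < 2:
            return 0.0
        return self.phi(parents[0], parents[1])

    def phi(self, a, b) -> float:
        a, b = str(a), str(b)
        key = (a, b) if a <= b else (b, a)
        if key in self._memo:
            return self._memo[key]

        if a == b:
            value = 0.5 * (1.0 + self.inbreeding(a))
        else:
            # Recurse on the later-generation individual: it cannot be an
            # ancestor of the other, so the recursion is exact and, on a
            # DAG, terminates (ticks strictly decrease).
            if self.ticks[a] > self.ticks[b]:
                x, y = a, b
            elif self.ticks[b] > self.ticks[a]:
                x, y = b, a
            else:
                x, y = (a, b) if self._parents[a] else (b, a)
            parents = self._parents[x]
            if not parents:
                value = 0.0  # two distinct founders are unrelated
            elif len(parents) == 1:
                value = 0.5 * self.phi(parents[0], y)
            else:
                value = 0.5 * (self.phi(parents[0], y) + self.phi(parents[1], y))
        self._memo[key] = value
        return value


def expected_kinship(ped: Pedigree, a, b) -> float:
    """Convenience wrapper; reuse a :class:`KinshipCalculator` for many pairs."""
    return KinshipCalculator(ped).phi(a, b)


def estimate_kinship_robust(genotypes_a, genotypes_b) -> float:
    """Robust kinship estimate from two dosage vectors (0/1/2) over the
    same site set; NaN when neither individual is heterozygous."""
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must cover the same sites")
    het_a = ga == 1
    het_b = gb == 1
    n_both_het = int(np.count_nonzero(het_a & het_b))
    n_opp_hom = int(np.count_nonzero(((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))))
    denom = int(np.count_nonzero(het_a)) + int(np.count_nonzero(het_b))
    if denom == 0:
        return float("nan")
    return (n_both_het - 2.0 * n_opp_hom) / denom


def kinship_matrix_robust(G: np.ndarray) -> np.ndarray:
    """All-pairs robust kinship from a dosage matrix (n individuals x sites)."""
    G = np.asarray(G)
    # float32 matmuls hit BLAS; counts stay < 2**24 so they are exact
    het = (G == 1).astype(np.float32)
    hom_ref = (G == 0).astype(np.float32)
    hom_alt = (G == 2).astype(np.float32)
    n_both_het = het @ het.T
    n_opp_hom = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    het_counts = het.sum(axis=1)
    denom = het_counts[:, None] + het_counts[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(denom > 0, (n_both_het - 2.0 * n_opp_hom) / denom, np.nan)
    return K


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def kinship_report(ped_completed: Pedigree, gs) -> tuple[pd.DataFrame, dict]:
    """Observed-vs-expected kinship over all non-implicit pairs.

    Returns a pair table (id_a, id_b, label, expected_phi, observed_phi)
    and a summary with per-relationship statistics plus the squared
    Pearson correlation of observed on expected over related pairs
    (expected_phi > 0) with defined estimates.
    """
    ids, _, G = gs.genotype_matrix()
    poly = (G.min(axis=0) < G.max(axis=0))
    G = G[:, poly]  # monomorphic sites carry no information
    K = kinship_matrix_robust(G)
    index = {iid: i for i, iid in enumerate(ids)}

    pairs = classify_all_pairs(ped_completed, ids=ids)
    calc = KinshipCalculator(ped_completed)
    expected = np.array([calc.phi(a, b) for a, b in zip(pairs["id_a"], pairs["id_b"])])
    observed = np.array([K[index[a], index[b]] for a, b in zip(pairs["id_a"], pairs["id_b"])])
    table = pairs.assign(expected_phi=expected, observed_phi=observed)

    related = table[(table["expected_phi"] > 0) & np.isfinite(table["observed_phi"])]
    per_label = {}
    for label, grp in related.groupby("label"):
        obs = grp["observed_phi"].to_numpy()
        per_label[label] = {
            "n": int(len(obs)),
            "expected": float(grp["expected_phi"].iloc[0]) if grp["expected_phi"].nunique() == 1
            else float(grp["expected_phi"].mean()),
            "mean": float(obs.mean()),
            "sd": float(obs.std(ddof=1)) if len(obs) > 1 else 0.0,
            "median": float(np.median(obs)),
            "iqr": _iqr(obs),
        }
    if len(related) > 1 and related["expected_phi"].nunique() > 1:
        r = np.corrcoef(related["expected_phi"], related["observed_phi"])[0, 1]
        r_squared = float(r * r)
    else:
        r_squared = float("nan")
    summary = {"n_pairs": int(len(table)), "n_related_pairs": int(len(related)),
               "r_squared": r_squared, "per_label": per_label}
    return table, summary
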