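"""Gene-drop simulation of diploid genomes down a completed pedigree.

Founder diploid genomes — loaded from a VCF panel or generated by the
built-in synthetic founder generator — are transmitted to descendants in
generation-tick order.  Each meiosis builds one gamete: the starting
parental haplotype is chosen with probability 1/2, crossovers fall as a
Poisson process along the chromosome (optionally rate-varying through a
recombination map), the source haplotype alternates at each crossover,
and de-novo mutations arrive as a Poisson process at previously unused
integer positions (infinite sites on discrete coordinates).

Alongside the alleles, every haplotype carries founder-haplotype
ancestry labels spliced through the same crossovers, which makes true
identity-by-descent exact rather than inferred: two individuals share a
genomic position IBD precisely when their labels match there.

Coordinates are 0-based half-open internally and 1-based in VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree, _natural_key


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant per-bp recombination rates on [0, L).

    Intervals are half-open ``[start, end)``, contiguous, non-overlapping
    and covering the whole sequence.
    """

    starts: tuple[int, ...]
    ends: tuple[int, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.starts:
            raise ValueError("recombination map needs at least one interval")
        if self.starts[0] != 0:
            raise ValueError("recombination map must start at 0")
        for i in range(len(self.starts)):
            if self.ends[i] <= self.starts[i]:
                raise ValueError("empty or inverted recombination-map interval")
            if i and self.starts[i] != self.ends[i - 1]:
                raise ValueError("recombination-map intervals must be contiguous")
            if self.rates[i] < 0:
                raise ValueError("recombination rates must be non-negative")

    @property
    def length(self) -> int:
        return self.ends[-1]

    @property
    def total_rate(self) -> float:
        """Expected crossovers per meiosis (sum of rate x interval length)."""
        return float(sum(r * (e - s) for s, e, r in zip(self.starts, self.ends, self.rates)))

    @classmethod
    def uniform(cls, rate: float, length: int) -> "RecombinationMap":
        return cls((0,), (int(length),), (float(rate),))

    @classmethod
    def from_hapmap(cls, table, length: int) -> "RecombinationMap":
        """Convert HapMap-style (position, cM/Mb) rows to per-bp intervals.

        The rate on each interval [pos_i, pos_{i+1}) is row i's cM/Mb
        value times 1e-8 (1 cM/Mb = 1e-8 crossovers per bp); the segment
        before the first position gets the first rate, the tail after the
        last position keeps the last rate.
        """
        import pandas as pd

        df = pd.DataFrame(table) if not isinstance(table, pd.DataFrame) else table
        pos = df.iloc[:, 0].to_numpy(dtype=np.int64)
        cm_per_mb = df.iloc[:, 1].to_numpy(dtype=float)
        if len(pos) == 0:
            raise ValueError("empty recombination map table")
        bounds = [0, *[int(p) for p in pos if 0 < p < length], int(length)]
        rates = []
        for start in bounds[:-1]:
            idx = int(np.searchsorted(pos, start, side="right"))
            idx = min(max(idx - 1, 0), len(cm_per_mb) - 1) if start >= pos[0] else 0
            rates.append(cm_per_mb[idx] * 1e-8)
        starts = tuple(bounds[:-1])
        ends = tuple(bounds[1:])
        return cls(starts, ends, tuple(float(r) for r in rates))

    def sample_breakpoints(self, rng: np.random.Generator) -> np.ndarray:
        """Crossover positions for one meiosis (sorted, deduplicated)."""
        weights = np.array([r * (e - s) for s, e, r in zip(self.starts, self.ends, self.rates)])
        total = weights.sum()
        k = rng.poisson(total) if total > 0 else 0
        if k == 0:
            return np.empty(0, dtype=np.int64)
        probs = weights / total
        which = rng.choice(len(weights), size=k, p=probs)
        pos = np.array(
            [self.starts[i] + int(rng.integers(self.ends[i] - self.starts[i])) for i in which],
            dtype=np.int64,
        )
        pos = np.unique(pos[pos > 0])
        return pos


@dataclass(frozen=True)
class GenomeParams:
    """Per-bp per-generation rates and sequence length for a gene drop."""

    sequence_length: int
    mutation_rate: float = 1e-8
    recombination_rate: float | RecombinationMap = 1e-7

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if isinstance(self.recombination_rate, float) and self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")

    def recombination_map(self) -> RecombinationMap:
        if isinstance(self.recombination_rate, RecombinationMap):
            if self.recombination_rate.length != self.sequence_length:
                raise ValueError("recombination map length does not match sequence_length")
            return self.recombination_rate
        return RecombinationMap.uniform(float(self.recombination_rate), self.sequence_length)


class FounderPanel:
    """Phased diploid genotypes used to initialize founder genomes."""

    def __init__(self, positions, haplotypes, samples, ref=None, alt=None) -> None:
        self.positions = np.asarray(positions, dtype=np.int64)
        self.haplotypes = np.asarray(haplotypes, dtype=np.uint8)  # (2n, S)
        self.samples = list(samples)
        n_sites = len(self.positions)
        if self.haplotypes.shape != (2 * len(self.samples), n_sites):
            raise ValueError("haplotype matrix must be (2 * n_samples, n_sites)")
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("panel positions must be strictly increasing")
        self.ref = list(ref) if ref is not None else ["A"] * n_sites
        self.alt = list(alt) if alt is not None else ["T"] * n_sites

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_haplotypes(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.samples.index(sample_id)
        return self.haplotypes[2 * idx], self.haplotypes[2 * idx + 1]

    @classmethod
    def from_vcf(cls, path) -> "FounderPanel":
        """Load a phased (or unphased, randomly phased upstream) panel
        from a VCF via cyvcf2; biallelic sites only."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        positions, ref, alt, rows = [], [], [], []
        for variant in vcf:
            if len(variant.ALT) != 1:
                continue
            positions.append(variant.POS - 1)
            ref.append(variant.REF)
            alt.append(variant.ALT[0])
            gts = np.asarray(variant.genotypes)  # (n, 3): a0, a1, phased
            col = np.empty(2 * len(samples), dtype=np.uint8)
            col[0::2] = np.clip(gts[:, 0], 0, 1)
            col[1::2] = np.clip(gts[:, 1], 0, 1)
            rows.append(col)
        haps = np.array(rows, dtype=np.uint8).T if rows else np.zeros((2 * len(samples), 0), np.uint8)
        return cls(np.array(positions, dtype=np.int64), haps, samples, ref, alt)


def generate_synthetic_founders(
    n_samples: int,
    n_sites: int,
    length: int,
    rng: np.random.Generator,
    spectrum: str = "uniform",
) -> FounderPanel:
    """Generate an unrelated founder panel under Hardy-Weinberg.

    Sites sit at distinct uniform positions on [0, length); each site's
    alternate-allele frequency is drawn from the requested spectrum —
    ``uniform`` on (0, 1), or ``neutral`` with density proportional to
    1/x truncated to [1/(2n), 1 - 1/(2n)] — and haplotype alleles are
    independent Bernoulli draws at that frequency (samples unrelated by
    construction).
    """
    if n_sites > length:
        raise ValueError("cannot place more sites than positions")
    positions = np.sort(rng.choice(length, size=n_sites, replace=False)).astype(np.int64)
    if spectrum == "uniform":
        freqs = rng.uniform(0.0, 1.0, size=n_sites)
    elif spectrum == "neutral":
        lo, hi = 1.0 / (2 * n_samples), 1.0 - 1.0 / (2 * n_samples)
        # Inverse-CDF sampling of density 1/x on [lo, hi].
        u = rng.uniform(0.0, 1.0, size=n_sites)
        freqs = lo * (hi / lo) ** u
    else:
        raise ValueError(f"unknown frequency spectrum {spectrum!r}")
    haps = (rng.uniform(size=(2 * n_samples, n_sites)) < freqs).astype(np.uint8)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return FounderPanel(positions, haps, samples)


def assign_founder_genomes(
    founder_ids,
    panel_samples,
    rng: np.random.Generator,
    mapping: dict[str, str] | None = None,
    with_replacement: bool = False,
) -> dict[str, str]:
    """Assign every founder a panel sample id.

    Without a mapping file the assignment is a random injective draw
    (sampling without replacement); a user mapping pins specific founders
    to specific samples and the remainder is drawn randomly.
    """
    founder_ids = sorted((str(f) for f in founder_ids), key=_natural_key)
    panel_samples = list(panel_samples)
    assignment: dict[str, str] = {}
    if mapping:
        for founder, sample in mapping.items():
            founder, sample = str(founder), str(sample)
            if founder not in founder_ids:
                raise ValueError(f"mapping references unknown founder {founder!r}")
            if sample not in panel_samples:
                raise ValueError(f"mapping references unknown panel sample {sample!r}")
            assignment[founder] = sample
    remaining = [f for f in founder_ids if f not in assignment]
    if with_replacement:
        pool = [panel_samples[int(i)] for i in rng.integers(len(panel_samples), size=len(remaining))]
    else:
        used = set(assignment.values())
        free = [s for s in panel_samples if s not in used]
        if len(free) < len(remaining):
            raise ValueError(
                f"{len(remaining)} founders need genomes but only {len(free)} unused panel samples remain"
            )
        pool = list(rng.choice(np.array(free, dtype=object), size=len(remaining), replace=False))
    assignment.update(zip(remaining, pool))
    return assignment


def read_founder_mapping(path) -> dict[str, str]:
    """Two whitespace-delimited columns: founder_id, sample_id."""
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            mapping[fields[0]] = fields[1]
    return mapping


@dataclass
class Haplotype:
    """One haplotype: alleles over the panel sites, de-novo mutation
    positions, and founder-haplotype ancestry segments partitioning
    [0, L)."""

    alleles: np.ndarray
    muts: np.ndarray
    ancestry: list[tuple[int, int, int]]


@dataclass
class GenomeSet:
    """Diploid genomes for every individual in a completed pedigree."""

    length: int
    panel_positions: np.ndarray
    panel_ref: list[str]
    panel_alt: list[str]
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = field(default_factory=dict)
    implicit_ids: set[str] = field(default_factory=set)
    founder_hap_labels: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.haplotypes, key=_natural_key)

    def output_individuals(self) -> list[str]:
        """Individuals reported in genotype output: implicit founders are
        simulated (their children need gametes) but excluded here."""
        return [i for i in self.individuals if i not in self.implicit_ids]

    def mutation_positions(self) -> np.ndarray:
        all_muts = [h.muts for pair in self.haplotypes.values() for h in pair]
        if not all_muts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(all_muts))

    def haplotype_matrix(self, ids=None) -> tuple[list[str], np.ndarray, np.ndarray, list[str], list[str]]:
        """Phased haplotype matrix over panel sites plus de-novo sites.

        Returns (ids, positions, H, ref, alt) with ``H`` of shape
        ``(2 * len(ids), n_sites)``; row 2i/2i+1 are individual i's two
        haplotypes, columns sorted by position.
        """
        ids = [str(i) for i in (ids if ids is not None else self.output_individuals())]
        mut_pos = self.mutation_positions()
        positions = np.concatenate([self.panel_positions, mut_pos])
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        ref = list(np.array(self.panel_ref + ["A"] * len(mut_pos), dtype=object)[order])
        alt = list(np.array(self.panel_alt + ["T"] * len(mut_pos), dtype=object)[order])
        H = np.zeros((2 * len(ids), len(positions)), dtype=np.uint8)
        for i, iid in enumerate(ids):
            for j, hap in enumerate(self.haplotypes[iid]):
                row = np.concatenate([hap.alleles, np.isin(mut_pos, hap.muts).astype(np.uint8)])
                H[2 * i + j] = row[order]
        return ids, positions, H, ref, alt

    def genotype_matrix(self, ids=None) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Diploid dosage matrix (n_individuals, n_sites) over all sites."""
        ids, positions, H, _, _ = self.haplotype_matrix(ids)
        return ids, positions, (H[0::2].astype(np.int16) + H[1::2].astype(np.int16))


def _splice(hap0: Haplotype, hap1: Haplotype, breakpoints: np.ndarray, start: int,
            panel_positions: np.ndarray, length: int) -> Haplotype:
    """Build a gamete by alternating between two parental haplotypes."""
    sources = (hap0, hap1)
    bounds = [0, *breakpoints.tolist(), length]
    alleles = np.empty(len(panel_positions), dtype=np.uint8)
    muts = []
    ancestry: list[tuple[int, int, int]] = []
    which = start
    for s, e in zip(bounds[:-1], bounds[1:]):
        src = sources[which]
        i0, i1 = np.searchsorted(panel_positions, (s, e))
        alleles[i0:i1] = src.alleles[i0:i1]
        m0, m1 = np.searchsorted(src.muts, (s, e))
        if m1 > m0:
            muts.append(src.muts[m0:m1])
        for a_start, a_end, label in src.ancestry:
            lo, hi = max(a_start, s), min(a_end, e)
            if lo < hi:
                if ancestry and ancestry[-1][2] == label and ancestry[-1][1] == lo:
                    ancestry[-1] = (ancestry[-1][0], hi, label)
                else:
                    ancestry.append((lo, hi, label))
        which ^= 1
    mut_arr = np.concatenate(muts) if muts else np.empty(0, dtype=np.int64)
    return Haplotype(alleles, np.sort(mut_arr), ancestry)


def drop_genomes(
    ped: Pedigree,
    ticks: dict[str, int] | None,
    assignment: dict[str, str],
    panel: FounderPanel,
    params: GenomeParams,
    rng: np.random.Generator,
    implicit_ids=None,
) -> GenomeSet:
    """Gene-drop genomes down a completed pedigree.

    Founders receive the phased haplotypes of their assigned panel
    sample; descendants are processed in ascending generation-tick order
    and receive one recombined, mutated gamete from each parent (father's
    first).  Each founder haplotype gets a unique integer ancestry label
    that is transmitted through the same crossovers as the alleles.
    """
    if ticks is None:
        ticks = {i: ped.tick(i) for i in ped.individuals}
    if any(ticks.get(i) is None for i in ped.individuals):
        raise ValueError("every individual needs a generation tick before gene drop")

    L = params.sequence_length
    if len(panel.positions) and panel.positions[-1] >= L:
        raise ValueError("panel contains positions beyond sequence_length")
    rec_map = params.recombination_map()
    mu_total = params.mutation_rate * L

    implicit_ids = {str(i) for i in (implicit_ids or set())}
    from .founders import IMPLICIT_PREFIX

    implicit_ids |= {i for i in ped.individuals if str(i).startswith(IMPLICIT_PREFIX)}

    gs = GenomeSet(
        length=L,
        panel_positions=panel.positions.copy(),
        panel_ref=list(panel.ref),
        panel_alt=list(panel.alt),
        implicit_ids=implicit_ids,
    )
    used_positions = set(panel.positions.tolist())

    def draw_mutations() -> np.ndarray:
        k = rng.poisson(mu_total)
        out = []
        for _ in range(k):
            pos = int(rng.integers(L))
            while pos in used_positions:
                pos = int(rng.integers(L))
            used_positions.add(pos)
            out.append(pos)
        return np.array(sorted(out), dtype=np.int64)

    def gamete(parent: str) -> Haplotype:
        h0, h1 = gs.haplotypes[parent]
        start = int(rng.integers(2))
        breakpoints = rec_map.sample_breakpoints(rng)
        gam = _splice(h0, h1, breakpoints, start, gs.panel_positions, L)
        de_novo = draw_mutations()
        if len(de_novo):
            gam.muts = np.sort(np.concatenate([gam.muts, de_novo]))
        return gam

    next_label = 0
    order = sorted(ped.individuals, key=lambda i: (ticks[i], _natural_key(i)))
    for iid in order:
        parents = ped.parents(iid)
        if not parents:
            sample = assignment.get(iid)
            if sample is None:
                raise ValueError(f"founder {iid} has no panel assignment")
            a0, a1 = panel.sample_haplotypes(sample)
            labels = (next_label, next_label + 1)
            next_label += 2
            gs.founder_hap_labels[iid] = labels
            empty = np.empty(0, dtype=np.int64)
            gs.haplotypes[iid] = (
                Haplotype(a0.copy(), empty, [(0, L, labels[0])]),
                Haplotype(a1.copy(), empty.copy(), [(0, L, labels[1])]),
            )
        elif len(parents) == 2:
            father, mother = parents
            gs.haplotypes[iid] = (gamete(father), gamete(mother))
        else:
            raise ValueError(
                f"individual {iid} has one recorded parent; resolve implicit founders before gene drop"
            )
    return gs


def _label_steps(hap: Haplotype) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([s for s, _, _ in hap.ancestry], dtype=np.int64)
    labels = np.array([lab for _, _, lab in hap.ancestry], dtype=np.int64)
    return starts, labels


def true_ibd_percent(gs: GenomeSet, a, b) -> float:
    """Percent of the genome two individuals share identical by descent.

    At every genomic position the four ordered haplotype pairings are
    checked for matching founder-haplotype labels; the match count is
    capped at 2 (a diploid can share at most both haplotypes), integrated
    along the chromosome and normalized by twice the sequence length.
    Parent and child share exactly 50% because one child haplotype is
    wholly parent-derived.
    """
    a, b = str(a), str(b)
    haps = [*gs.haplotypes[a], *gs.haplotypes[b]]
    bounds = np.unique(np.concatenate([[0, gs.length], *[[s for s, _, _ in h.ancestry] for h in haps]]))
    steps = [_label_steps(h) for h in haps]
    shared = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        labels = []
        for starts, labs in steps:
            idx = int(np.searchsorted(starts, s, side="right")) - 1
            labels.append(labs[idx])
        count = sum(1 for i in (0, 1) for j in (2, 3) if labels[i] == labels[j])
        shared += min(count, 2) * (e - s)
    return 100.0 * shared / (2 * gs.length)


def write_vcf(gs: GenomeSet, path, include_implicit: bool = False, contig: str = "1") -> None:
    """Write phased diploid genotypes as VCF 4.2 text.

    One sample column per individual, excluding implicit founders unless
    ``include_implicit``; sites sorted by position, biallelic, 1-based
    coordinates, GT-only FORMAT.
    """
    ids = gs.individuals if include_implicit else gs.output_individuals()
    ids, positions, H, ref, alt = gs.haplotype_matrix(ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedforge\n")
        fh.write(f"##contig=<ID={contig},length={gs.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for j, pos in enumerate(positions):
            gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(len(ids)))
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")
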