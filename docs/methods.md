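# Methods

## Pedigree model

A pedigree is a directed acyclic graph: nodes are individuals, a
directed edge records parent→child genetic transmission, and each node
carries a sex (`F`/`M`/`U`, defined by gamete production, not
chromosomes — sex chromosomes are not simulated) and a generation tick
(a discrete time unit; root founders sit at tick 1, their children at
tick 2). Structural validity means: acyclic, at most two parents per
individual, complementary sexes for co-parents whose sexes are known,
and `tick(parent) < tick(child)` along every edge. Spouse links are not
edges; a childless married-in spouse is an isolated node, which is why
the edge-list dialect alone cannot carry a full family and a companion
profile CSV (id, sex, generation_tick) travels with it.

`.ped` sex coding follows the PLINK convention (1 = male, 2 = female,
0 = unknown) and phenotype is written as 0; family ids are preserved on
read, defaulted to a single id on write, and otherwise ignored by the
graph model. Duplicate edges in `.nx` input collapse to one with a
logged warning. Ids are opaque strings internally; simulated individuals
get consecutive integer ids.

## Structure simulator

Simulation starts from exactly one root founder couple. For every couple
whose tick t is below the requested number of generations, a sibship
size is drawn from the tick-t row of the sibship table and that many
children are created at tick t+1; each child receives a brand-new
unrelated spouse (an explicit founder of the complementary sex, same
tick — including children of the final generation, whose spouses remain
isolated), and recursion proceeds depth first. Child sex is
Bernoulli(`sex_probability`, default 0.5, probability of male); spouse
sex is the deterministic complement. Draw order is fixed (sibship size,
then child sexes left to right) so one seed reproduces one family
byte-for-byte. Mortality, remarriage, assortative mating and
population-level mate pools are out of scope; consanguinity enters only
through MAP events.

**Discretization of sibship draws.** The normal draw is rounded to the
nearest integer and clamped below at 0 (a `min_sibship` parameter can
raise the floor). Zero-child couples terminate their branch — which also
means family size is heavy-tailed: a childless root couple ends the run
at two individuals. Helpers that need a family "of typical size" retry
consecutive child seeds until the realized size lands in a window
(80–400 individuals for the five-generation default). The
round-and-clamp transform shifts the realized mean slightly above the
specified mean and the SD slightly below (for mean 2.30, SD 1.43 the
closed form gives realized 2.33/1.40); tests compare realized moments
against the closed form and against the census table with a tolerance of
0.12, covering the ≤0.05 model gap plus 3σ Monte-Carlo error at 10,000
draws.

**Sibship table.** CSV columns `generation, mean, sd`
(order-insensitive); ticks must be unique and ascending, and lookups
past the last row return the last row, so a short table extends to
deeper pedigrees. The packaged default holds US census estimates
(generations mapped to census years 1850, 1880, 1910, 1940, 1970).

## Misattributed paternity

Three steps: (1) eligibility — individuals with *both* parents recorded
(one-parent records are excluded; there is no father edge to rewire
against a known mother's context); (2) an independent Bernoulli(p_map)
per eligible child; (3) on an event, Bernoulli(p_within) decides whether
the replacement father is drawn uniformly from existing males at the
replaced father's tick (excluding him) — which can create consanguinity
— or is a newly created outside male at that tick. An empty within-
family pool falls back to a new individual. Each eligible child is
processed exactly once per run, and the within-family pool is frozen at
the input pedigree (fathers created earlier in the same pass are not
candidates). Mothers' edges are never rewired; misattributed maternity
and declared half-sibships are out of scope. Rewiring cannot create a
cycle because the new father occupies the same tick as the old one.

## Family broadening

Non-root founders are founders whose tick exceeds the pedigree's
minimum — the spouses who married in. For each (in id order), a fresh
pedigree is simulated and the founder is identified with a same-sex,
same-tick individual in it, up to 25 resimulation attempts before
erroring. Two choices here were genuinely open:

* **Graft depth.** The graft is simulated to depth `tick(founder) + 1`,
  one generation *past* the founder. At depth `tick(founder)` the
  founder's new siblings would be childless, so the founder's own
  descendants would gain no first cousins and broadening would do little
  beyond attaching parents. The extra generation is what makes cousin
  counts rise for the founder's descendants, which is the point of the
  feature.
* **Pruning.** The stand-in individual's own simulated descendants (and
  anyone the removal isolates, i.e. childless spouses) are pruned before
  identification, so the founder does not acquire a second, simulated
  set of children alongside their real ones.

New individuals get ids incrementally above the running maximum; the
original node set and edge set are always subsets of the output.
Broadening is a single pass over the original non-root founders —
founders introduced by grafts are not themselves broadened.

## Founder resolution and generation ticks

Explicit founders are individuals with no recorded ancestors; implicit
founders are synthetic co-parents created for single-parent records
(id-prefixed `imp_`, sex complementary to the known parent, excluded
from genotype output downstream). Tick assignment on an arbitrary
pedigree proceeds in four phases:

1. root founders — the explicit founders with the maximal descendant
   set — get tick 1, and every individual reachable from them gets
   1 + (shortest directed path);
2. unplaced individuals are placed by offset from placed neighbours
   (co-parent's tick; parent's tick + 1; child's tick − 1), iterated to
   a fixpoint, taking the maximum induced tick when offsets conflict;
3. still-unplaced components keep recorded profile ticks when present
   (the only information available for isolated spouses), otherwise get
   a warned local scale starting at 1;
4. a topological repair pass raises every child to at least
   1 + max(parent ticks) — this is what handles consanguineous loops and
   cross-generation mating — and finally the whole scale is shifted so
   the minimum tick is 1 (relevant when a married-in spouse's recorded
   ancestors reach above the chosen roots).

Repair only ever raises children, never lowers parents, so root ticks
are preserved. On simulator output the resolver reproduces the recorded
ticks exactly, and resolving an already-complete pedigree is a no-op.
The `[Gen IID P1 P2]` export lists individuals sorted by generation then
id, founders with `P1=P2=0` at their own tick, so a forward simulator
can instantiate individuals in file order.

## Relationship metrics

All paths run through parent→child edges only (the ancestor lattice);
spouse links never create genetic relationships. Per-individual ancestor
distances come from BFS up the parent edges. For a pair:

* one an ancestor of the other → GRT `direct`, MD = GDD = directed path
  length;
* otherwise, over common ancestors, MD is the minimum of
  `d_a(c) + d_b(c)`; the ancestors achieving that minimum are the MRCAs;
  GDD is the minimum `|d_a(c) − d_b(c)|` over MRCAs; GRT is `full` with
  two or more MRCAs, `half` with exactly one, `NA` with none.

Under consanguinity MD uses minimum distances, and GRT counts only
minimum-achieving MRCAs; richer consanguineous typing (and a special
label for double first cousins, which simply report `full`) is out of
scope. Labels are derived from (MD, GDD, GRT): direct lines by depth;
collateral pairs via m = (MD−GDD)/2 meioses to the MRCA and removal
r = GDD (m = 1 → sibling/avuncular lines, m ≥ 2 → cousins of degree
m−1), `half-` prefixed for single-MRCA pairs, out to 3rd cousins twice
removed and `distant (MD=k)` beyond. The test suite checks all three
metrics against an independent brute-force oracle that enumerates every
ancestor path on small random pedigrees, including MAP-rewired ones.

## Gene dropping

Founders receive the phased haplotypes of their assigned panel sample —
a random injective assignment by default (sampling without replacement;
a mapping file can pin founders to samples, and with-replacement
sampling is available). Implicit founders are assigned genomes too
(their children need two gametes) but are excluded from output.
Descendants are processed in ascending tick order; each child receives
one gamete per parent (father's first), built by choosing the starting
parental haplotype with probability 1/2, placing a Poisson number of
crossovers (expected count = Σ rate × interval length; uniform placement
within constant-rate intervals of the recombination map, without
interference) and alternating the source haplotype at each crossover.
De-novo mutations arrive as Poisson(μL) per gamete at uniformly drawn,
previously unused integer positions (infinite sites on discrete
coordinates), biallelic with REF=A/ALT=T by convention. Founder genomes
are not mutated — mutation happens in transmission.

Every founder haplotype carries a unique integer ancestry label;
segments are spliced through the same crossovers as the alleles, so each
descendant haplotype is partitioned into founder-haplotype segments and
true IBD needs no inference: the shared fraction integrates, along the
chromosome, the number of label-matching ordered haplotype pairings
between two individuals (capped at 2, the diploid maximum) and
normalizes by twice the sequence length. Parent and child share exactly
50% by construction. One run simulates one chromosome;
multi-chromosome experiments are independent runs with independent
seeds. Coordinates are 0-based half-open internally, 1-based in VCF 4.2
output (phased GT, biallelic records, written as plain text; panels are
read back through cyvcf2). Selection, demography, sex chromosomes,
genotype error and nucleotide-explicit simulation are out of scope.

**Synthetic founder panels.** Sites at distinct uniform positions;
per-site alternate-allele frequency from a `uniform` (0,1) spectrum or a
`neutral` 1/x spectrum truncated to [1/2n, 1−1/2n]; haplotype alleles
are independent Bernoulli draws (Hardy–Weinberg, unrelated samples, no
linkage between panel sites). Mean per-site heterozygosity under the
uniform spectrum is E[2x(1−x)] = 1/3.

## Kinship

Expected kinship uses the classical recursion — φ(a,a) = (1+F_a)/2 with
F_a the kinship of a's parents; distinct founders are unrelated; for
other pairs φ(a,b) = [φ(father_a,b) + φ(mother_a,b)]/2, recursing on the
individual with the larger tick, which on a DAG cannot be an ancestor of
the other, so the recursion is exact under consanguinity and terminates;
results are memoized per pair. The genotype-based estimator is the
robust within-family form
φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(a) + N_Aa(b)), undefined (NaN) when
neither individual is heterozygous; it is exactly symmetric and is
computed for all pairs at once with BLAS matrix products (float32
accumulators, exact for counts below 2²⁴). Monomorphic sites are dropped
before estimation. The validation report joins relationship labels,
expected and estimated kinship over all non-implicit pairs, with
per-label mean/SD/median/IQR and the squared Pearson correlation of
observed on expected over related pairs (expected φ > 0) with defined
estimates. Allele-frequency-based estimators, IBD-segment detection from
genotypes, and inbreeding estimation from genotypes are out of scope.

## Desk-scale validation configuration

The standard self-validation run (`pedforge.validation`, the acceptance
script, the end-to-end tests) uses: a five-generation census-model
family of 80–400 individuals; a synthetic uniform-spectrum founder panel
of 25,000 sites on a 30 Mb chromosome; recombination 1e-6 per bp per
generation and mutation 1e-7 per bp per generation. The rates give ~30
crossovers and ~3 de-novo mutations per meiosis. The chromosome length
matters for the *spread* of realized kinship: with ~1 crossover per
meiosis (a 1 Mb region at the same rate) realized IBD fractions for
collateral relatives vary so much that the observed-versus-expected
regression degrades even though every mean is unbiased; ~30 crossovers
concentrate realized IBD near its expectation, and per-relationship
SDs of a few hundredths remain — intermediate between a single short
region and a 22-chromosome genome.

What the synthetic conditions do not model: linkage disequilibrium and
realistic allele-frequency structure in founders (panel sites are
independent), crossover interference and sex-specific maps, genotype
error and missingness, and population structure. Passing validations
therefore demonstrate correctness of transmission, relationship
classification and the estimator algebra — not robustness of kinship
estimation on real data.

## Numerical and degenerate-input choices

* Normal draws are rounded with `rint` (ties to even; immaterial for
  continuous draws) and clamped at the configured floor.
* A single-generation request returns the root couple alone; a
  founders-only pedigree has all expected kinships 0 and an undefined
  regression (reported NaN).
* A zero-site panel produces a valid header-only VCF; a panel with no
  polymorphic sites leaves the robust estimator undefined (NaN).
* Kinship expected values are kept as exact binary fractions; rounding
  to three decimals for display uses half-up (1/16 → 0.063).
* Tick assignment of an empty pedigree is an empty map; disconnected
  anchor-less components warn and start a local scale at tick 1.
* Crossover breakpoints at identical positions are deduplicated (an even
  number of hits at one position is a no-op either way).
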