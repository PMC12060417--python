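# pedforge

Forward simulation of family pedigrees and the genomes on them, for
medical, evolutionary and forensic genetics work that needs families
with *known* ground truth: every parent–child edge, every relationship
label, every identity-by-descent segment, and every expected kinship
coefficient is available exactly, so estimators and study designs can be
tested against truth instead of against other estimates.

Pedigrees are directed acyclic graphs (nodes are individuals, edges are
parent→child genetic transmission) built on networkx, interoperable with
the traditional 6-column `.ped`/`.fam` format, a two-column edge-list
dialect (`.nx`), and a generation-ordered `[Gen IID P1 P2]` dialect for
forward simulators that create individuals generation by generation.

## What it does

* **Pedigree structures** — forward simulation from one root founder
  couple with sibship sizes drawn per generation from a normal
  distribution (mean/SD can change each generation; a US-census table
  for 1850–1970 ships as the default), Bernoulli sex assignment, and a
  newly created spouse for every child.
* **Misattributed paternity (MAP)** — for each individual with both
  parents recorded, with probability *p* the paternal edge is rewired,
  either to an existing male of the father's generation (possible
  consanguinity) or to a new outside male; this is how half-sibling
  relationships enter a simulated family.
* **Family broadening** — every married-in founder receives a simulated
  family of their own, grafted on, giving their descendants the aunts,
  uncles and cousins a real family would have.
* **Founder resolution** — explicit founders (no recorded ancestors) and
  implicit founders (the missing co-parent of a single-parent record)
  are identified, and generation ticks are assigned on arbitrary
  pedigrees — including consanguineous loops and cross-generation
  mating — so that every child strictly follows both parents.
* **Gene dropping** — founder diploid genomes (from a VCF or the
  built-in synthetic panel generator) are transmitted down the pedigree
  with Poisson crossovers (constant rate or recombination map) and
  infinite-sites mutation; founder-haplotype ancestry labels ride along,
  so true IBD is tracked exactly. Output is phased VCF (implicit
  founders are simulated but excluded from the output).
* **Relationship identification** — every pair is coded by meiotic
  distance (MD), generation depth difference (GDD) and relationship type
  (direct / full / half / NA), and labelled (sibling, avuncular,
  1st cousin once removed, ...). For non-inbred pairs the kinship
  coefficient is `(#MRCA routes) × (1/2)^(MD+1)`.
* **Kinship** — the classical recursion for expected kinship
  (φ(a,a) = (1+F_a)/2, φ(a,b) = [φ(father_a,b)+φ(mother_a,b)]/2) and the
  robust within-family genotype estimator
  φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(a)+N_Aa(b)), joined into an
  observed-versus-expected validation report.

## Worked example

`examples/gene_drop_kinship.py` simulates a five-generation
census-model family, drops synthetic founder genomes (25,000 sites on a
30 Mb chromosome, recombination 1e-6/bp, mutation 1e-7/bp) and compares
genotype-estimated with pedigree-expected kinship:

```
family of 232 individuals; 7071 related pairs with genotype estimates

                  label   n  expected  mean    sd  median   iqr
                sibling 156     0.250 0.252 0.023   0.251 0.030
           parent-child 230     0.250 0.250 0.003   0.250 0.003
            grandparent 222     0.125 0.125 0.022   0.124 0.032
              avuncular 268     0.125 0.126 0.018   0.125 0.026
             1st cousin 340     0.062 0.062 0.015   0.061 0.021
      great-grandparent 200     0.062 0.064 0.018   0.066 0.025
        great-avuncular 244     0.062 0.067 0.018   0.066 0.027
1st cousin once removed 497     0.031 0.034 0.013   0.033 0.018

parent-child estimates in [0.24, 0.26]: 100.0%
R^2 of observed on expected kinship:    0.964
true IBD between parent 1 and child 3: 50.0% of the genome
```

Per-relationship mean estimates sit on their pedigree expectations
(0.25 for parent–child and siblings, 0.125 for grandparents and
avuncular pairs, 1/16 for first cousins), the regression of observed on
expected kinship is tight, and the segment-based IBD between a parent
and child is exactly 50% because one child haplotype is wholly
parent-derived. The other scripts in `examples/` demonstrate pedigree
simulation, MAP, family broadening and relationship classification the
same way.

There is also a CLI mirroring the feature set
(`pedforge sim_ped | sim_map | sim_fb | sim_genomes | check_rel |
ped_to_slim | kinship_report | convert`), e.g.

```bash
pedforge sim_ped --generations 5 --seed 1 --out fam
pedforge sim_genomes --ped fam.nx --profile fam_profile.csv \
    --synthetic-sites 25000 --length 30000000 --mu 1e-7 --rho 1e-6 \
    --seed 2 --out fam
pedforge kinship_report --ped fam.nx --profile fam_profile.csv \
    --vcf fam.vcf --out fam_kinship
```

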