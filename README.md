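# enums-ne

Estimation of effective-population-size (Ne) dynamics from phased
autosomal SNP haplotypes, by combining many short recombination-free
segments.

Whole-chromosome coalescent inference with recombination is intractable
for medium-to-large samples, and site-frequency-spectrum methods discard
linkage information. This package takes the middle road: it carves phased
haplotypes into blocks that carry no trace of crossover, estimates each
block's Ne trajectory with a Bayesian skyline coalescent MCMC, and merges
the per-block trajectories into one population-level Ne(t) curve. It is
aimed at population geneticists who want demographic history out of
phased resequencing panels (or simulated data) without cluster-scale
machinery.

## The method

**Step 1 — blocks.** For a pair of biallelic SNPs, observing all four
two-locus gametes (00, 01, 10, 11) implies a historical crossover between
them under infinite sites (the four-gamete test, FGT). A greedy
left-to-right scan partitions each chromosome into maximal contiguous
blocks in which *every* site pair shows ≤ 3 gametes; blocks shorter than
5,000 bp are discarded. Each surviving block is treated as
recombination-free, i.e. described by a single genealogy.

**Step 2 — per-block skyline.** For block *j*, a Metropolis–Hastings
chain samples jointly the genealogy *g* and a grouped piecewise-constant
population-size function θ(t):

- likelihood: Felsenstein pruning under JC69, strict clock, branch
  lengths in substitutions/site (invariant positions of the block are
  included, so θ is per site);
- coalescent prior: an interval with *k* lineages, duration *t* and
  governing θ contributes `ln(k(k−1)/2θ) − k(k−1)t/2θ`;
- θ prior: independent uniform-on-log θ per group, with an exact
  inverse-gamma Gibbs update (the conditional is conjugate because the
  likelihood does not involve θ).

Heights convert to calendar time with a mutation rate μ = 2.5×10⁻⁸ per
site per generation and 25-year generations: `years = (h/μ)·25`,
`Ne = θ/(2μ)` (diploid). Each posterior is discretized onto the grid
T = (0, 1000, …, 25000) years before present, giving a 26-element vector
N_j with per-time posterior SDs; blocks whose posterior-median TMRCA is
younger than 25,000 years are dropped.

**Step 3 — aggregation.** The population trajectory is the minimizer of
the weighted squared Euclidean distance to all block vectors,
F(x) = Σ_j ‖diag(w_j)(x − N_j)‖², with w_{j,i} = 1/sd_{j,i}. By
convexity the unique solution is, per time point,

    x̂_i = Σ_j w_{j,i}² N_{j,i} / Σ_j w_{j,i}² .

An unweighted variant (plain mean), labeled-subset comparisons, and
per-block Weir–Cockerham Fst between two subpopulations (with the 0.12%
threshold partition) are included. A built-in coalescent simulator
(piecewise-constant demography, infinite-sites mutations, single-crossover
splicing, clean two-deme splits) generates phased VCF fixtures with known
truth for every stage.

## Worked example

Ten independent 5-kb loci simulated at constant Ne = 10,000 (n = 20
haplotypes, μ = 2.5×10⁻⁸), then the full pipeline:

```python
import numpy as np
from enums_ne import (DemographyModel, HaplotypeMatrix, MCMCConfig,
                      RunConfig, run_enums, sim_sequences, sim_tree)

rng = np.random.default_rng(11)
demo = DemographyModel.constant(10_000)
parts, offset = [], 0
for _ in range(10):
    tree = sim_tree(20, demo, rng)
    parts.append(sim_sequences(tree, 2.5e-8, 5000, rng,
                               span_bp=5000, pos_offset=offset))
    offset += 6000
parts = [p for p in parts if p.n_sites]
matrix = HaplotypeMatrix(
    chromosome="1",
    positions=np.concatenate([p.positions for p in parts]),
    ref_alleles=np.concatenate([p.ref_alleles for p in parts]),
    alt_alleles=np.concatenate([p.alt_alleles for p in parts]),
    alleles=np.concatenate([p.alleles for p in parts], axis=1),
    haplotype_ids=parts[0].haplotype_ids,
    sample_ids=parts[0].sample_ids,
)

config = RunConfig(min_length_bp=0, master_seed=11,
                   mcmc=MCMCConfig(chain_length=2_000_000, thin=200))
result = run_enums(config, matrix=matrix)
```

Output:

```
blocks found: 10 | past TMRCA filter: 10
       0 YBP  Ne = 9,093
    5000 YBP  Ne = 9,093
   ...
   25000 YBP  Ne = 9,093
max/min ratio across the grid: 1.000
```

All ten loci are recognized as single FGT-clean blocks, every
posterior-median TMRCA exceeds 25,000 years (deep genealogies at
Ne = 10⁴), and the aggregated trajectory is flat at ≈ 9,100 — within 10%
of the simulated truth. The max/min ratio of 1.000 reflects that 5-kb
blocks at this sample size carry no resolvable signal of Ne *change*
inside 0–25,000 YBP; the level is what the data determine.

The same stages are available from the shell:

```bash
enums simulate --n 20 --ne 10000 --mu 2.5e-8 --length 5000 --seed 11 --out-vcf sim.vcf
enums blocks   --vcf sim.vcf --min-length 0 --out-bed blocks.bed --out-fasta-dir fasta
enums skyline  --fasta fasta/1_b0.fasta --block-length 5000 \
               --steps 2000000 --thin 200 --seed 11 --out skyline.tsv
```

which prints, e.g.,

```
wrote 8 SNPs x 20 haplotypes to sim.vcf
8 sites -> 1 blocks, 1 of >= 0 bp
retained 9000 draws; acceptance node_height=0.68, root_scale=0.64, ...
```

`enums trajectory`, `enums aggregate`, `enums fst` and `enums run
--config cfg.json` cover the remaining stages.

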