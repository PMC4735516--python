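# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.

## Model and units

The pipeline assumes an isolated, randomly mating diploid population
sampled at one time point, phased biallelic SNPs, infinite-sites
mutation, and a strict molecular clock. Three unit systems appear:

- **substitutions/site** — the chain's native time unit; all node heights
  and θ values live here. θ is defined so the pairwise coalescent rate is
  1/θ, hence θ = 2·Ne·μ with Ne in diploid individuals and μ in
  mutations/site/generation. The simulator uses the matching diploid
  convention: with k lineages the coalescence rate is k(k−1)/(4Ne) per
  generation.
- **generations** — simulator output; converts to substitutions/site by
  multiplying with μ.
- **years** — trajectory output; `years = (height/μ)·gen_years`.

Defaults: μ = 2.5×10⁻⁸ per site per generation, 25 years per generation,
grid 0–25,000 YBP at 1,000-year intervals (26 points; both grid
parameters are free, e.g. 500-year intervals or a 300,000-year horizon),
minimum block length 5,000 bp, minimum posterior-median TMRCA 25,000
years (boundary inclusive), Fst partition threshold 0.0012. Halving μ
doubles all inferred times — the rate is a straight calibration factor.

## Block construction

The four-gamete test is applied greedily left to right: a block grows
while the candidate site is pairwise compatible (≤ 3 distinct two-locus
gametes) with every site already inside; the first violation closes the
block before the violating site. This is the strictest contiguous
interpretation; boundaries are forced, so there are no ties. Sites
monomorphic in the sample are compatible with everything and never break
a block. Block coordinates are the first/last SNP positions — the only
coordinates the data define — and the length filter uses them.

Two resolution limits are inherent and documented rather than corrected:
the FGT misses crossovers that do not produce all four gametes, and at a
simulated splice the greedy block always absorbs the entire left side
(mutually compatible) plus any right-side rare variants — a singleton can
never complete four gametes — so detected boundaries sit at or slightly
beyond the true breakpoint.

## Skyline likelihood and prior

The substitution model is JC69; intraspecific SNP blocks carry almost no
information to fit richer models, and the likelihood enters mostly
through the number and placement of mutations. Site patterns are
compressed, and the positions of a block that carry no SNP record are
included as one invariant pattern so that θ is anchored per physical
site. The generalized-skyline coalescent density groups the n−1
coalescent intervals into m groups sharing one θ each (piecewise
constant; the linear variant is not implemented).

The per-group θ prior is uniform on log θ over [10⁻⁶, 10] — a
scale-invariant choice with hard bounds, deliberately simpler than an
autocorrelated smoothing prior. Its consequence: a group whose intervals
carry no realized mutations has an essentially unconstrained θ posterior.
The default group count therefore adapts to the data: the largest
m ≤ min(10, n−1) whose *tip-most* group (always the most data-poor — an
interval with k lineages expects 2θL/(k−1) mutations) still expects ≥ 8
segregating sites, which leaves fewer than 3 realized sites with ~1%
probability. For 5-kb human-scale blocks at n = 20 this typically yields
m = 1–3; `group_count` overrides the rule.

## MCMC

Metropolis–Hastings over (genealogy, θ vector, interval grouping) with
seven proposals: uniform slide of a non-root internal node, root-height
scale, narrow subtree exchange, per-group θ scale, shifting one interval
between adjacent groups, a joint scale of all heights and θs (the prior
is invariant under this map, so it traverses magnitudes freely), and an
exact Gibbs draw of one θ from its inverse-gamma conditional
IG(c_g, A_g), where c_g counts the group's coalescences and A_g sums
k(k−1)·Δt/2 over its intervals — exact because the likelihood does not
involve θ. Scale moves use s = exp(λ(u−½)) with the appropriate Jacobian
and Hastings terms; λ values (2.0 θ, 1.0 root, 3.0 joint) were chosen for
healthy acceptance on desk-scale blocks.

Starting state: UPGMA tree from p-distances (tied heights nudged apart by
10⁻⁹ to keep parent > child strict) and Watterson's θ per group. A
non-finite posterior at that state is an error. Chains record every
`thin` steps from the start; the burn-in fraction (default 10%) is
trimmed at access time, so a longer chain extends — never rewrites — the
recorded prefix for a fixed seed. Desk-scale default: 2×10⁶ steps,
thin 200 (≈ 6 s per block); the schedule scales to cluster settings
(e.g. 6×10⁸ steps, thin 2,000) unchanged. All randomness flows from one
seed per run; two runs with equal seeds are bit-identical, and pipeline
block seeds are a pure function of (master seed, block index), so
block-level parallelism cannot change results.

Sampler validation: with the likelihood forced constant the chain
samples the joint prior; long runs (3×10⁷ steps) reproduce flat decade
occupancy of log θ across all seven decades, and narrow-bound runs match
the closed-form prior mean to three decimals. Because E[θ] under the
full-width prior is dominated by the top decade, short validation chains
use several overdispersed starts (θ₀ drawn from the prior, start tree
rescaled accordingly) and a between-chain Monte-Carlo SE; a
Geyer initial-monotone-sequence MCSE utility (`mcse_mean`) is provided
for single-chain checks.

## Trajectories and aggregation

Grid times map to substitutions/site through the clock, each retained
draw is evaluated by piecewise-constant lookup over that draw's group
boundaries (a time on a boundary takes the older interval's value; times
beyond the root extend the root-most θ), and θ converts to Ne. The
per-time point estimate is the posterior median (robust to the heavy
upper tail the log-uniform prior permits; the mean is available), the
per-time uncertainty is the sample SD of the Ne draws, and the TMRCA
statistic is the posterior-median root height.

Weights are w = 1/sd, with zero SDs floored at the smallest positive SD
of that time point (equal weights, with a warning, if a whole column is
zero). The distance objective treats w linearly, giving
x̂_i = Σw²N/Σw²; a `weight_power=1` switch provides the alternative
reading (weights already squared). The closed form is verified against
numeric minimization — implemented as bracketed root-finding of the
objective's per-coordinate gradient, because value-based search cannot
resolve x below ~10⁻⁸ relative on this objective in float64. Note that
inverse-SD weighting concentrates on the blocks with the most confident
posteriors; with few blocks this makes the aggregate sensitive to any
block whose posterior is confidently wrong, which is one reason the
block-count regime of the method matters.

## Fst

Weir–Cockerham variance components adapted to haploid (haplotype-level)
counts for exactly two populations, combined over a block's polymorphic
sites as ratio of averages Σa/Σ(a+b). The estimator is unbiased, so
identical populations give slightly negative raw values; raw values are
reported and clamped at 0 for range reporting and threshold
partitioning. Blocks with no polymorphic site are flagged undefined and
excluded from partitioning.

## Simulator

Time-rescaled coalescent under piecewise-constant demography (exponential
waiting times truncated at epoch boundaries), Poisson mutations placed on
branches proportional to length, each at a fresh uniformly drawn bp
position (collisions capped with a warning — relevant only at extreme
θL). Binary 0/1 alleles map to random REF/ALT nucleotides on export, so
the JC69 likelihood is exercised on realistic alignments. The splice
fixture concatenates two independent genealogies at a known breakpoint;
the two-deme fixture coalesces within demes until a clean split time,
then pools lineages.

What the simulator does *not* emulate: recurrent mutation, gene
conversion, continuous recombination (ancestral recombination graphs),
migration, selection, sequencing or phasing error. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness of the method on real low-coverage data —
blocks from real panels violate infinite sites occasionally and carry
phasing switch errors that the FGT interprets as crossovers.

## Problem sizes used in validation

Oracle equivalences run on deliberately tiny instances where brute force
is exact (≤ 4 taxa for likelihood enumeration, 16 × 12 matrices for the
FGT oracle). Parameter recovery uses 20 replicates of n = 20 haplotypes
over 5,000 sites at Ne = 10,000 with 2×10⁶-step chains, and the
end-to-end check uses ten such blocks; at this scale a single block
determines the *level* of Ne to ~30% but cannot resolve change within
0–25,000 YBP (the expected tree has only ~7 of its 19 coalescences
there, and those intervals expect ≪ 1 mutation each on 5 kb). Resolving
recent dynamics, as in large resequencing panels, requires hundreds of
haplotypes and hundreds of blocks — two orders of magnitude more compute
than a test suite should spend, and exactly the regime the method's
weighted many-block averaging was designed for.

## Known limitations

- Piecewise-constant skyline only; no linear interpolation between
  grouped intervals.
- No smoothing prior across groups; the data-adaptive group count is the
  mitigation.
- Contemporaneous tips and a strict clock only.
- The TMRCA filter and grid use posterior medians; mean-based variants
  exist but are untested against each other on real data.
- Fst supports exactly two populations.
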