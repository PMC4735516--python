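"""Coalescent fixture generator with known truth.

Genealogies are drawn under piecewise-constant demography (diploid-Ne
convention: with k lineages the coalescence rate is k(k-1)/(4 Ne) per
generation), mutations are laid on branches under the infinite-sites
model as binary 0/1 alleles, and the result is packaged as the same
phased haplotype matrix the pipeline reads from VCF.  Single-crossover
splicing and clean two-deme splits provide ground truth for the block
finder and the Fst estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .block_finder import Block
from .genealogy import GenealogyTree
from .io_formats import HaplotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant Ne backward in time.

    ``epochs`` is a tuple of (start_generation, diploid_Ne); the first
    epoch must start at 0 and starts must strictly increase.
    """

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [e[0] for e in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must strictly increase")
        if any(e[1] <= 0 for e in self.epochs):
            raise ValueError("Ne must be positive")

    @classmethod
    def constant(cls, ne: float) -> "DemographyModel":
        return cls(((0.0, float(ne)),))

    def ne_at(self, t: float) -> float:
        ne = self.epochs[0][1]
        for start, size in self.epochs:
            if t >= start:
                ne = size
        return ne


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_tree(n: int, demography: DemographyModel, seed) -> GenealogyTree:
    """Coalescent genealogy; heights in generations.

    Waiting times are exponential with rate k(k-1)/(4 Ne) within an epoch
    and truncated at epoch boundaries (time-rescaled coalescent).
    """
    if n < 2:
        raise ValueError("need at least two tips")
    rng = _rng(seed)
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int32)
    left = np.full(total, -1, dtype=np.int32)
    right = np.full(total, -1, dtype=np.int32)
    heights = np.zeros(total)

    lineages = list(range(n))
    starts = [e[0] for e in demography.epochs]
    epoch = 0
    t = 0.0
    nxt = n
    while len(lineages) > 1:
        k = len(lineages)
        ne = demography.epochs[epoch][1]
        rate = k * (k - 1) / (4.0 * ne)
        wait = rng.exponential(1.0 / rate)
        boundary = starts[epoch + 1] if epoch + 1 < len(starts) else np.inf
        if t + wait >= boundary:
            t = boundary
            epoch += 1
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent[a] = parent[b] = nxt
        left[nxt], right[nxt] = a, b
        heights[nxt] = t
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    return GenealogyTree(n_tips=n, parent=parent, left=left, right=right,
                         heights=heights)


def sim_sequences(tree: GenealogyTree, mu: float, length: int, seed,
                  span_bp: int | None = None, pos_offset: int = 0,
                  chromosome: str = "1") -> HaplotypeMatrix:
    """Infinite-sites mutations on the genealogy -> phased 0/1 matrix.

    The expected mutation count is mu * length * total branch length
    (generations); each mutation lands on a fresh position drawn
    uniformly without replacement from [1 + pos_offset, span_bp +
    pos_offset] (``span_bp`` defaults to ``length``).  The ALT allele
    marks the tips below the mutated branch.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = _rng(seed)
    span = int(span_bp if span_bp is not None else length)
    bl = tree.branch_lengths()
    total_len = float(bl.sum())
    n_mut = rng.poisson(mu * length * total_len) if total_len > 0 and mu > 0 else 0
    if n_mut > span:
        warnings.warn(
            f"{n_mut} mutations exceed the {span}-bp span; "
            "capping (infinite-sites collision)", stacklevel=2,
        )
        n_mut = span

    n = tree.n_tips
    sample_ids = [f"s{i}" for i in range(n // 2)] if n % 2 == 0 else []
    if n_mut == 0:
        return HaplotypeMatrix(
            chromosome=chromosome,
            positions=np.empty(0, dtype=np.int64),
            ref_alleles=np.empty(0, dtype="<U1"),
            alt_alleles=np.empty(0, dtype="<U1"),
            alleles=np.empty((n, 0), dtype=np.int8),
            haplotype_ids=[f"s{i // 2}|{i % 2}" for i in range(n)],
            sample_ids=sample_ids,
        )

    probs = bl / total_len
    branch_nodes = rng.choice(tree.n_nodes, size=n_mut, p=probs)
    positions = np.sort(rng.choice(span, size=n_mut, replace=False) + 1 + pos_offset)
    order = rng.permutation(n_mut)  # decouple position order from branch draw order
    alleles = np.zeros((n, n_mut), dtype=np.int8)
    for col, bi in enumerate(order):
        carriers = tree.tips_below(int(branch_nodes[bi]))
        alleles[carriers, col] = 1
    refs = _BASES[rng.integers(0, 4, size=n_mut)]
    alts = np.array(
        [_BASES[(np.flatnonzero(_BASES != r))[rng.integers(0, 3)]] for r in refs]
    )
    return HaplotypeMatrix(
        chromosome=chromosome,
        positions=positions,
        ref_alleles=refs,
        alt_alleles=alts,
        alleles=alleles,
        haplotype_ids=[f"s{i // 2}|{i % 2}" for i in range(n)],
        sample_ids=sample_ids,
    )


def full_span_block(matrix: HaplotypeMatrix, span_bp: int,
                    block_id: str = "sim_block") -> Block:
    """Block covering a simulated region's full physical span (for
    invariant-site padding in the likelihood)."""
    if matrix.n_sites == 0:
        raise ValueError("matrix has no sites")
    return Block(
        chromosome=matrix.chromosome, start_pos=1, end_pos=span_bp,
        first_site=0, last_site=matrix.n_sites - 1, block_id=block_id,
    )


def sim_recombinant_block(n: int, demography: DemographyModel, mu: float,
                          length: int, breakpoint_bp: int, seed,
                          chromosome: str = "1"):
    """Two independent genealogies spliced at a known crossover point.

    Sites at positions <= breakpoint evolve on tree A, the rest on an
    independent tree B.  Returns (matrix, true_breakpoint_bp).
    """
    if not (0 < breakpoint_bp < length):
        raise ValueError("breakpoint must lie strictly inside the region")
    rng = _rng(seed)
    tree_a = sim_tree(n, demography, rng)
    tree_b = sim_tree(n, demography, rng)
    left = sim_sequences(tree_a, mu, breakpoint_bp, rng,
                         span_bp=breakpoint_bp, chromosome=chromosome)
    right = sim_sequences(tree_b, mu, length - breakpoint_bp, rng,
                          span_bp=length - breakpoint_bp,
                          pos_offset=breakpoint_bp, chromosome=chromosome)
    matrix = HaplotypeMatrix(
        chromosome=chromosome,
        positions=np.concatenate([left.positions, right.positions]),
        ref_alleles=np.concatenate([left.ref_alleles, right.ref_alleles]),
        alt_alleles=np.concatenate([left.alt_alleles, right.alt_alleles]),
        alleles=np.concatenate([left.alleles, right.alleles], axis=1),
        haplotype_ids=left.haplotype_ids,
        sample_ids=left.sample_ids,
    )
    return matrix, breakpoint_bp


def sim_two_demes(n_per_deme: int, ne: float, split_generations: float,
                  mu: float, length: int, seed, chromosome: str = "1"):
    """Clean split, no migration: within-deme coalescence until the split
    (backward in time), then one ancestral pool of the same size.

    Returns (matrix, sample -> deme labels); haplotypes 0..n_per_deme-1
    belong to deme1.
    """
    if split_generations < 0:
        raise ValueError("split time cannot be negative")
    if n_per_deme % 2:
        raise ValueError("n_per_deme must be even (haplotypes pair into "
                         "diploid samples, and samples cannot straddle demes)")
    rng = _rng(seed)
    n = 2 * n_per_deme
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int32)
    left_c = np.full(total, -1, dtype=np.int32)
    right_c = np.full(total, -1, dtype=np.int32)
    heights = np.zeros(total)
    demes = [list(range(n_per_deme)), list(range(n_per_deme, n))]
    t = 0.0
    nxt = n

    def merge(pool: list[int], time: float) -> None:
        nonlocal nxt
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = nxt
        left_c[nxt], right_c[nxt] = a, b
        heights[nxt] = time
        pool[:] = [x for x in pool if x not in (a, b)] + [nxt]
        nxt += 1

    while t < split_generations and sum(len(d) for d in demes) > 1:
        rates = [len(d) * (len(d) - 1) / (4.0 * ne) for d in demes]
        total_rate = sum(rates)
        if total_rate == 0:
            break
        wait = rng.exponential(1.0 / total_rate)
        if t + wait >= split_generations:
            break
        t += wait
        which = 0 if rng.random() < rates[0] / total_rate else 1
        merge(demes[which], t)

    pool = demes[0] + demes[1]
    t = max(t, split_generations)
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(4.0 * ne / (k * (k - 1)))
        merge(pool, t)

    tree = GenealogyTree(n_tips=n, parent=parent, left=left_c, right=right_c,
                         heights=heights)
    matrix = sim_sequences(tree, mu, length, rng, chromosome=chromosome)
    labels = {}
    for i in range(n_per_deme // 2):
        labels[f"s{i}"] = "deme1"
    for i in range(n_per_deme // 2, n_per_deme):
        labels[f"s{i}"] = "deme2"
    return matrix, labels
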