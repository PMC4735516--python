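"""Per-block Fst between two labeled subpopulations.

Weir–Cockerham variance-component estimator adapted to haploid
(haplotype-level) allele counts, combined across a block's polymorphic
sites as a ratio of averages: Fst = sum(a) / sum(a + b), where a is the
among-population and b the within-population component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .block_finder import Block
from .io_formats import HaplotypeMatrix


@dataclass
class FstResult:
    """Block Fst; ``fst`` is the raw ratio-of-averages estimate (may be
    slightly negative), ``fst_clamped`` floors it at 0 for reporting."""

    block_id: str
    fst: float
    n_sites: int
    defined: bool = True

    @property
    def fst_clamped(self) -> float:
        return max(self.fst, 0.0)


def _site_components(counts1: tuple[int, int], counts2: tuple[int, int]):
    """Haploid two-population variance components (a, b) for one site.

    counts: (ALT copies, haplotypes sampled) per population.  Uses the
    among/within mean squares with the standard n_c correction.
    """
    x1, n1 = counts1
    x2, n2 = counts2
    p1, p2 = x1 / n1, x2 / n2
    n_t = n1 + n2
    p_bar = (x1 + x2) / n_t
    r = 2
    n_c = (n_t - (n1 * n1 + n2 * n2) / n_t) / (r - 1)
    msp = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - r)
    a = (msp - msg) / n_c
    b = msg
    return a, b


def weir_cockerham_fst(matrix: HaplotypeMatrix, block: Block,
                       pop_labels: dict[str, str]) -> FstResult:
    """Block Fst between exactly two populations of phased haplotypes.

    ``pop_labels`` maps sample ids to population names; both haplotypes of
    a sample inherit its label.  Monomorphic sites carry no information
    and are skipped; a block with no polymorphic site returns an undefined
    (NaN, ``defined=False``) result.
    """
    pops = sorted(set(pop_labels.values()))
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations, got {pops}")
    rows: dict[str, list[int]] = {p: [] for p in pops}
    for h, hid in enumerate(matrix.haplotype_ids):
        sample = hid.rsplit("|", 1)[0]
        if sample in pop_labels:
            rows[pop_labels[sample]].append(h)
    for p in pops:
        if len(rows[p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 haplotypes")

    a_sum = b_sum = 0.0
    n_used = 0
    sl = block.site_slice
    sub1 = matrix.alleles[rows[pops[0]], sl]
    sub2 = matrix.alleles[rows[pops[1]], sl]
    n1, n2 = sub1.shape[0], sub2.shape[0]
    for s in range(sub1.shape[1]):
        x1 = int(sub1[:, s].sum())
        x2 = int(sub2[:, s].sum())
        if x1 + x2 == 0 or x1 + x2 == n1 + n2:
            continue  # monomorphic across the two populations
        a, b = _site_components((x1, n1), (x2, n2))
        a_sum += a
        b_sum += b
        n_used += 1
    if n_used == 0:
        return FstResult(block_id=block.block_id, fst=float("nan"),
                         n_sites=0, defined=False)
    return FstResult(block_id=block.block_id, fst=a_sum / (a_sum + b_sum),
                     n_sites=n_used)


def partition_by_fst(results: list[FstResult],
                     threshold: float = 0.0012) -> tuple[list[FstResult],
                                                         list[FstResult]]:
    """Split into (low, high): high means Fst strictly above the threshold
    (the genome-wide average between the two samples); undefined results
    are excluded from both."""
    low = [r for r in results if r.defined and r.fst_clamped <= threshold]
    high = [r for r in results if r.defined and r.fst_clamped > threshold]
    return low, high
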