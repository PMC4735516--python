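"""Four-gamete-test partitioning of haplotypes into crossover-free blocks.

Under the infinite-sites model, observing all four two-locus gametes
(00, 01, 10, 11) at a pair of SNPs implies at least one historical
crossover between them.  A block is a maximal contiguous run of sites in
which every internal pair shows at most three gametes, so the block can be
modelled with a single genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HaplotypeMatrix


@dataclass(frozen=True)
class Block:
    """Contiguous FGT-clean interval; coordinates 1-based inclusive bp."""

    chromosome: str
    start_pos: int
    end_pos: int
    first_site: int          # index into the matrix columns
    last_site: int           # inclusive
    block_id: str = ""

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def n_sites(self) -> int:
        return self.last_site - self.first_site + 1

    @property
    def site_slice(self) -> slice:
        return slice(self.first_site, self.last_site + 1)


def gamete_count(matrix: HaplotypeMatrix, i: int, j: int) -> int:
    """Distinct ordered (allele_i, allele_j) pairs across all haplotypes."""
    n = matrix.n_sites
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"site index out of range (n_sites={n})")
    if i == j:
        raise ValueError("gamete count requires two distinct sites")
    combo = 2 * matrix.alleles[:, i].astype(np.int8) + matrix.alleles[:, j]
    return int(np.unique(combo).size)


def fgt_compatible(matrix: HaplotypeMatrix, i: int, j: int) -> bool:
    """True iff fewer than four gametes: no crossover trace between i and j."""
    return gamete_count(matrix, i, j) < 4


def _pair_compatible(a_i: np.ndarray, a_j: np.ndarray) -> bool:
    # Four gametes iff both sites polymorphic and all of 00,01,10,11 seen.
    combo = 2 * a_i + a_j
    return np.unique(combo).size < 4


def partition_blocks(matrix: HaplotypeMatrix) -> list[Block]:
    """Greedy left-to-right maximal FGT-clean partition of the site range.

    Starting at the leftmost unassigned site, the block is extended
    rightward while the candidate site is pairwise compatible with every
    site already in the block; the first violation closes the block before
    the violating site.  The result is a complete, non-overlapping,
    ordered partition of all sites.
    """
    if matrix.n_sites < 1:
        raise ValueError("need at least one site to partition")
    alleles = matrix.alleles.astype(np.int8)
    blocks: list[Block] = []
    start = 0
    n = matrix.n_sites
    while start < n:
        end = start
        for j in range(start + 1, n):
            ok = True
            for i in range(start, j):
                if not _pair_compatible(alleles[:, i], alleles[:, j]):
                    ok = False
                    break
            if not ok:
                break
            end = j
        blocks.append(
            Block(
                chromosome=matrix.chromosome,
                start_pos=int(matrix.positions[start]),
                end_pos=int(matrix.positions[end]),
                first_site=start,
                last_site=end,
                block_id=f"{matrix.chromosome}_b{len(blocks)}",
            )
        )
        start = end + 1
    return blocks


def filter_blocks(blocks: list[Block], min_length_bp: int = 5000) -> list[Block]:
    """Keep blocks spanning at least ``min_length_bp`` (boundary inclusive)."""
    if min_length_bp < 0:
        raise ValueError("min_length_bp must be non-negative")
    return [b for b in blocks if b.length_bp >= min_length_bp]
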