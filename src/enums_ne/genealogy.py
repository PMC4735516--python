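"""Binary ultrametric genealogies shared by the simulator and the MCMC.

Nodes are indexed 0..2n-2: tips are 0..n-1 (height 0, contemporaneous
sampling), internal nodes n..2n-2.  Heights are stored in whichever unit
the producer uses — generations for the coalescent simulator,
substitutions/site for the skyline machinery — and converted with
:meth:`GenealogyTree.scaled`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenealogyTree:
    """Rooted binary tree with tips at height 0 and parent above child."""

    n_tips: int
    parent: np.ndarray        # int32, (2n-1,); root has parent -1
    left: np.ndarray          # int32, (2n-1,); -1 for tips
    right: np.ndarray
    heights: np.ndarray       # float64, (2n-1,); tips exactly 0
    tip_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int32)
        self.left = np.asarray(self.left, dtype=np.int32)
        self.right = np.asarray(self.right, dtype=np.int32)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if not self.tip_labels:
            self.tip_labels = [f"t{i}" for i in range(self.n_tips)]
        self.validate()

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def root_height(self) -> float:
        """TMRCA of the sample, in the tree's height unit."""
        return float(self.heights[self.root])

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise ValueError("a genealogy needs at least two tips")
        for arr in (self.parent, self.left, self.right, self.heights):
            if arr.shape != (2 * n - 1,):
                raise ValueError("tree arrays must have length 2n-1")
        if np.any(self.heights[:n] != 0.0):
            raise ValueError("tips must sit at height 0 (contemporaneous sampling)")
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("exactly one root required")
        for u in range(n, 2 * n - 1):
            for c in (self.left[u], self.right[u]):
                if c < 0:
                    raise ValueError("internal node missing a child")
                if self.heights[u] <= self.heights[c]:
                    raise ValueError("parent height must exceed child height")
                if self.parent[c] != u:
                    raise ValueError("parent/child arrays disagree")

    def coalescent_times(self) -> np.ndarray:
        """Sorted internal-node heights: the n-1 coalescence times."""
        return np.sort(self.heights[self.n_tips:])

    def branch_lengths(self) -> np.ndarray:
        """Per-node length of the branch to the parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        for u in range(self.n_nodes):
            p = self.parent[u]
            if p >= 0:
                out[u] = self.heights[p] - self.heights[u]
        return out

    def tips_below(self, node: int) -> np.ndarray:
        """Tip indices in the clade under ``node`` (inclusive for a tip)."""
        stack, tips = [node], []
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                tips.append(u)
            else:
                stack.extend((self.left[u], self.right[u]))
        return np.array(sorted(tips), dtype=np.int64)

    def scaled(self, factor: float) -> "GenealogyTree":
        """New tree with all heights multiplied by ``factor`` (unit change)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return GenealogyTree(
            n_tips=self.n_tips,
            parent=self.parent.copy(),
            left=self.left.copy(),
            right=self.right.copy(),
            heights=self.heights * factor,
            tip_labels=list(self.tip_labels),
        )

    def to_newick(self) -> str:
        def rec(u: int) -> str:
            p = self.parent[u]
            bl = self.heights[p] - self.heights[u] if p >= 0 else 0.0
            if u < self.n_tips:
                return f"{self.tip_labels[u]}:{bl:.10g}"
            return f"({rec(self.left[u])},{rec(self.right[u])}):{bl:.10g}"

        return rec(self.root) + ";"


def upgma_tree(distances: np.ndarray, tip_labels: list[str] | None = None,
               min_step: float = 1e-9) -> GenealogyTree:
    """Average-linkage (UPGMA) ultrametric tree from a distance matrix.

    Heights are half the merge distance; ties and zero distances are
    nudged apart by ``min_step`` so every internal branch is strictly
    positive (the MCMC needs strict parent > child).
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = distances.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    condensed = squareform(np.asarray(distances, dtype=float), checks=False)
    merges = linkage(condensed, method="average")

    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int32)
    left = np.full(total, -1, dtype=np.int32)
    right = np.full(total, -1, dtype=np.int32)
    heights = np.zeros(total)
    prev_h = 0.0
    for k, (a, b, dist, _cnt) in enumerate(merges):
        u = n + k
        a, b = int(a), int(b)
        h = max(dist / 2.0, prev_h + min_step)
        prev_h = h
        heights[u] = h
        left[u], right[u] = a, b
        parent[a] = parent[b] = u
    return GenealogyTree(
        n_tips=n, parent=parent, left=left, right=right,
        heights=heights, tip_labels=tip_labels or [],
    )
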