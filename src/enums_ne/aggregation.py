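"""Combining block trajectories into one population trajectory.

The population Ne vector is the minimizer of the weighted squared
Euclidean distance to all block vectors,

    F(x) = sum_j || diag(w_j) (x - N_j) ||^2 ,

whose closed-form solution (by convexity, setting the gradient to zero)
is, per time point i,

    x_hat_i = sum_j w_ji^2 N_ji / sum_j w_ji^2 ,

with w_ji the inverse of block j's posterior SD of Ne at time i.  An
unweighted variant (plain per-time mean) and labeled-subset comparisons
are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory import BlockTrajectory


@dataclass
class WeightMatrix:
    """Per-block, per-time positive weights (rows follow the block list)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("weights must be a blocks x times matrix")
        if not np.all(np.isfinite(self.w)) or np.any(self.w <= 0):
            raise ValueError("weights must be finite and positive")


@dataclass
class PopulationTrajectory:
    """Aggregated Ne per grid time over M blocks."""

    x_hat: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float)
        if np.any(self.x_hat <= 0):
            raise ValueError("aggregated Ne must be positive")


def compute_weights(trajectories: list[BlockTrajectory]) -> WeightMatrix:
    """Inverse-SD weights, w_ji = 1 / sd_ji.

    A zero SD (degenerate posterior) is floored at the smallest positive
    SD observed at that time point; if every block has zero SD at a time
    point the weights there fall back to equal, with a warning.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    sd = np.vstack([t.sd_j for t in trajectories])
    w = np.empty_like(sd)
    for i in range(sd.shape[1]):
        col = sd[:, i]
        pos = col[col > 0]
        if pos.size == 0:
            warnings.warn(
                f"all posterior SDs are zero at time index {i}; "
                "using equal weights there", stacklevel=2,
            )
            w[:, i] = 1.0
        else:
            w[:, i] = 1.0 / np.where(col > 0, col, pos.min())
    return WeightMatrix(w)


def aggregate(trajectories: list[BlockTrajectory],
              weights: WeightMatrix | None = None,
              weight_power: int = 2) -> PopulationTrajectory:
    """Closed-form minimizer of the weighted squared-distance objective.

    ``weight_power=2`` treats the stored weights as entering the distance
    linearly (inverse-variance-style combination); ``weight_power=1``
    treats them as already squared.
    """
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    if weight_power not in (1, 2):
        raise ValueError("weight_power must be 1 or 2")
    N = np.vstack([t.N_j for t in trajectories])
    if weights is None:
        weights = compute_weights(trajectories)
    w = weights.w
    if w.shape != N.shape:
        raise ValueError("weight shape does not match trajectories")
    wp = w**weight_power
    x_hat = (wp * N).sum(axis=0) / wp.sum(axis=0)
    return PopulationTrajectory(x_hat=x_hat, M=len(trajectories))


def aggregate_unweighted(trajectories: list[BlockTrajectory]) -> PopulationTrajectory:
    """Per-time arithmetic mean: every block weighted equally."""
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    N = np.vstack([t.N_j for t in trajectories])
    return PopulationTrajectory(x_hat=N.mean(axis=0), M=len(trajectories))


def subset_compare(trajectories: list[BlockTrajectory],
                   labels: dict[str, str],
                   weight_power: int = 2) -> tuple[dict, float]:
    """Aggregate per labeled subset and quantify their divergence.

    Returns (subset -> PopulationTrajectory, divergence), where the
    divergence is the maximum over time points and subset pairs of the
    relative difference |x_A - x_B| / mean(x_A, x_B).  Empty subsets are
    omitted with a warning; with fewer than two subsets the divergence is
    0.0 by convention.
    """
    groups: dict[str, list[BlockTrajectory]] = {}
    for t in trajectories:
        if t.block_id not in labels:
            raise ValueError(f"block {t.block_id!r} has no subset label")
        groups.setdefault(labels[t.block_id], []).append(t)
    out: dict[str, PopulationTrajectory] = {}
    for name, members in sorted(groups.items()):
        if not members:
            warnings.warn(f"subset {name!r} is empty; omitted", stacklevel=2)
            continue
        out[name] = aggregate(members, compute_weights(members), weight_power)
    names = list(out)
    div = 0.0
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            xa, xb = out[names[a]].x_hat, out[names[b]].x_hat
            rel = np.abs(xa - xb) / ((xa + xb) / 2.0)
            div = max(div, float(rel.max()))
    return out, div
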