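"""Per-block Bayesian skyline estimation.

A Metropolis–Hastings chain samples jointly over the block genealogy and a
grouped piecewise-constant population-size function, under a JC69
substitution likelihood with a strict clock (rate folded into the height
unit, substitutions/site) and a scale-invariant prior on each group's
theta.  Theta is defined so that the pairwise coalescent rate is 1/theta
in substitutions/site time, i.e. theta = 2 * Ne_diploid * mu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .genealogy import GenealogyTree, upgma_tree
from .io_formats import HaplotypeMatrix

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}


class BlockAlignment:
    """Pattern-compressed nucleotide alignment for one haplotype block.

    Stores the distinct site patterns (states 0..3 = A,C,G,T) and their
    multiplicities.  Monomorphic positions inside the block that carry no
    SNP record are represented by one constant pattern, so the likelihood
    is anchored to the block's physical length and theta comes out in
    per-site units.
    """

    def __init__(self, patterns: np.ndarray, counts: np.ndarray,
                 ids: list[str], total_sites: int):
        self.patterns = np.asarray(patterns, dtype=np.int8)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.ids = list(ids)
        self.total_sites = int(total_sites)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != self.counts.shape[0]:
            raise ValueError("patterns and counts disagree")
        if self.patterns.size and (
            self.patterns.min() < 0 or self.patterns.max() > 3
        ):
            raise ValueError("non-ACGT state in alignment")

    @property
    def n_seqs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_variable_sites(self) -> int:
        nv = 0
        for p in range(self.patterns.shape[1]):
            if np.unique(self.patterns[:, p]).size > 1:
                nv += int(self.counts[p])
        return nv

    @classmethod
    def from_site_matrix(cls, states: np.ndarray, ids: list[str],
                         n_invariant_pad: int = 0) -> "BlockAlignment":
        """Compress a (n_seqs, n_sites) state matrix into patterns."""
        states = np.asarray(states, dtype=np.int8)
        if states.size:
            cols, counts = np.unique(states, axis=1, return_counts=True)
        else:
            cols = np.empty((states.shape[0], 0), dtype=np.int8)
            counts = np.empty(0, dtype=np.int64)
        counts = counts.astype(float)
        if n_invariant_pad > 0:
            pad = np.zeros((states.shape[0], 1), dtype=np.int8)  # all-A column
            cols = np.concatenate([cols, pad], axis=1)
            counts = np.concatenate([counts, [float(n_invariant_pad)]])
        return cls(cols, counts, ids, total_sites=states.shape[1] + n_invariant_pad)

    @classmethod
    def from_haplotype_matrix(cls, matrix: HaplotypeMatrix, block,
                              pad_invariant: bool = True) -> "BlockAlignment":
        """Alignment over a block: REF base where allele 0, ALT where 1.

        With ``pad_invariant`` the positions of the block that carry no SNP
        are added as monomorphic sites (length_bp minus SNP count).
        """
        sl = block.site_slice
        refs = np.array([_NUC[b] for b in matrix.ref_alleles[sl]], dtype=np.int8)
        alts = np.array([_NUC[b] for b in matrix.alt_alleles[sl]], dtype=np.int8)
        a = matrix.alleles[:, sl]
        states = np.where(a == 0, refs[None, :], alts[None, :]).astype(np.int8)
        pad = max(block.length_bp - states.shape[1], 0) if pad_invariant else 0
        return cls.from_site_matrix(states, list(matrix.haplotype_ids), pad)

    @classmethod
    def from_sequences(cls, ids: list[str], seqs: list[str],
                       total_length: int | None = None) -> "BlockAlignment":
        """From raw sequence strings; ``total_length`` pads invariant sites
        when the strings hold only the SNP columns of a longer block."""
        mat = np.empty((len(seqs), len(seqs[0])), dtype=np.int8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s):
                if ch not in _NUC:
                    raise ValueError(f"non-ACGT character {ch!r} in sequence {ids[i]}")
                mat[i, j] = _NUC[ch]
        pad = 0
        if total_length is not None:
            if total_length < mat.shape[1]:
                raise ValueError("total_length shorter than the alignment")
            pad = total_length - mat.shape[1]
        return cls.from_site_matrix(mat, ids, pad)


@dataclass
class SkylineParameters:
    """Grouped piecewise-constant skyline: thetas per group, coalescent
    intervals per group (summing to n-1, tip-most group first)."""

    group_sizes: np.ndarray
    thetas: np.ndarray

    def __post_init__(self) -> None:
        self.group_sizes = np.asarray(self.group_sizes, dtype=np.int64)
        self.thetas = np.asarray(self.thetas, dtype=np.float64)
        if self.group_sizes.shape != self.thetas.shape:
            raise ValueError("one theta per group required")
        if np.any(self.group_sizes < 1):
            raise ValueError("group sizes must be positive")
        if np.any(self.thetas <= 0):
            raise ValueError("thetas must be positive")


@dataclass
class MCMCConfig:
    """Chain schedule and proposal tuning.

    Desk-scale defaults (2e6 steps, thin 200, 10% burn-in) keep one block
    to seconds; the schedule is fully configurable up to cluster scale.
    """

    chain_length: int = 2_000_000
    thin: int = 200
    burn_in_fraction: float = 0.1
    seed: int = 0
    group_count: int | None = None      # default min(10, n-1)
    theta_bounds: tuple[float, float] = (1e-6, 10.0)
    move_weights: tuple[float, ...] = (0.25, 0.10, 0.15, 0.10, 0.05, 0.15, 0.20)
    lam_theta: float = 2.0
    lam_root: float = 1.0
    lam_joint: float = 3.0

    def __post_init__(self) -> None:
        if self.chain_length < self.thin:
            raise ValueError("chain_length must be at least thin")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if len(self.move_weights) != _kernel.N_MOVES:
            raise ValueError(f"need {_kernel.N_MOVES} move weights")


class SkylinePosterior:
    """Retained post-burn-in draws of (coalescent times, thetas, grouping)."""

    def __init__(self, coal_times: np.ndarray, thetas: np.ndarray,
                 group_sizes: np.ndarray, n_tips: int,
                 config: MCMCConfig, acceptance: dict[str, float],
                 burn_in_draws: int):
        self._raw_ct = coal_times
        self._raw_th = thetas
        self._raw_gs = group_sizes
        self.n_tips = n_tips
        self.config = config
        self.acceptance = acceptance
        self._burn = burn_in_draws

    # raw = every recorded draw including burn-in (determinism/prefix checks)
    @property
    def raw_coal_times(self) -> np.ndarray:
        return self._raw_ct

    @property
    def coal_times(self) -> np.ndarray:
        return self._raw_ct[self._burn:]

    @property
    def thetas(self) -> np.ndarray:
        return self._raw_th[self._burn:]

    @property
    def group_sizes(self) -> np.ndarray:
        return self._raw_gs[self._burn:]

    @property
    def n_samples(self) -> int:
        return self._raw_ct.shape[0] - self._burn

    @property
    def root_heights(self) -> np.ndarray:
        """TMRCA draws, substitutions/site."""
        return self.coal_times[:, -1]

    def group_boundaries(self) -> np.ndarray:
        """(n_samples, m) per-draw upper time boundary of each group."""
        cum = np.cumsum(self.group_sizes, axis=1) - 1
        return np.take_along_axis(self.coal_times, cum, axis=1)

    def theta_at_times(self, times: np.ndarray) -> np.ndarray:
        """(n_samples, len(times)) piecewise-constant theta lookups."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        bounds = self.group_boundaries()
        m = bounds.shape[1]
        out = np.empty((self.n_samples, times.shape[0]))
        for s in range(self.n_samples):
            idx = np.searchsorted(bounds[s], times, side="left")
            # t exactly on a boundary belongs to the older (root-ward) side
            on_edge = idx < m
            idx2 = idx.copy()
            edge_hits = on_edge & (np.take(bounds[s], np.minimum(idx, m - 1)) == times)
            idx2[edge_hits] += 1
            idx2 = np.minimum(idx2, m - 1)
            out[s] = self.thetas[s, idx2]
        return out


def skyline_at_time(coal_times: np.ndarray, group_sizes: np.ndarray,
                    thetas: np.ndarray, t: float) -> float:
    """Theta of one draw at time ``t`` (substitutions/site).

    Piecewise-constant over the draw's group boundaries; a time at an
    internal boundary takes the older interval's value, and times beyond
    the root return the root-most group's theta.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    bounds = np.take(np.asarray(coal_times), np.cumsum(group_sizes) - 1)
    idx = int(np.searchsorted(bounds, t, side="left"))
    if idx < bounds.shape[0] and bounds[idx] == t:
        idx += 1
    idx = min(idx, len(thetas) - 1)
    return float(thetas[idx])


def tree_log_likelihood(alignment: BlockAlignment, tree: GenealogyTree) -> float:
    """JC69 pruning log-likelihood of the alignment on the clock tree."""
    if tree.n_tips != alignment.n_seqs:
        raise ValueError("tip count does not match alignment")
    if not np.all(np.isfinite(tree.heights)):
        raise ValueError("non-finite node height")
    return float(
        _kernel.jc69_loglik(
            alignment.patterns, alignment.counts,
            tree.left, tree.right, tree.heights, tree.n_tips,
        )
    )


def coalescent_log_density(tree: GenealogyTree,
                           params: SkylineParameters) -> float:
    """Log density of the genealogy under the grouped skyline coalescent
    alone (no theta prior): an interval ending in the i-th coalescence
    with k = n - i lineages and duration dt contributes
    ln(k(k-1)/(2 theta)) - k(k-1) dt / (2 theta)."""
    if int(params.group_sizes.sum()) != tree.n_tips - 1:
        raise ValueError("group sizes must sum to n-1")
    return float(
        _kernel.coalescent_log_density(
            tree.heights, tree.n_tips, params.group_sizes, params.thetas
        )
    )


def skyline_log_prior(tree: GenealogyTree, params: SkylineParameters,
                      theta_bounds: tuple[float, float] = (1e-6, 10.0)) -> float:
    """Coalescent density of the genealogy under the grouped skyline, plus
    the uniform-on-log theta prior."""
    if int(params.group_sizes.sum()) != tree.n_tips - 1:
        raise ValueError("group sizes must sum to n-1")
    return float(
        _kernel._log_prior(
            tree.heights, tree.n_tips, params.group_sizes, params.thetas,
            theta_bounds[0], theta_bounds[1],
        )
    )


def _default_group_count(n: int, n_var: int) -> int:
    """Largest group count whose tip-most group still expects >= 8
    segregating sites.

    With k lineages an interval expects 2*theta*L/(k-1) mutations, so the
    tip-most group always carries the least data; under the independent
    uniform-log theta prior a group with no realized mutations is
    prior-dominated and its Ne estimate meaningless.  The expected share
    of segregating sites in the g tip-most intervals is
    (H_{n-1} - H_{n-1-g}) / H_{n-1} of the total, with H the harmonic
    number; requiring an expectation of 8 leaves fewer than 3 realized
    sites with probability ~1% (Poisson).
    """
    if n_var < 1:
        return 1
    h = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, n))])  # h[j] = H_j
    best = 1
    for m in range(2, min(10, n - 1) + 1):
        g = -(-(n - 1) // m)  # tip group size under the even split
        tip_expect = n_var * (h[n - 1] - h[n - 1 - g]) / h[n - 1]
        if tip_expect >= 8.0:
            best = m
    return best


def _even_groups(n_intervals: int, m: int) -> np.ndarray:
    base, extra = divmod(n_intervals, m)
    sizes = np.full(m, base, dtype=np.int64)
    sizes[:extra] += 1
    return sizes


def _init_state(alignment: BlockAlignment, m: int,
                theta_bounds: tuple[float, float]):
    """UPGMA starting tree from p-distances; theta from Watterson."""
    n = alignment.n_seqs
    pat = alignment.patterns.astype(np.int16)
    w = alignment.counts
    total = alignment.total_sites
    D = np.zeros((n, n))
    for i in range(n):
        diff = (pat != pat[i][None, :]).astype(float) @ w
        D[i] = diff / max(total, 1)
    np.fill_diagonal(D, 0.0)
    tree = upgma_tree(D, tip_labels=alignment.ids, min_step=1e-9)

    S = alignment.n_variable_sites
    a_n = np.sum(1.0 / np.arange(1, n))
    theta0 = S / (2.0 * a_n * max(total, 1)) if S > 0 else 1e-4
    theta0 = float(np.clip(theta0, theta_bounds[0] * 10, theta_bounds[1] / 10))
    # keep the start tree consistent with theta0's time scale
    if tree.root_height <= 0:
        tree.heights[n:] = theta0 * np.linspace(0.1, 1.0, n - 1)
    params = SkylineParameters(_even_groups(n - 1, m), np.full(m, theta0))
    return tree, params


def mcmc_run(alignment: BlockAlignment, config: MCMCConfig,
             sample_prior: bool = False) -> SkylinePosterior:
    """Run the seeded Metropolis–Hastings chain for one block.

    With ``sample_prior`` the likelihood is held constant, so the chain
    samples the joint prior exactly (the standard sampler validation).
    """
    n = alignment.n_seqs
    if n < 3:
        raise ValueError("need at least 3 haplotypes")
    n_var = alignment.n_variable_sites
    if n_var == 0 and not sample_prior:
        warnings.warn("no variable site in block; posterior follows the prior",
                      stacklevel=2)
    if config.group_count is not None:
        m = config.group_count
    else:
        m = _default_group_count(n, n_var)
    m = int(min(m, n - 1))

    n_recorded = config.chain_length // config.thin
    burn_draws = int(np.floor(n_recorded * config.burn_in_fraction))
    if n_recorded - burn_draws < 100:
        raise ValueError(
            f"chain retains only {n_recorded - burn_draws} draws; "
            "need at least 100 (lengthen the chain or thin less)"
        )

    tree, params = _init_state(alignment, m, config.theta_bounds)
    if sample_prior:
        # overdisperse starts across the prior's full range: a shared
        # data-derived start would bias short prior-validation chains
        rng = np.random.default_rng(int(config.seed) % (2**31))
        lo, hi = config.theta_bounds
        theta0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        scale = theta0 / params.thetas[0]
        tree.heights[tree.n_tips:] *= scale
        params = SkylineParameters(params.group_sizes, np.full(m, theta0))
    lp0 = skyline_log_prior(tree, params, config.theta_bounds)
    ll0 = 0.0 if sample_prior else tree_log_likelihood(alignment, tree)
    if not np.isfinite(lp0 + ll0):
        raise ValueError("non-finite posterior at the UPGMA starting state")

    ct, th, gs, acc, tries = _kernel.run_chain(
        alignment.patterns, alignment.counts,
        tree.parent.copy(), tree.left.copy(), tree.right.copy(),
        tree.heights.copy(),
        params.thetas.copy(), params.group_sizes.copy(),
        config.chain_length, config.thin, int(config.seed) % (2**31),
        np.asarray(config.move_weights, dtype=np.float64),
        config.lam_theta, config.lam_root, config.lam_joint,
        config.theta_bounds[0], config.theta_bounds[1],
        sample_prior,
    )
    acceptance = {
        name: (acc[i] / tries[i] if tries[i] else float("nan"))
        for i, name in enumerate(_kernel.MOVE_NAMES)
    }
    return SkylinePosterior(ct, th, gs, n, config, acceptance, burn_draws)


def mcse_mean(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean of a correlated chain.

    Uses the autocovariance summed under Geyer's initial monotone positive
    sequence, which is consistent for reversible chains and does not
    understate the error when the integrated autocorrelation time is long.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        return 0.0
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}: keep while positive and
    # non-increasing
    gam_prev = np.inf
    total = 0.0
    m = 0
    while 2 * m + 1 < n:
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        g = min(g, gam_prev)
        total += g
        gam_prev = g
        m += 1
    tau = max(2.0 * total - 1.0, 1.0)  # integrated autocorrelation time
    return float(np.sqrt(acov[0] * tau / n))


def posterior_summary(posterior: SkylinePosterior, times: np.ndarray) -> dict:
    """Per-time mean/median/SD/central-95% of theta, plus the TMRCA summary.

    ``times`` are in substitutions/site, the chain's native unit.
    """
    if posterior.n_samples < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    draws = posterior.theta_at_times(np.asarray(times, dtype=float))
    rh = posterior.root_heights
    return {
        "times": np.asarray(times, dtype=float),
        "mean": draws.mean(axis=0),
        "median": np.median(draws, axis=0),
        "sd": draws.std(axis=0, ddof=1),
        "lower95": np.quantile(draws, 0.025, axis=0),
        "upper95": np.quantile(draws, 0.975, axis=0),
        "tmrca": {
            "mean": float(rh.mean()),
            "median": float(np.median(rh)),
            "sd": float(rh.std(ddof=1)),
            "lower95": float(np.quantile(rh, 0.025)),
            "upper95": float(np.quantile(rh, 0.975)),
        },
    }
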