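"""Calendar rescaling and discretization of skyline posteriors.

Skyline output lives in substitutions/site; trajectories live on a fixed
year grid.  With mutation rate mu per site per generation and g years per
generation, a height h converts as years = (h / mu) * g, and theta
converts to diploid effective size as Ne = theta / (2 mu).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skyline_mcmc import SkylinePosterior


@dataclass(frozen=True)
class ClockScaling:
    """Strict-clock unit conversions: mu per site per generation, years
    per generation.  Defaults follow the neutral-rate calibration of
    2.5e-8 with 25-year generations."""

    mu: float = 2.5e-8
    gen_years: float = 25.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_years <= 0:
            raise ValueError("mu and gen_years must be positive")

    def height_to_years(self, height: float | np.ndarray):
        return (np.asarray(height, dtype=float) / self.mu) * self.gen_years

    def years_to_height(self, years: float | np.ndarray):
        return (np.asarray(years, dtype=float) / self.gen_years) * self.mu

    def theta_to_ne(self, theta: float | np.ndarray):
        """Diploid Ne from theta = 2 * Ne * mu."""
        return np.asarray(theta, dtype=float) / (2.0 * self.mu)


def rescale_to_years(height, clock: ClockScaling):
    """Substitutions/site -> years before present (linear, monotone)."""
    h = np.asarray(height, dtype=float)
    if np.any(h < 0):
        raise ValueError("height must be non-negative")
    out = clock.height_to_years(h)
    return float(out) if np.isscalar(height) else out


@dataclass(frozen=True)
class TimeGrid:
    """Evenly spaced year grid 0, interval, ..., t_max (inclusive)."""

    t_max: int = 25_000
    interval: int = 1_000

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.t_max <= 0:
            raise ValueError("t_max and interval must be positive")
        if self.t_max % self.interval != 0:
            raise ValueError("interval must divide t_max")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0, self.t_max + self.interval, self.interval, dtype=float)

    @property
    def count(self) -> int:
        return self.t_max // self.interval + 1


def make_grid(t_max: int = 25_000, interval: int = 1_000) -> TimeGrid:
    """Grid of t_max/interval + 1 points starting at the present (0)."""
    return TimeGrid(t_max=t_max, interval=interval)


@dataclass
class BlockTrajectory:
    """One block's Ne dynamics on the grid: point estimate, posterior SD
    per time point, and the posterior-median TMRCA in years."""

    block_id: str
    N_j: np.ndarray
    sd_j: np.ndarray
    tmrca_years: float

    def __post_init__(self) -> None:
        self.N_j = np.asarray(self.N_j, dtype=float)
        self.sd_j = np.asarray(self.sd_j, dtype=float)
        if self.N_j.shape != self.sd_j.shape:
            raise ValueError("N_j and sd_j must have the same length")
        if np.any(self.N_j <= 0):
            raise ValueError("Ne values must be positive")
        if np.any(self.sd_j < 0):
            raise ValueError("posterior SDs cannot be negative")


def block_trajectory(posterior: SkylinePosterior, grid: TimeGrid,
                     clock: ClockScaling, block_id: str = "",
                     point_estimate: str = "median") -> BlockTrajectory:
    """Discretize a block posterior onto the year grid.

    Each grid time maps back to substitutions/site, every retained draw is
    evaluated through the piecewise-constant skyline (draws older than a
    draw's root extend the root-most theta), thetas convert to diploid Ne,
    and the per-time median (or mean) and sample SD across draws are
    recorded.
    """
    if posterior.n_samples == 0:
        raise ValueError("empty posterior")
    if point_estimate not in ("median", "mean"):
        raise ValueError("point_estimate must be 'median' or 'mean'")
    heights = clock.years_to_height(grid.times)
    ne_draws = clock.theta_to_ne(posterior.theta_at_times(heights))
    if point_estimate == "median":
        point = np.median(ne_draws, axis=0)
    else:
        point = ne_draws.mean(axis=0)
    sd = ne_draws.std(axis=0, ddof=1) if ne_draws.shape[0] > 1 else np.zeros(
        ne_draws.shape[1]
    )
    tmrca_years = float(
        rescale_to_years(float(np.median(posterior.root_heights)), clock)
    )
    return BlockTrajectory(block_id=block_id, N_j=point, sd_j=sd,
                           tmrca_years=tmrca_years)


def tmrca_filter(trajectories: list[BlockTrajectory],
                 min_age_years: float = 25_000.0) -> list[BlockTrajectory]:
    """Keep blocks whose posterior-median TMRCA is at least ``min_age_years``
    (boundary inclusive): genealogies too young to inform the grid's full
    span are excluded."""
    return [t for t in trajectories if t.tmrca_years >= min_age_years]
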