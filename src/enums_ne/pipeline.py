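"""End-to-end orchestration of the three-step strategy.

Step 1 partitions phased haplotypes into crossover-free blocks (four-
gamete test, minimum-length filter); step 2 runs an independent seeded
skyline MCMC per block; step 3 converts posteriors to year-grid
trajectories, applies the TMRCA filter, and aggregates with inverse-SD
weights.  Per-block seeds are a pure function of (master seed, block
index), so block-level parallelism cannot change results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregation import aggregate, aggregate_unweighted, compute_weights
from .block_finder import Block, filter_blocks, partition_blocks
from .io_formats import (
    HaplotypeMatrix,
    read_phased_vcf,
    write_blocks_bed,
    write_population_trajectory,
    write_trajectories_tsv,
)
from .skyline_mcmc import BlockAlignment, MCMCConfig, mcmc_run
from .trajectory import (
    BlockTrajectory,
    ClockScaling,
    TimeGrid,
    block_trajectory,
    tmrca_filter,
)

logger = logging.getLogger("enums")


@dataclass
class RunConfig:
    """One structured object holding every pipeline parameter.

    Defaults are the study settings: 5,000-bp minimum block length,
    mu = 2.5e-8 per site per generation, 25-year generations, a
    26-point grid from 0 to 25,000 YBP at 1,000-year steps, a 25,000-year
    minimum TMRCA, and inverse-SD weighting.
    """

    vcf: str | None = None
    region: str | None = None
    samples: list[str] | None = None
    min_length_bp: int = 5000
    mu: float = 2.5e-8
    gen_years: float = 25.0
    t_max: int = 25_000
    interval: int = 1_000
    min_tmrca_years: float = 25_000.0
    weight_scheme: str = "inverse-sd"       # or "equal"
    weight_power: int = 2
    point_estimate: str = "median"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    master_seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land must not change them
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def block_seed(master_seed: int, block_index: int) -> int:
    """Deterministic per-block chain seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(block_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """Counts at every filter stage plus provenance."""

    n_sites: int = 0
    n_blocks_raw: int = 0
    n_blocks_min_length: int = 0
    n_blocks_mcmc: int = 0
    n_blocks_tmrca: int = 0
    config_hash: str = ""
    master_seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    report: RunReport
    blocks: list[Block]
    trajectories: list[BlockTrajectory]
    retained: list[BlockTrajectory]
    population: "object"
    population_unweighted: "object"
    grid: TimeGrid


def run_enums(config: RunConfig,
              matrix: HaplotypeMatrix | None = None,
              precomputed_blocks: list[Block] | None = None) -> RunResult:
    """Run blocks -> skylines -> trajectories -> aggregation.

    ``matrix`` may be passed directly (e.g. from the simulator) instead of
    ``config.vcf``.  When an output directory is configured, BED, per-block
    trajectory TSV, population TSV/JSON and a JSON run report are written,
    each stamped with the config hash.
    """
    if matrix is None:
        if config.vcf is None:
            raise ValueError("either a matrix or config.vcf is required")
        matrix = read_phased_vcf(config.vcf, region=config.region,
                                 samples=config.samples)
    report = RunReport(config_hash=config.config_hash(),
                       master_seed=config.master_seed)
    report.n_sites = matrix.n_sites

    blocks = precomputed_blocks or partition_blocks(matrix)
    report.n_blocks_raw = len(blocks)
    blocks = filter_blocks(blocks, config.min_length_bp)
    report.n_blocks_min_length = len(blocks)
    if not blocks:
        raise RuntimeError(
            f"no blocks of at least {config.min_length_bp} bp survive "
            "the minimum-length filter"
        )
    logger.info("partitioned %d sites into %d blocks (%d >= %d bp)",
                report.n_sites, report.n_blocks_raw, len(blocks),
                config.min_length_bp)

    grid = TimeGrid(t_max=config.t_max, interval=config.interval)
    clock = ClockScaling(mu=config.mu, gen_years=config.gen_years)

    trajectories: list[BlockTrajectory] = []
    for idx, block in enumerate(blocks):
        aln = BlockAlignment.from_haplotype_matrix(matrix, block)
        cfg = dataclasses.replace(config.mcmc,
                                  seed=block_seed(config.master_seed, idx))
        posterior = mcmc_run(aln, cfg)
        tr = block_trajectory(posterior, grid, clock,
                              block_id=block.block_id or f"b{idx}",
                              point_estimate=config.point_estimate)
        trajectories.append(tr)
        logger.info("block %s: %d SNPs, %d bp, tmrca %.0f yr",
                    tr.block_id, block.n_sites, block.length_bp,
                    tr.tmrca_years)
    report.n_blocks_mcmc = len(trajectories)

    retained = tmrca_filter(trajectories, config.min_tmrca_years)
    report.n_blocks_tmrca = len(retained)
    if not retained:
        raise RuntimeError(
            f"no blocks survive the TMRCA >= {config.min_tmrca_years:.0f}-year "
            "filter"
        )

    if config.weight_scheme == "equal":
        population = aggregate_unweighted(retained)
    else:
        population = aggregate(retained, compute_weights(retained),
                               weight_power=config.weight_power)
    population_unweighted = aggregate_unweighted(retained)

    result = RunResult(report=report, blocks=blocks, trajectories=trajectories,
                       retained=retained, population=population,
                       population_unweighted=population_unweighted, grid=grid)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.report.config_hash
    write_blocks_bed(result.blocks, out / f"blocks_{h}.bed")
    write_trajectories_tsv(result.trajectories, result.grid,
                           out / f"block_trajectories_{h}.tsv")
    write_population_trajectory(result.population, result.grid,
                                out / f"population_ne_{h}.tsv")
    write_population_trajectory(result.population, result.grid,
                                out / f"population_ne_{h}.json")
    (out / f"run_report_{h}.json").write_text(
        json.dumps(result.report.as_dict(), indent=2) + "\n"
    )
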