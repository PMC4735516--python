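"""Reading and writing the pipeline's on-disk formats.

Phased VCF in, haplotype matrices in memory; FASTA block alignments, BED
block coordinates and TSV/JSON trajectory tables out.  Coordinates are
1-based inclusive internally (the VCF convention); conversion to BED's
0-based half-open intervals happens only at the file boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class EmptyInputError(ValueError):
    """No usable sites remained after filtering an input file."""


@dataclass
class LoadReport:
    """Bookkeeping for sites examined and dropped while loading a VCF."""

    n_records: int = 0
    n_retained: int = 0
    n_not_biallelic_snp: int = 0
    n_unphased: int = 0
    n_missing: int = 0
    n_outside_region: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix over ordered SNP positions.

    Rows are haplotypes (two per diploid sample), columns are biallelic SNP
    sites on a single chromosome.  ``alleles[h, s]`` is 0 for the REF allele
    and 1 for the ALT allele.
    """

    chromosome: str
    positions: np.ndarray          # 1-based bp, strictly increasing
    ref_alleles: np.ndarray        # dtype '<U1'
    alt_alleles: np.ndarray
    alleles: np.ndarray            # int8, shape (n_haplotypes, n_sites)
    haplotype_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)
    sample_populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype="<U1")
        self.alt_alleles = np.asarray(self.alt_alleles, dtype="<U1")
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("site dimension mismatch between alleles and positions")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0 or 1")
        if self.sample_ids and self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must be 2 x diploid sample count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def subset_haplotypes(self, row_indices: np.ndarray) -> "HaplotypeMatrix":
        """Row subset (sample bookkeeping is dropped; haplotype ids kept)."""
        row_indices = np.asarray(row_indices)
        return HaplotypeMatrix(
            chromosome=self.chromosome,
            positions=self.positions.copy(),
            ref_alleles=self.ref_alleles.copy(),
            alt_alleles=self.alt_alleles.copy(),
            alleles=self.alleles[row_indices].copy(),
            haplotype_ids=[self.haplotype_ids[i] for i in row_indices],
        )


def _parse_region(region: str | None) -> tuple[str | None, int, int]:
    if region is None:
        return None, 1, np.iinfo(np.int64).max
    if ":" not in region:
        return region, 1, np.iinfo(np.int64).max
    chrom, span = region.split(":", 1)
    start_s, end_s = span.replace(",", "").split("-")
    start, end = int(start_s), int(end_s)
    if start < 1 or end < start:
        raise ValueError(f"malformed region {region!r}")
    return chrom, start, end


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    samples: list[str] | None = None,
    return_report: bool = False,
):
    """Load a phased, biallelic-SNP haplotype matrix from a VCF.

    Only records that are biallelic SNPs with fully phased, non-missing GT
    for every selected sample are retained; everything else is dropped and
    counted in the :class:`LoadReport`.  ``region`` is ``chrom`` or
    ``chrom:start-end`` with 1-based inclusive coordinates.

    Raises :class:`EmptyInputError` when no site survives, and
    :class:`ValueError` when the retained sites span more than one
    chromosome (pass a region to disambiguate).
    """
    from cyvcf2 import VCF

    want_chrom, want_start, want_end = _parse_region(region)
    vcf = VCF(str(path), samples=samples, gts012=False)
    kept_samples = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(kept_samples)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")

    report = LoadReport()
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    chroms: set[str] = set()

    for rec in vcf:
        report.n_records += 1
        if want_chrom is not None and rec.CHROM != want_chrom:
            report.n_outside_region += 1
            continue
        if not (want_start <= rec.POS <= want_end):
            report.n_outside_region += 1
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            report.n_not_biallelic_snp += 1
            continue
        if rec.REF not in "ACGT" or rec.ALT[0] not in "ACGT":
            report.n_not_biallelic_snp += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(2 * len(kept_samples), dtype=np.int8)
        ok = True
        unphased = False
        for i, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], bool(g[-1])
            if a0 < 0 or a1 < 0:
                ok = False
                break
            if not phased:
                unphased = True
                ok = False
                break
            col[2 * i] = a0
            col[2 * i + 1] = a1
        if not ok:
            if unphased:
                report.n_unphased += 1
                warnings.warn(
                    f"dropping unphased site {rec.CHROM}:{rec.POS}", stacklevel=2
                )
            else:
                report.n_missing += 1
            continue
        report.n_retained += 1
        chroms.add(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        cols.append(col)

    if not positions:
        raise EmptyInputError(f"no phased biallelic SNPs retained from {path}")
    if len(chroms) > 1:
        raise ValueError(
            f"sites span chromosomes {sorted(chroms)}; pass region= to select one"
        )

    hap_ids = [f"{s}|{k}" for s in kept_samples for k in (0, 1)]
    matrix = HaplotypeMatrix(
        chromosome=chroms.pop(),
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=np.array(refs),
        alt_alleles=np.array(alts),
        alleles=np.column_stack(cols),
        haplotype_ids=hap_ids,
        sample_ids=kept_samples,
    )
    if return_report:
        return matrix, report
    return matrix


def vcf_chromosomes(path: str | Path) -> list[str]:
    """Distinct chromosome names in record order of appearance."""
    from cyvcf2 import VCF

    seen: dict[str, None] = {}
    for rec in VCF(str(path)):
        seen.setdefault(rec.CHROM, None)
    return list(seen)


def write_phased_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as minimal phased VCF 4.2 text.

    Consecutive haplotype rows are paired into diploid samples.
    """
    if matrix.n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes for diploid VCF output")
    n_samples = matrix.n_haplotypes // 2
    if matrix.sample_ids and len(matrix.sample_ids) == n_samples:
        names = matrix.sample_ids
    else:
        # consecutive haplotype rows pair into one sample: s0|0, s0|1 -> s0
        names = [matrix.haplotype_ids[2 * i].rsplit("|", 1)[0]
                 for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for s in range(matrix.n_sites):
            gts = "\t".join(
                f"{matrix.alleles[2 * i, s]}|{matrix.alleles[2 * i + 1, s]}"
                for i in range(n_samples)
            )
            fh.write(
                f"{matrix.chromosome}\t{matrix.positions[s]}\t.\t"
                f"{matrix.ref_alleles[s]}\t{matrix.alt_alleles[s]}\t.\tPASS\t.\tGT\t"
                + gts
                + "\n"
            )


def write_block_fasta(matrix: HaplotypeMatrix, block, path: str | Path) -> None:
    """One FASTA record per haplotype over the block's SNP columns.

    Character per site: the REF base where the allele is 0, the ALT base
    where it is 1, in position order.
    """
    sl = block.site_slice
    if sl.stop - sl.start <= 0:
        raise ValueError("empty block")
    refs = matrix.ref_alleles[sl]
    alts = matrix.alt_alleles[sl]
    records = []
    for h in range(matrix.n_haplotypes):
        a = matrix.alleles[h, sl]
        seq = "".join(np.where(a == 0, refs, alts))
        records.append(
            SeqRecord(Seq(seq), id=matrix.haplotype_ids[h], description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta_alignment(path: str | Path) -> tuple[list[str], list[str]]:
    """(ids, sequences) from a FASTA alignment; lengths must agree."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise EmptyInputError(f"no records in {path}")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("FASTA records have unequal lengths; not an alignment")
    return ids, seqs


def write_blocks_bed(blocks, path: str | Path) -> None:
    """BED4 (0-based half-open): 1-based inclusive [start,end] -> start-1, end."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start_pos - 1}\t{b.end_pos}\t{b.block_id}\n")


def read_blocks_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Inverse of :func:`write_blocks_bed`; intervals back in 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            out.append((chrom, start0 + 1, end, name))
    return out


def read_population_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population label file needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_trajectories_tsv(trajectories, grid, path: str | Path) -> None:
    """One row per block: id, tmrca, Ne per grid time, SD per grid time."""
    rows = []
    for tr in trajectories:
        row = {"block_id": tr.block_id, "tmrca_years": tr.tmrca_years}
        for t, n in zip(grid.times, tr.N_j):
            row[f"ne_{int(t)}"] = n
        for t, s in zip(grid.times, tr.sd_j):
            row[f"sd_{int(t)}"] = s
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trajectories_tsv(path: str | Path):
    """Inverse of :func:`write_trajectories_tsv` -> (trajectories, grid)."""
    from .trajectory import BlockTrajectory, TimeGrid

    df = pd.read_csv(path, sep="\t")
    ne_cols = [c for c in df.columns if c.startswith("ne_")]
    times = sorted(int(c[3:]) for c in ne_cols)
    if len(times) < 2:
        raise ValueError("trajectory table needs at least two grid times")
    interval = times[1] - times[0]
    grid = TimeGrid(t_max=times[-1], interval=interval)
    out = []
    for _, row in df.iterrows():
        out.append(
            BlockTrajectory(
                block_id=str(row["block_id"]),
                N_j=np.array([row[f"ne_{t}"] for t in times], dtype=float),
                sd_j=np.array([row[f"sd_{t}"] for t in times], dtype=float),
                tmrca_years=float(row["tmrca_years"]),
            )
        )
    return out, grid


def write_population_trajectory(pop_traj, grid, path: str | Path) -> None:
    """Aggregated Ne(t) as TSV (``.tsv``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".tsv":
        pd.DataFrame(
            {"time_ybp": grid.times, "ne": pop_traj.x_hat}
        ).to_csv(path, sep="\t", index=False)
    else:
        payload = {
            "times_ybp": [int(t) for t in grid.times],
            "ne": [float(v) for v in pop_traj.x_hat],
            "n_blocks": pop_traj.M,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
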