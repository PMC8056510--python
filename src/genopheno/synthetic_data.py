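"""Seeded synthetic case-control genotype cohorts with planted associations.

The generator emulates a crowd-sourced direct-to-consumer cohort: two
phenotype groups, raw genotype files in the 23andme or AncestryDNA dialect,
a plain-text reference VCF, a phenotype table, and a planted ground truth.
Genotypes are drawn directly from per-SNP mutation-type probability vectors
(p_no, p_partial, p_full) — the quantity the selection statistics operate
on — and rendered against each SNP's REF/ALT alleles: no mutation → ref/ref,
partial → ref/alt, full → alt/alt. Informative SNPs get different vectors
per group; background SNPs share one vector drawn from a Dirichlet prior.
Per-record missingness (the record is absent from the file) and no-calls
('--', or 0/0 alleles in the AncestryDNA dialect) are injected at
configurable rates. All randomness derives from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import FORMAT_23ANDME, FORMAT_ANCESTRYDNA
from .mutation_coding import MutationMatrix

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort shape and signal structure.

    ``n_per_class`` defaults to the 404/402 case-control shape of the kind
    of crowd-sourced cohort this emulates. Informative SNPs carry the
    group-specific probability vectors in ``informative_profiles`` (a single
    pair is recycled across all planted SNPs); background SNPs draw one
    shared vector from Dirichlet(``background_alpha``) — balanced by default
    so that no mutation type dominates both groups, which would trip the
    linear threshold regardless of group difference.
    """

    n_per_class: tuple[int, int] = (404, 402)
    n_snps: int = 1000
    n_informative: int = 20
    informative_profiles: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.10, 0.10, 0.80),  # group A: (p_no, p_partial, p_full)
        (0.60, 0.30, 0.10),  # group B
    )
    background_alpha: tuple[float, float, float] = (200.0, 200.0, 200.0)
    missing_rate: float = 0.05
    nocall_rate: float = 0.02
    output_format: str = FORMAT_23ANDME
    seed: int = 0

    def __post_init__(self) -> None:
        for vec in self.informative_profiles:
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"probability vector {vec} must be non-negative and sum to 1")
        if self.n_informative > self.n_snps:
            raise ValueError("n_informative must not exceed n_snps")
        if self.output_format not in (FORMAT_23ANDME, FORMAT_ANCESTRYDNA):
            raise ValueError(f"unknown output format {self.output_format!r}")
        for rate in (self.missing_rate, self.nocall_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")


@dataclass
class PlantedTruth:
    """Which SNPs carry signal, and the probability vectors they were drawn from."""

    informative_snp_ids: set[str]
    profiles: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "informative_snp_ids": sorted(self.informative_snp_ids),
                    "profiles": {k: list(map(list, v)) for k, v in self.profiles.items()},
                },
                indent=2,
            )
        )


@dataclass
class SimulatedCohort:
    """File paths plus the in-memory truth of one simulated cohort."""

    genotype_paths: list[Path]
    vcf_path: Path
    phenotype_path: Path
    truth_path: Path
    truth: PlantedTruth
    matrix: MutationMatrix  # drawn codes with NaN at missing/no-call cells


def _draw_codes(
    rng: np.random.Generator, probs: np.ndarray, n_samples: int
) -> np.ndarray:
    """Vectorized multinomial draw: probs is (n_snps, 3) -> (n_samples, n_snps)."""
    u = rng.random((n_samples, probs.shape[0]))
    c0 = probs[:, 0]
    c1 = probs[:, 0] + probs[:, 1]
    return (u > c0).astype(np.int8) + (u > c1).astype(np.int8)


def _snp_metadata(rng: np.random.Generator, n_snps: int):
    rsids = np.array([f"rs{i + 1}" for i in range(n_snps)])
    chroms = np.array([str(i % 22 + 1) for i in range(n_snps)])
    positions = 10_000 + (np.arange(n_snps) // 22) * 100
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_shift = rng.integers(1, 4, size=n_snps)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]
    return rsids, chroms, positions, refs, alts


def _simulate_arrays(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_per_class
    rsids, chroms, positions, refs, alts = _snp_metadata(rng, config.n_snps)

    background = rng.dirichlet(config.background_alpha, size=config.n_snps)
    informative_idx = np.sort(
        rng.choice(config.n_snps, size=config.n_informative, replace=False)
    )
    probs_a = background.copy()
    probs_b = background.copy()
    vec_a, vec_b = config.informative_profiles
    probs_a[informative_idx] = vec_a
    probs_b[informative_idx] = vec_b

    codes_a = _draw_codes(rng, probs_a, n_a)
    codes_b = _draw_codes(rng, probs_b, n_b)
    codes = np.vstack([codes_a, codes_b]).astype(float)

    n_total = n_a + n_b
    missing_mask = rng.random((n_total, config.n_snps)) < config.missing_rate
    nocall_mask = (~missing_mask) & (
        rng.random((n_total, config.n_snps)) < config.nocall_rate
    )

    sample_ids = [f"case_{i + 1:04d}" for i in range(n_a)] + [
        f"control_{i + 1:04d}" for i in range(n_b)
    ]
    labels = pd.Series(
        ["case"] * n_a + ["control"] * n_b, index=sample_ids, name="phenotype"
    )
    truth = PlantedTruth(
        informative_snp_ids={str(rsids[i]) for i in informative_idx},
        profiles={str(rsids[i]): (vec_a, vec_b) for i in informative_idx},
    )
    return (
        rsids, chroms, positions, refs, alts,
        codes, missing_mask, nocall_mask, sample_ids, labels, truth,
    )


def simulate_matrix(config: SimulationConfig) -> tuple[MutationMatrix, PlantedTruth]:
    """In-memory fast path: the labelled mutation matrix the pipeline would
    reconstruct from the files (missing and no-call cells are NaN)."""
    (rsids, _, _, _, _, codes, missing_mask, nocall_mask, sample_ids, labels, truth
     ) = _simulate_arrays(config)
    observed = codes.copy()
    observed[missing_mask | nocall_mask] = np.nan
    frame = pd.DataFrame(observed, index=sample_ids, columns=[str(r) for r in rsids])
    return MutationMatrix(frame, labels), truth


def _write_vcf(path: Path, rsids, chroms, positions, refs, alts) -> None:
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genopheno-simulate\n")
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = np.lexsort((positions, np.char.zfill(np.asarray(chroms, dtype=str), 2)))
        for i in order:
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t{rsids[i]}\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\n"
            )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Write a full cohort: raw genotype files, reference VCF, phenotype table
    and planted-truth JSON. Identical seeds produce byte-identical files."""
    out_dir = Path(out_dir)
    genotype_dir = out_dir / "genotypes"
    genotype_dir.mkdir(parents=True, exist_ok=True)
    (rsids, chroms, positions, refs, alts, codes, missing_mask, nocall_mask,
     sample_ids, labels, truth) = _simulate_arrays(config)

    vcf_path = out_dir / "reference.vcf"
    _write_vcf(vcf_path, rsids, chroms, positions, refs, alts)

    phenotype_path = out_dir / "phenotypes.csv"
    labels.rename_axis("sample_id").to_csv(phenotype_path)

    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    # genotype strings per code: 0 -> ref/ref, 1 -> ref/alt, 2 -> alt/alt
    allele1 = np.where(codes >= 1, alts[None, :], refs[None, :])
    allele1 = np.where(codes == 1, refs[None, :], allele1)
    allele2 = np.where(codes >= 1, alts[None, :], refs[None, :])

    ext = "txt" if config.output_format == FORMAT_23ANDME else "tsv"
    genotype_paths: list[Path] = []
    for s, sample in enumerate(sample_ids):
        path = genotype_dir / f"{sample}.{ext}"
        genotype_paths.append(path)
        keep = ~missing_mask[s]
        with path.open("w") as fh:
            if config.output_format == FORMAT_23ANDME:
                fh.write("# rsid\tchromosome\tposition\tgenotype\n")
                for j in np.flatnonzero(keep):
                    g = "--" if nocall_mask[s, j] else allele1[s, j] + allele2[s, j]
                    fh.write(f"{rsids[j]}\t{chroms[j]}\t{positions[j]}\t{g}\n")
            else:
                fh.write("# rsid\tchromosome\tposition\tallele1\tallele2\n")
                for j in np.flatnonzero(keep):
                    a1, a2 = (
                        ("0", "0")
                        if nocall_mask[s, j]
                        else (allele1[s, j], allele2[s, j])
                    )
                    fh.write(f"{rsids[j]}\t{chroms[j]}\t{positions[j]}\t{a1}\t{a2}\n")

    observed = codes.copy()
    observed[missing_mask | nocall_mask] = np.nan
    frame = pd.DataFrame(observed, index=sample_ids, columns=[str(r) for r in rsids])
    return SimulatedCohort(
        genotype_paths=genotype_paths,
        vcf_path=vcf_path,
        phenotype_path=phenotype_path,
        truth_path=truth_path,
        truth=truth,
        matrix=MutationMatrix(frame, labels),
    )
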