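"""Additive mutation coding of genotypes against the reference allele.

Each person × SNP genotype becomes 0 (no mutation: every observed allele
equals the reference), 1 (partial: one of two alleles differs) or 2 (full:
every observed allele differs). Haploid calls (X/Y/MT single characters)
therefore code to {0, 2}. The code depends on the reference allele only;
an allele matching neither REF nor ALT still counts as mutated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import VALID_BASES, GenotypeProfile, ReferencePanel

#: sentinel for a missing code in the numeric matrix
MISSING = np.nan


@lru_cache(maxsize=4096)
def code_genotype(genotype: Optional[str], ref_allele: str) -> Optional[int]:
    """Code one genotype call against the reference allele.

    Parameters
    ----------
    genotype
        1–2 character allele string, or ``None`` for a no-call.
    ref_allele
        Single character in {A, C, G, T}.

    Returns
    -------
    0, 1 or 2 for diploid calls (count of alleles differing from the
    reference); 0 or 2 for haploid calls; ``None`` when the genotype is
    missing or contains characters outside {A, C, G, T}.
    """
    if ref_allele not in VALID_BASES:
        raise ValueError(f"ref_allele must be one of A/C/G/T, got {ref_allele!r}")
    if genotype is None:
        return None
    g = genotype.upper()
    if not (1 <= len(g) <= 2) or not set(g) <= VALID_BASES:
        return None
    if len(g) == 1:
        return 0 if g == ref_allele else 2
    return sum(1 for allele in g if allele != ref_allele)


@dataclass
class MutationMatrix:
    """Persons × SNPs table of mutation codes.

    ``codes`` is a float DataFrame (rows = sample ids, columns = rsids) with
    values in {0, 1, 2} and NaN for missing; ``labels`` optionally maps each
    sample to its phenotype label.
    """

    codes: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        values = self.codes.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("mutation codes must be 0, 1, 2 or missing")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def with_labels(self, labels: pd.Series | dict) -> "MutationMatrix":
        labels = pd.Series(labels)
        return MutationMatrix(self.codes, labels)

    def to_csv(self, path: str | Path) -> None:
        """Serialize as CSV: first column sample_id, header row of rsids."""
        out = self.codes.copy()
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path, labels: Optional[pd.Series] = None) -> "MutationMatrix":
        codes = pd.read_csv(path, index_col="sample_id", na_values=["NA"])
        return cls(codes.astype(float), labels)


def build_mutation_matrix(
    profiles: Sequence[GenotypeProfile], panel: ReferencePanel
) -> MutationMatrix:
    """Code every profile against every panel SNP.

    One row per profile, one column per panel entry; a SNP absent from a
    profile's file yields a missing cell. The panel should already be cleaned
    (complete, deduplicated entries).
    """
    if not len(panel.entries):
        raise ValueError("reference panel is empty")
    if not profiles:
        raise ValueError("no genotype profiles given")
    rsids = [e.rsid for e in panel.entries]
    refs = [e.ref_allele for e in panel.entries]
    rows = np.full((len(profiles), len(rsids)), np.nan)
    for i, profile in enumerate(profiles):
        records = profile.records
        for j, (rsid, ref) in enumerate(zip(rsids, refs)):
            rec = records.get(rsid)
            if rec is None:
                continue
            code = code_genotype(rec.genotype, ref)
            if code is not None:
                rows[i, j] = code
    codes = pd.DataFrame(
        rows, index=[p.sample_id for p in profiles], columns=rsids
    )
    return MutationMatrix(codes)
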