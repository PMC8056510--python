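"""Reference-panel and matrix-level quality control.

Two cleaning steps run before SNP pre-selection: reference entries with a
missing REF or ALT allele are dropped outright (no imputation), duplicate
rsids keep their first occurrence, and SNP columns with too many missing
per-person observations are removed from the mutation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genotype_io import ReferencePanel
from .mutation_coding import MutationMatrix


@dataclass(frozen=True)
class QcConfig:
    """Per-SNP missingness bound: a SNP is dropped when the fraction of
    samples with a missing code is strictly greater than this."""

    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class QcReport:
    n_input_snps: int = 0
    n_removed_incomplete: int = 0
    n_removed_duplicate: int = 0
    n_removed_missingness: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_snps
            - self.n_removed_incomplete
            - self.n_removed_duplicate
            - self.n_removed_missingness
        )

    def as_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_incomplete": self.n_removed_incomplete,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_removed_missingness": self.n_removed_missingness,
            "n_retained": self.n_retained,
        }


def clean_reference(panel: ReferencePanel) -> tuple[ReferencePanel, QcReport]:
    """Drop incomplete and duplicate reference SNPs (first occurrence wins).

    Idempotent; retained entries keep their relative order.
    """
    report = QcReport(n_input_snps=len(panel.entries))
    seen: set[str] = set()
    kept = []
    for entry in panel.entries:
        if not entry.complete:
            report.n_removed_incomplete += 1
            continue
        if entry.rsid in seen:
            report.n_removed_duplicate += 1
            continue
        seen.add(entry.rsid)
        kept.append(entry)
    return ReferencePanel(kept, list(panel.warnings)), report


def filter_by_missingness(
    matrix: MutationMatrix, config: QcConfig | None = None
) -> tuple[MutationMatrix, QcReport]:
    """Drop SNP columns whose missing fraction exceeds the configured bound.

    The comparison is strict ``>`` so a SNP at exactly the threshold is
    retained. Sample rows are untouched and column order is preserved.
    """
    config = config or QcConfig()
    report = QcReport(n_input_snps=matrix.n_snps)
    missing_frac = matrix.codes.isna().mean(axis=0)
    keep = missing_frac <= config.max_missing_fraction
    report.n_removed_missingness = int((~keep).sum())
    filtered = MutationMatrix(matrix.codes.loc[:, keep], matrix.labels)
    return filtered, report
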