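"""SNP pre-selection by mutation-percentage differences under a linear threshold.

For each SNP the fraction of people in each phenotype group showing no (PNM),
partial (PPM) and full (PFM) mutation is computed over the non-missing
observations. A SNP can then be screened two ways:

1. an optional prefilter on the absolute between-group percentage difference
   (discard when every type's |difference| is at or below a fixed cutoff), and
2. the linear threshold, applied once per mutation type with that type's
   between-group max/min percentages::

       threshold       = slope * max_pct + intercept
       lower_threshold = (1 - threshold / 100) * max_pct
       selected        = min_pct <= lower_threshold

With the intercept at its default of 100, ``lower_threshold`` reduces to
``(-slope / 100) * max_pct**2``: slope 0 selects (essentially) nothing and
increasingly negative slopes select more SNPs, so the selected sets nest as
the slope decreases. A SNP enters the panel when any tested mutation type
satisfies the predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json

import numpy as np
import pandas as pd

from .mutation_coding import MutationMatrix

MUTATION_TYPES = ("no", "partial", "full")
_CODE_OF_TYPE = {"no": 0.0, "partial": 1.0, "full": 2.0}


@dataclass(frozen=True)
class GroupMutationProfile:
    """Per-SNP mutation-type percentages within one phenotype group."""

    snp_id: str
    group: str
    pnm: float
    ppm: float
    pfm: float
    n_observed: int

    def pct(self, mutation_type: str) -> float:
        return {"no": self.pnm, "partial": self.ppm, "full": self.pfm}[mutation_type]


@dataclass(frozen=True)
class MutationDifference:
    snp_id: str
    abs_no_diff: float
    abs_partial_diff: float
    abs_full_diff: float

    def get(self, mutation_type: str) -> float:
        return {
            "no": self.abs_no_diff,
            "partial": self.abs_partial_diff,
            "full": self.abs_full_diff,
        }[mutation_type]

    @property
    def max_diff(self) -> float:
        return max(self.abs_no_diff, self.abs_partial_diff, self.abs_full_diff)


@dataclass(frozen=True)
class MutationExtrema:
    snp_id: str
    max_no: float
    min_no: float
    max_partial: float
    min_partial: float
    max_full: float
    min_full: float

    def pair(self, mutation_type: str) -> tuple[float, float]:
        return {
            "no": (self.max_no, self.min_no),
            "partial": (self.max_partial, self.min_partial),
            "full": (self.max_full, self.min_full),
        }[mutation_type]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the pre-selection rule.

    slope
        Dimensionless controlling factor, typically negative; more negative
        slopes admit more SNPs.
    intercept
        Percent-scale offset of the linear threshold (default 100, keeping
        the threshold on the percent scale).
    abs_diff_threshold
        Prefilter cutoff in percentage points; a SNP is discarded when every
        mutation type's absolute between-group difference is <= this value.
        0 disables the prefilter.
    mutation_types
        Which of {no, partial, full} the linear threshold is applied to.
    invert_threshold
        Flip the selection predicate (min_pct > lower_threshold) for
        sensitivity analysis.
    """

    slope: float = -1.5
    intercept: float = 100.0
    abs_diff_threshold: float = 0.0
    mutation_types: tuple[str, ...] = MUTATION_TYPES
    invert_threshold: bool = False

    def __post_init__(self) -> None:
        if self.abs_diff_threshold < 0:
            raise ValueError("abs_diff_threshold must be >= 0")
        unknown = set(self.mutation_types) - set(MUTATION_TYPES)
        if unknown:
            raise ValueError(f"unknown mutation types: {sorted(unknown)}")


@dataclass
class SnpAudit:
    """Everything the selection rule computed for one SNP."""

    snp_id: str
    difference: MutationDifference
    extrema: MutationExtrema
    thresholds: dict[str, float]
    lower_thresholds: dict[str, float]
    selected_by: list[str]

    def as_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "abs_diff": {
                t: self.difference.get(t) for t in MUTATION_TYPES
            },
            "extrema": {
                t: self.extrema.pair(t) for t in MUTATION_TYPES
            },
            "threshold": self.thresholds,
            "lower_threshold": self.lower_thresholds,
            "selected_by": self.selected_by,
        }


@dataclass
class SnpPanel:
    """Selected rsids (descending max |difference|, ties by rsid) + audit."""

    snp_ids: list[str]
    audits: dict[str, SnpAudit]
    config: SelectionConfig

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "snp_ids": self.snp_ids,
            "config": {
                "slope": self.config.slope,
                "intercept": self.config.intercept,
                "abs_diff_threshold": self.config.abs_diff_threshold,
                "mutation_types": list(self.config.mutation_types),
                "invert_threshold": self.config.invert_threshold,
            },
            "audit": {s: self.audits[s].as_dict() for s in self.snp_ids},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def load_snp_ids(path: str | Path) -> list[str]:
        return json.loads(Path(path).read_text())["snp_ids"]


def _percentage_table(matrix: MutationMatrix) -> tuple[list, dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-group percentage DataFrames (rows = groups, one frame per type).

    Returns (group labels, {type: group × SNP percentages}, group × SNP
    observation counts). Percentages are over non-missing codes; a group with
    zero observations at a SNP gets (0, 0, 0).
    """
    if matrix.labels is None:
        raise ValueError("matrix has no phenotype labels")
    labels = matrix.labels
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two phenotype labels required, got {groups}")
    counts: dict[str, pd.DataFrame] = {}
    values = matrix.codes
    n_obs = pd.DataFrame(index=groups, columns=values.columns, dtype=float)
    pct = {t: pd.DataFrame(index=groups, columns=values.columns, dtype=float) for t in MUTATION_TYPES}
    for g in groups:
        sub = values.loc[labels[labels == g].index]
        observed = sub.notna().sum(axis=0).astype(float)
        n_obs.loc[g] = observed
        denom = observed.replace(0.0, np.nan)
        for t in MUTATION_TYPES:
            frac = (sub == _CODE_OF_TYPE[t]).sum(axis=0) / denom
            pct[t].loc[g] = (100.0 * frac).fillna(0.0)
    return groups, pct, n_obs


def group_percentages(
    matrix: MutationMatrix,
) -> dict[str, tuple[GroupMutationProfile, GroupMutationProfile]]:
    """PNM/PPM/PFM per SNP for both phenotype groups.

    Requires a matrix with exactly two label values. A SNP with zero
    non-missing observations in a group yields (0, 0, 0) for that group.
    """
    groups, pct, n_obs = _percentage_table(matrix)
    out: dict[str, tuple[GroupMutationProfile, GroupMutationProfile]] = {}
    for snp in matrix.snp_ids:
        pair = tuple(
            GroupMutationProfile(
                snp_id=snp,
                group=str(g),
                pnm=float(pct["no"].loc[g, snp]),
                ppm=float(pct["partial"].loc[g, snp]),
                pfm=float(pct["full"].loc[g, snp]),
                n_observed=int(n_obs.loc[g, snp]),
            )
            for g in groups
        )
        out[snp] = pair  # type: ignore[assignment]
    return out


def mutation_differences(
    profile_a: GroupMutationProfile, profile_b: GroupMutationProfile
) -> MutationDifference:
    """Absolute between-group percentage difference per mutation type."""
    if profile_a.snp_id != profile_b.snp_id:
        raise ValueError("profiles refer to different SNPs")
    return MutationDifference(
        snp_id=profile_a.snp_id,
        abs_no_diff=abs(profile_a.pnm - profile_b.pnm),
        abs_partial_diff=abs(profile_a.ppm - profile_b.ppm),
        abs_full_diff=abs(profile_a.pfm - profile_b.pfm),
    )


def mutation_extrema(
    profile_a: GroupMutationProfile, profile_b: GroupMutationProfile
) -> MutationExtrema:
    """Componentwise max/min of the two groups' percentages per type."""
    if profile_a.snp_id != profile_b.snp_id:
        raise ValueError("profiles refer to different SNPs")
    return MutationExtrema(
        snp_id=profile_a.snp_id,
        max_no=max(profile_a.pnm, profile_b.pnm),
        min_no=min(profile_a.pnm, profile_b.pnm),
        max_partial=max(profile_a.ppm, profile_b.ppm),
        min_partial=min(profile_a.ppm, profile_b.ppm),
        max_full=max(profile_a.pfm, profile_b.pfm),
        min_full=min(profile_a.pfm, profile_b.pfm),
    )


def apply_linear_threshold(
    max_pct: float, min_pct: float, config: SelectionConfig
) -> tuple[float, float, bool]:
    """Evaluate the linear-threshold predicate for one mutation type.

    Returns (threshold, lower_threshold, selected).
    """
    threshold = config.slope * max_pct + config.intercept
    lower_threshold = (1.0 - threshold / 100.0) * max_pct
    selected = min_pct <= lower_threshold
    if config.invert_threshold:
        selected = not selected
    return threshold, lower_threshold, selected


def select_snps(matrix: MutationMatrix, config: SelectionConfig) -> SnpPanel:
    """Run the full pre-selection pipeline over a labelled mutation matrix.

    Per SNP: group percentages → prefilter on absolute differences →
    linear threshold per configured mutation type (any type selecting admits
    the SNP). SNPs with zero observations in either group are excluded.
    The panel is ordered by descending max absolute difference, ties broken
    by rsid.
    """
    groups, pct, n_obs = _percentage_table(matrix)
    g_a, g_b = groups
    snps = np.asarray(matrix.snp_ids)

    diffs = {t: (pct[t].loc[g_a] - pct[t].loc[g_b]).abs().to_numpy(dtype=float) for t in MUTATION_TYPES}
    maxima = {t: np.maximum(pct[t].loc[g_a].to_numpy(float), pct[t].loc[g_b].to_numpy(float)) for t in MUTATION_TYPES}
    minima = {t: np.minimum(pct[t].loc[g_a].to_numpy(float), pct[t].loc[g_b].to_numpy(float)) for t in MUTATION_TYPES}

    observed_both = (n_obs.loc[g_a].to_numpy(float) > 0) & (n_obs.loc[g_b].to_numpy(float) > 0)
    max_diff = np.maximum.reduce([diffs[t] for t in MUTATION_TYPES])
    passes_prefilter = (
        max_diff > config.abs_diff_threshold
        if config.abs_diff_threshold > 0
        else np.ones(len(snps), dtype=bool)
    )

    thresholds: dict[str, np.ndarray] = {}
    lowers: dict[str, np.ndarray] = {}
    selected_any = np.zeros(len(snps), dtype=bool)
    selected_by_type: dict[str, np.ndarray] = {}
    for t in config.mutation_types:
        thr = config.slope * maxima[t] + config.intercept
        low = (1.0 - thr / 100.0) * maxima[t]
        sel = minima[t] <= low
        if config.invert_threshold:
            sel = ~sel
        thresholds[t] = thr
        lowers[t] = low
        selected_by_type[t] = sel
        selected_any |= sel

    chosen = observed_both & passes_prefilter & selected_any
    order = np.lexsort((snps, -max_diff))
    ordered_idx = [i for i in order if chosen[i]]

    audits: dict[str, SnpAudit] = {}
    snp_ids: list[str] = []
    for i in ordered_idx:
        snp = str(snps[i])
        snp_ids.append(snp)
        diff = MutationDifference(snp, diffs["no"][i], diffs["partial"][i], diffs["full"][i])
        ext = MutationExtrema(
            snp,
            maxima["no"][i], minima["no"][i],
            maxima["partial"][i], minima["partial"][i],
            maxima["full"][i], minima["full"][i],
        )
        audits[snp] = SnpAudit(
            snp_id=snp,
            difference=diff,
            extrema=ext,
            thresholds={t: float(thresholds[t][i]) for t in config.mutation_types},
            lower_thresholds={t: float(lowers[t][i]) for t in config.mutation_types},
            selected_by=[t for t in config.mutation_types if selected_by_type[t][i]],
        )
    return SnpPanel(snp_ids, audits, config)
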