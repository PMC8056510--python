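"""Feature-matrix assembly, stratified splitting and scaling.

The mutation matrix restricted to the selected panel becomes the numeric
feature matrix (missing cells filled, by default with 0). The train/test
split randomly permutes samples under a seed and allocates the train budget
to the two classes by largest-remainder rounding so the class ratio is
preserved within one sample per class. Scaling statistics are always fitted
on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .mutation_coding import MutationMatrix
from .snp_preselection import SnpPanel

SCALING_METHODS = ("none", "minmax", "standard")


@dataclass
class FeatureDataset:
    """Numeric sample × selected-SNP matrix with aligned binary labels."""

    features: np.ndarray
    labels: np.ndarray
    snp_order: list[str]
    sample_ids: list[str]
    scaling: str = "none"
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.shape[1] != len(self.snp_order):
            raise ValueError("feature width does not match snp_order")
        if self.features.shape[0] != len(self.labels):
            raise ValueError("labels length does not match feature rows")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.features[idx],
            self.labels[idx],
            list(self.snp_order),
            [self.sample_ids[i] for i in idx],
            self.scaling,
            self.n_imputed,
        )


@dataclass
class SplitDataset:
    train: FeatureDataset
    test: FeatureDataset
    seed: int
    train_size: int


def default_train_size(n_samples: int) -> int:
    """Train budget proportional to a 540-of-806 hold-out design."""
    return int(round(n_samples * 540 / 806))


def build_feature_dataset(
    matrix: MutationMatrix,
    panel: SnpPanel | Sequence[str],
    labels: Optional[pd.Series] = None,
    fill_value: float = 0.0,
) -> FeatureDataset:
    """Restrict the matrix to the panel's SNPs, in panel order.

    Missing codes are replaced by ``fill_value`` (default 0) and the number
    of imputed cells is recorded on the dataset.
    """
    snp_order = list(panel.snp_ids) if isinstance(panel, SnpPanel) else list(panel)
    missing_cols = [s for s in snp_order if s not in matrix.codes.columns]
    if missing_cols:
        raise KeyError(f"panel SNPs absent from matrix: {missing_cols[:5]}")
    labels = labels if labels is not None else matrix.labels
    if labels is None:
        raise ValueError("no labels available")
    sub = matrix.codes.loc[:, snp_order]
    n_imputed = int(sub.isna().to_numpy().sum())
    features = sub.fillna(fill_value).to_numpy(dtype=float)
    aligned = pd.Series(labels).reindex(sub.index)
    classes = sorted(aligned.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    y = aligned.map({classes[0]: 0, classes[1]: 1}).to_numpy()
    return FeatureDataset(
        features, y.astype(int), snp_order, list(sub.index), "none", n_imputed
    )


def stratified_split(
    dataset: FeatureDataset, train_size: Optional[int] = None, seed: int = 0
) -> SplitDataset:
    """Seeded permutation split preserving the class ratio within ±1 sample.

    The per-class training allocation is ``train_size`` shared between the
    classes by largest-remainder rounding of ``n_class * train_size / n``.
    """
    n = dataset.n_samples
    if train_size is None:
        train_size = default_train_size(n)
    if not 0 < train_size < n:
        raise ValueError(f"train_size must be in (0, {n}), got {train_size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    y = dataset.labels[perm]

    classes, counts = np.unique(dataset.labels, return_counts=True)
    exact = counts * train_size / n
    base = np.floor(exact).astype(int)
    remainder = train_size - base.sum()
    # largest remainders get the leftover slots (ties by class order)
    order = np.argsort(-(exact - base), kind="stable")
    alloc = base.copy()
    alloc[order[:remainder]] += 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    taken = {c: 0 for c in classes}
    quota = dict(zip(classes, alloc))
    for pos in perm:
        c = dataset.labels[pos]
        if taken[c] < quota[c]:
            taken[c] += 1
            train_idx.append(pos)
        else:
            test_idx.append(pos)
    return SplitDataset(
        dataset.subset(np.array(train_idx)),
        dataset.subset(np.array(test_idx)),
        seed,
        train_size,
    )


def _fit_scaler(train: np.ndarray, method: str):
    if method == "minmax":
        return MinMaxScaler().fit(train)
    if method == "standard":
        return StandardScaler().fit(train)
    raise ValueError(f"unknown scaling method {method!r}")


def scale_features(
    data: FeatureDataset | SplitDataset, method: str = "minmax"
) -> FeatureDataset | SplitDataset:
    """Scale features to [0,1] (minmax) or zero mean/unit variance (standard).

    For a :class:`SplitDataset` the scaler is fitted on the training split
    only and applied to both splits; constant columns map to 0. ``none`` is
    the identity.
    """
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    if method == "none":
        return data
    if isinstance(data, SplitDataset):
        scaler = _fit_scaler(data.train.features, method)
        train = replace(
            data.train, features=scaler.transform(data.train.features), scaling=method
        )
        test = replace(
            data.test, features=scaler.transform(data.test.features), scaling=method
        )
        return SplitDataset(train, test, data.seed, data.train_size)
    if data.scaling != "none":
        raise ValueError("dataset already scaled")
    scaler = _fit_scaler(data.features, method)
    return replace(data, features=scaler.transform(data.features), scaling=method)
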