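import numpy as np
import pandas as pd
import pytest

from genopheno import (
    MutationMatrix,
    SelectionConfig,
    SimulationConfig,
    simulate_matrix,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-effect cohort used by the model-level tests: 100+100 samples,
    300 SNPs of which 20 are planted with an ~70-point PFM gap."""
    config = SimulationConfig(
        n_per_class=(100, 100), n_snps=300, n_informative=20,
        missing_rate=0.05, seed=7,
    )
    return simulate_matrix(config)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    from genopheno import build_feature_dataset, scale_features, select_snps, stratified_split

    matrix, _ = small_cohort
    panel = select_snps(matrix, SelectionConfig(slope=-1.5, abs_diff_threshold=25.0))
    dataset = build_feature_dataset(matrix, panel)
    split = stratified_split(dataset, seed=1)
    return scale_features(split, "minmax")


def random_matrix(rng: np.random.Generator, n_samples: int, n_snps: int,
                  missing_rate: float = 0.1) -> MutationMatrix:
    """Small random labelled matrix for oracle-equivalence tests."""
    codes = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    codes[rng.random((n_samples, n_snps)) < missing_rate] = np.nan
    frame = pd.DataFrame(
        codes,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"rs{j}" for j in range(n_snps)],
    )
    labels = pd.Series(
        rng.permutation(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)),
        index=frame.index,
    )
    return MutationMatrix(frame, labels)
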