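import numpy as np
import pandas as pd
import pytest

import dnamproxy as dp


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with all effect types present, shared across tests."""
    cfg = dp.SimulationConfig(
        n_samples=150,
        n_probes=400,
        n_causal=12,
        n_smoking_probes=10,
        n_celltype_probes=80,
        n_batches=5,
        detection_fail_rate=0.05,
        seed=42,
    )
    return dp.simulate_cohort(cfg)


@pytest.fixture()
def tiny_beta():
    """A 3-probe × 2-sample matrix with detection p-values."""
    values = pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.9, 0.95]],
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2"],
    )
    dp_vals = pd.DataFrame(
        np.zeros((3, 2)), index=values.index, columns=values.columns
    )
    return dp.BetaMatrix(values=values, detection_p=dp_vals)


def make_orthonormal_design(n, p, seed=0):
    """Design with columns orthogonal to each other and to the intercept,
    scaled so XᵀX = n·I (mean 0, population SD 1)."""
    rng = np.random.default_rng(seed)
    A = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(A)
    X = Q[:, 1:] * np.sqrt(n)
    return X


@pytest.fixture(scope="session")
def orthonormal_design():
    return make_orthonormal_design
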