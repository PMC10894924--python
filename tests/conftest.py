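import warnings

import numpy as np
import pandas as pd
import pytest

from stimnet import preprocess, synthetic
from stimnet.preprocess import ResponseMatrix


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SimulationConfig:
    """Compact cohort: 3 modules + regulons + noise, fast to simulate."""
    return synthetic.SimulationConfig(
        n_genes=700,
        n_patients=38,
        n_modules=3,
        module_sizes=(80, 70, 60),
        n_tfs=10,
        targets_per_tf=25,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synthetic.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_response(small_cohort) -> ResponseMatrix:
    baseline, stimulated, _, _ = small_cohort
    resp, _ = preprocess.build_response_matrix(baseline, stimulated)
    return resp


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_response(values: np.ndarray, prefix: str = "G") -> ResponseMatrix:
    genes = [f"{prefix}{i:04d}" for i in range(values.shape[0])]
    patients = [f"P{j:03d}" for j in range(values.shape[1])]
    return ResponseMatrix(pd.DataFrame(values, index=genes, columns=patients))


@pytest.fixture(scope="session")
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
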