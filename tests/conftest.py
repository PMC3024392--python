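import numpy as np
import pandas as pd
import pytest

import lipidshape as ls


@pytest.fixture(scope="session")
def default_panel():
    return ls.default_lipid_panel()


@pytest.fixture(scope="session")
def lamin_plus_table(default_panel):
    """Discovery-study-sized draw: 11 cases vs 11 controls, 286 species."""
    return ls.generate_lipid_study(default_panel, 11, 11, seed=1)


@pytest.fixture(scope="session")
def augmented_table(lamin_plus_table):
    return ls.enumerate_ratio_variables(lamin_plus_table)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Scaled-down mesh (full pipeline, fewer vertices) for fast shape tests."""
    return ls.HeartCohortSpec(
        points_per_surface={"lv_endo": 180, "rv_endo": 240, "epicardium": 180},
    )


def make_chain(n: int, p: int, r: float, rng: np.random.Generator) -> pd.DataFrame:
    """First-order Gauss-Markov chain: corr(i, j) = r^|i-j|; the conditional
    independence graph is the path v0 - v1 - ... - v_{p-1}."""
    X = np.empty((n, p))
    X[:, 0] = rng.standard_normal(n)
    for k in range(1, p):
        X[:, k] = r * X[:, k - 1] + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return pd.DataFrame(X, columns=[f"v{k}" for k in range(p)])
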