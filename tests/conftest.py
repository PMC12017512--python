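import numpy as np
import pandas as pd
import pytest

import msgrad as mg


@pytest.fixture(scope="session")
def parcels100():
    return mg.make_parcels(100, 4, seed=1)


@pytest.fixture(scope="session")
def truth100(parcels100):
    return mg.default_truth(parcels100, seed=1)


@pytest.fixture(scope="session")
def small_cohort(parcels100, truth100):
    scans, truth = mg.simulate_cohort(parcels100, truth100, n_subjects=30, seed=3)
    return scans, truth


@pytest.fixture(scope="session")
def fitted_cohort(parcels100, small_cohort):
    scans, _ = small_cohort
    return mg.MultiscaleGradientModel(scans, parcels100).fit()


def make_phenotypes(n_subj, rng, longitudinal=True):
    """Accelerated-longitudinal phenotype table (1-3 scans per subject)."""
    rows = []
    for s in range(n_subj):
        k = int(rng.choice([1, 2, 3], p=[0.57, 0.30, 0.13])) if longitudinal else 1
        a0 = rng.uniform(6, 14 - 1.0 * (k - 1))
        for t in range(k):
            rows.append({
                "subject_id": f"s{s}",
                "age": a0 + t * rng.uniform(0.5, 1.5),
                "sex": int(rng.integers(0, 2)),
                "motion": float(rng.gamma(2, 0.05)),
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sphere200():
    p = mg.make_parcels(200, 4, seed=2)
    d = p.distance()
    chol = np.linalg.cholesky(np.exp(-d / 0.5) + 1e-8 * np.eye(200))
    return p, d, chol
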