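import numpy as np
import pytest

import lesionpls as lp


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-configuration synthetic cohort shared across tests."""
    return lp.make_cohort(seed=0)


@pytest.fixture(scope="session")
def fitted_best_model(default_synthetic):
    """PLS(lesions+hours) fitted on the full default cohort, plus its design."""
    spec = lp.ModelSpec(("hours", "lesions"), n_components=2)
    model = lp.fit_model(default_synthetic.cohort, spec)
    X = default_synthetic.cohort.design(spec.block_names)
    return model, X


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_tiny_cohort(n=12, p=4, seed=0, coef=None, noise_sd=0.0):
    """Small dense cohort with a planted linear response, for unit tests."""
    import pandas as pd

    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    if coef is None:
        coef = np.zeros(p)
        coef[0] = 3.0
    y = X @ coef + r.normal(0, noise_sd, size=n)
    cols = [f"x{j}" for j in range(p)]
    return lp.Cohort(
        patient_ids=tuple(f"P{i:02d}" for i in range(n)),
        blocks={"lesions": pd.DataFrame(X, columns=cols)},
        response=y,
    )
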