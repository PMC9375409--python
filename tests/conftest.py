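import numpy as np
import pandas as pd
import pytest

from standcomp import CauseModelSet, FPMSpec, SurvivalDataset, fit
from standcomp.simulate import default_spec, simulate


@pytest.fixture(scope="session")
def sim_spec():
    return default_spec(n=800, seed=42)


@pytest.fixture(scope="session")
def sim_data(sim_spec):
    return simulate(sim_spec)


@pytest.fixture(scope="session")
def fitted_pair(sim_data):
    """Two cause-specific proportional-hazards fits on the shared dataset."""
    spec = FPMSpec(df=2, covariates=("x", "age1", "age2", "comorb"))
    m1 = fit(sim_data, spec, event_cause=1)
    m2 = fit(sim_data, spec, event_cause=2)
    return CauseModelSet((m1, m2), ("c1", "c2"))


def make_weibull_data(n, lam, shape, beta, seed, censor=60.0):
    """Single-cause Weibull data with one binary covariate; known truth."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    e = rng.exponential(size=n)
    t = (e / (lam * np.exp(beta * x))) ** (1.0 / shape)
    time = np.minimum(t, censor)
    cause = (t <= censor).astype(int)
    # guard against all-censored pathological draws in tiny samples
    time = np.maximum(time, 1e-9)
    return SurvivalDataset(
        time=time, cause=cause, covariates=pd.DataFrame({"x": x}), treatment="x"
    )


@pytest.fixture(scope="session")
def weibull_fit():
    """A df=1 fit on large single-cause Weibull data (lam=0.01, p=1.3, b=-0.5)."""
    data = make_weibull_data(5000, 0.01, 1.3, -0.5, seed=7)
    model = fit(data, FPMSpec(df=1, covariates=("x",)), event_cause=1)
    return data, model
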