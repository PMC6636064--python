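import numpy as np
import pandas as pd
import pytest

from cvduncert.synthetic_cohort import TrueModelSpec, generate_cohort


def null_spec(**overrides):
    """Spec with every covariate effect, trend, region and dropout removed."""
    spec = TrueModelSpec.default()
    cfg = spec.cfg
    for key in ("age", "bmi", "sbp", "sbp_variability", "chol_hdl", "townsend"):
        cfg["loghr"][key]["value"] = 0.0
    cfg["loghr"]["smoking"] = {k: 0.0 for k in cfg["loghr"]["smoking"]}
    cfg["loghr"]["ethnicity"] = {k: 0.0 for k in cfg["loghr"]["ethnicity"]}
    cfg["loghr"]["flags"] = {k: 0.0 for k in cfg["loghr"]["flags"]}
    cfg["loghr"]["consult_gt50"] = 0.0
    cfg["loghr"]["rx_gt50"] = 0.0
    cfg["trend_loghr"] = 0.0
    cfg["region_effect_sd"] = 0.0
    cfg["dropout_rate"] = 0.0
    cfg.update(overrides)
    return TrueModelSpec(cfg)


@pytest.fixture(scope="session")
def default_spec():
    return TrueModelSpec.default()


@pytest.fixture(scope="session")
def cohort_20k(default_spec):
    """One mid-sized complete cohort shared across read-only tests."""
    return generate_cohort(default_spec, 20_000, seed=42)


@pytest.fixture()
def survival_fixture_200():
    """200-row survival fixture with tied event times, three covariates."""
    rng = np.random.default_rng(7)
    n = 200
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.binomial(1, 0.4, n).astype(float),
        "x3": rng.uniform(-1, 1, n),
    })
    lp = 0.6 * X["x1"] - 0.8 * X["x2"] + 0.3 * X["x3"]
    t = rng.exponential(np.exp(-(lp - lp.mean())))
    c = rng.exponential(1.5, n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    times = np.ceil(times * 8) / 8          # coarsen to force ties
    return X, times, events
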