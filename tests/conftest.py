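import numpy as np
import pandas as pd
import pytest

from betaforest import simulate


def make_bivariate(beta0: float, n: int, seed: int) -> pd.DataFrame:
    """Bivariate normal sample whose population standardized slope is beta0."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = beta0 * x + np.sqrt(1.0 - beta0**2) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y})


@pytest.fixture(scope="session")
def decathlon_small() -> pd.DataFrame:
    return simulate.simulate_decathlon(n_units=2_000, seed=11)


@pytest.fixture(scope="session")
def timss_small() -> pd.DataFrame:
    cfg = simulate.HierarchyConfig(
        n_countries=8, schools_per_country=6, students_per_school=8, seed=21
    )
    return simulate.simulate_timss_like(cfg)


@pytest.fixture(scope="session")
def timss_fit_table(timss_small) -> pd.DataFrame:
    """The 250-row fit table (5 predictors x 50 PV outcomes), plain OLS for speed."""
    from betaforest import regression

    pvs = simulate.pv_column_names()
    preds = list(simulate.PREDICTOR_MARGINALS)
    fits = regression.fit_model_grid(timss_small, pvs, preds)
    assert (fits["error"] == "").all()
    return fits
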