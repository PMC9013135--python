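import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import wealthgap as wg


@pytest.fixture(scope="session")
def default_config():
    return wg.default_population_config(seed=11)


@pytest.fixture(scope="session")
def default_data(default_config):
    """60k records: 40 countries x 50 clusters x 30 births."""
    return wg.generate_multicountry(default_config, 11)


@pytest.fixture(scope="session")
def default_frame(default_data):
    return wg.build_analysis_frame(default_data)


@pytest.fixture(scope="session")
def null_config():
    """No group effect, no covariate gaps, no random effects."""
    return wg.PopulationConfig(
        n_countries=2,
        clusters_per_country=40,
        births_per_cluster=50,
        covariates=(
            wg.CovariateSpec("x", ("a", "b"), p_poor=(0.5, 0.5), p_non_poor=(0.5, 0.5)),
        ),
        outcome=wg.OutcomeModel(
            intercept=float(logit(0.05)), poor_effect=0.0, covariate_effects={"x": {"a": 0.3}}
        ),
        cluster_re_sd=0.0,
        country_effect_sd=0.0,
    )


def make_frame(rates, n_per_group=1000, weights=None):
    """Deterministic single-country frame with exact per-quintile death rates.

    ``rates`` maps quintile -> death proportion with n_per_group records each.
    """
    rows = []
    for q, rate in rates.items():
        deaths = int(round(rate * n_per_group))
        for i in range(n_per_group):
            rows.append(
                {
                    "country_id": "X",
                    "cluster_id": f"X-{q}",
                    "weight": 1.0 if weights is None else weights,
                    "wealth_quintile": q,
                    "died": 1 if i < deaths else 0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
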