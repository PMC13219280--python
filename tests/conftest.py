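import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import groovesync as gs

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    return gs.generate_design(gs.DesignSpec(n_participants=12, seed=11))


@pytest.fixture(scope="session")
def trial_table(small_design) -> pd.DataFrame:
    table, _ = gs.simulate_ratings(small_design, seed=12)
    return table


@pytest.fixture(scope="session")
def iid_dgp() -> gs.RatingDGP:
    """Study DGP without participant random intercepts: iid trials."""
    base = gs.default_rating_dgp()
    return gs.RatingDGP(
        intercepts=base.intercepts,
        paths=base.paths,
        random_intercept_sd={k: 0.0 for k in base.random_intercept_sd},
        residual_sd=base.residual_sd,
    )


def make_exact_correlation(r: float, n: int, seed: int = 0):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y
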