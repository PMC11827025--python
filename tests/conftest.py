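import numpy as np
import pytest

from usualintake.cohort import GROUPS
from usualintake.dietary_references import load_dri_table
from usualintake.synthetic import SimConfig, generate_cohort, make_truth


def homogeneous_config(lam, median, cv_between=0.10, cv_within=0.20, n=2000, seed=1, **kw):
    """Single-population config: identical group means, no covariate effects."""
    truth = make_truth(
        lam, {g: median for g in GROUPS}, cv_between, cv_within,
        weekend_pct=0.0, seq_pct=0.0,
    )
    return SimConfig(
        n_persons=n, nutrients={"x": truth}, supplement_dose={"x": 0.0}, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def dri():
    return load_dri_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Default study-condition generator at a small size, fixed seed."""
    return generate_cohort(SimConfig(n_persons=400, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
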