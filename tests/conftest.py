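import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COMP_COLS = ["mvpa_min", "lpa_min", "sb_min", "sleep_min"]


@pytest.fixture(scope="session")
def basis():
    from movetypes.composition import build_basis

    return build_basis(4)


@pytest.fixture(scope="session")
def children_cohort():
    """One fixed synthetic children cohort (n=374, seed 1)."""
    from movetypes.synthetic import children_preset, generate_cohort

    return generate_cohort(children_preset(), seed=1)


@pytest.fixture(scope="session")
def children_fit(children_cohort, basis):
    """A 2-class fit on the fixed children cohort."""
    from movetypes.composition import ilr_matrix
    from movetypes.lpa import fit_lpa

    Z = ilr_matrix(children_cohort[COMP_COLS].to_numpy(), basis)
    return Z, fit_lpa(Z, K=2, n_starts=20, seed=1, tol=1e-8, max_iter=600)
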