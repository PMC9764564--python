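import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_spec():
    from costnet.synthetic import CohortSpec

    # small cohort: enough subjects per group for covariate-adjusted inference
    return CohortSpec(n_per_group=(5, 4, 4), n_timepoints=80, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    from costnet.synthetic import simulate_cohort

    return simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_spec, tmp_path_factory):
    from costnet.synthetic import synthesize_cohort

    path = tmp_path_factory.mktemp("cohort")
    synthesize_cohort(tiny_spec, path)
    return path


def star_graph(n_leaves: int = 4, weight: float = 1.0) -> np.ndarray:
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = weight
    w[1:, 0] = weight
    return w


def path_graph(weights) -> np.ndarray:
    n = len(weights) + 1
    w = np.zeros((n, n))
    for i, wt in enumerate(weights):
        w[i, i + 1] = w[i + 1, i] = wt
    return w


def complete_graph(n: int, weight: float = 1.0) -> np.ndarray:
    w = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(w, 0.0)
    return w
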