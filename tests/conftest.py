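import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import woundcdss as w

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tree():
    return w.load_default_tree()


@pytest.fixture(scope="session")
def key():
    return w.load_default_key()


@pytest.fixture(scope="session")
def question_states():
    return w.load_question_states()


@pytest.fixture(scope="session")
def all_states():
    return w.enumerate_states()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def sim_table():
    """One moderately sized simulated crossover trial (reused read-only)."""
    params = w.SimulationParams(
        n_participants=60,
        p_correct_control=0.25,
        p_correct_intervention=0.60,
        random_intercept_sd=1.0,
        seed=42,
    )
    return w.simulate_trial(params)


def random_binary_table(rng, n_clusters=30, cluster_size=6, p=0.4, beta_x=0.8):
    """Small clustered logistic table for oracle comparisons."""
    rows = []
    for c in range(n_clusters):
        x = rng.normal(size=cluster_size)
        eta = np.log(p / (1 - p)) + beta_x * x
        y = (rng.random(cluster_size) < 1 / (1 + np.exp(-eta))).astype(int)
        for xi, yi in zip(x, y):
            rows.append({"cluster": c, "x": float(xi), "y": int(yi)})
    return pd.DataFrame(rows)
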