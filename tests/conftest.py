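"""Shared fixtures: random model instances and precomputed sweep results."""

from __future__ import annotations

import numpy as np
import pytest

import livingpresent as lp

SUITE_SEED = 1234
SUITE_SIZE = 100


def random_model(rng: np.random.Generator,
                 n_states: int | None = None,
                 n_outcomes: int | None = None) -> lp.GenerativeModel:
    """A fully interior (no zero entries) random categorical model."""
    n = n_states or int(rng.integers(2, 6))
    no = n_outcomes or int(rng.integers(2, 6))
    a = rng.dirichlet(np.ones(no), size=n).T
    b = rng.dirichlet(np.ones(n), size=n).T
    d = rng.dirichlet(np.ones(n))
    return lp.GenerativeModel(A=a, B=(b,), D=d)


def random_instance(rng: np.random.Generator,
                    ) -> tuple[lp.GenerativeModel, list[int]]:
    """Random model (2-5 states/outcomes) plus 3-8 random outcomes."""
    model = random_model(rng)
    T = int(rng.integers(3, 9))
    obs = [int(x) for x in rng.integers(0, model.n_outcomes, T)]
    return model, obs


@pytest.fixture(scope="session")
def model_suite() -> list[tuple[lp.GenerativeModel, list[int]]]:
    rng = np.random.default_rng(SUITE_SEED)
    return [random_instance(rng) for _ in range(SUITE_SIZE)]


@pytest.fixture(scope="session")
def swept_suite(model_suite):
    """Gradient-sweep results (default message reading) plus exact posteriors
    for every suite instance; shared across the slow property tests."""
    results = []
    config = lp.UpdateConfig()  # dt=0.1, elementwise-log messages
    for model, obs in model_suite:
        lattice = lp.BeliefLattice.from_observations(model, obs)
        swept, record = lp.gradient_sweep(lattice, config)
        exact = lp.forward_backward(model, obs)
        results.append({
            "model": model,
            "obs": obs,
            "lattice": swept,
            "record": record,
            "exact": exact,
        })
    return results
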