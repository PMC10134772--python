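import numpy as np
import pytest

import snapkin as sk
from snapkin.kinetics import propagate_moments


def random_conserving_matrix(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random rate matrix with nonnegative off-diagonal and zero column sums."""
    M = rng.uniform(0.0, 1.0, size=(p, p))
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, -M.sum(axis=0))
    return M


@pytest.fixture(scope="session")
def chain4_run():
    """2,500-cell four-species chain with U(0,1) rates, snapshots at 0 and 30 s."""
    return sk.simulate_chain(4, n_cells=2500, times=(0.0, 30.0), seed=1)


@pytest.fixture(scope="session")
def chain4_truth_rates():
    return sk.chain_rates(4, np.random.default_rng(1))


@pytest.fixture(scope="session")
def chain4_moments(chain4_run):
    m1 = sk.compute_moments(chain4_run.snapshots[0])
    m2 = sk.compute_moments(chain4_run.snapshots[1])
    return m1, m2


@pytest.fixture(scope="session")
def chain4_closed_form(chain4_run, chain4_truth_rates):
    """t1 moments from the cells; t2 moments by exact closed-form propagation."""
    m1 = sk.compute_moments(chain4_run.snapshots[0])
    M = sk.build_rate_matrix(chain4_truth_rates, chain4_run.measured_panel)
    m2 = propagate_moments(m1, M, 30.0)
    return m1, m2, M
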