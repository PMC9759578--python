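import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_symmetric(rng, n, radius=0.8):
    """Random symmetric matrix rescaled to the given spectral radius."""
    M = rng.standard_normal((n, n))
    W = (M + M.T) / 2.0
    rho = np.max(np.abs(np.linalg.eigvalsh(W)))
    return W * (radius / rho)


def truncated_series_avg_ctrb(A, n_terms=500):
    """Brute-force average controllability: sum_t ||A^t e_i||^2 per region.

    Independent of the Lyapunov solver: accumulates the matrix power
    series term by term.
    """
    n = A.shape[0]
    acc = np.zeros(n)
    P = np.eye(n)
    for _ in range(n_terms):
        acc += np.sum(P**2, axis=0)  # column i: A^t e_i
        P = A @ P
    return acc
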