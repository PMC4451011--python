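"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from coadapt.encoding import Encoder
from coadapt.statespace import KinematicPrior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_prior(rng: np.random.Generator, n: int, rho_max: float = 0.95) -> KinematicPrior:
    """Random stable AR(1) prior with PSD process noise."""
    P = rng.standard_normal((n, n))
    radius = np.max(np.abs(np.linalg.eigvals(P)))
    P *= rng.uniform(0.3, rho_max) / max(radius, 1e-12)
    B = rng.standard_normal((n, n))
    Q = B @ B.T / n + 0.05 * np.eye(n)
    return KinematicPrior(P, Q)


def random_instance(rng: np.random.Generator, n: int, k: int) -> tuple[KinematicPrior, Encoder]:
    """Random stable prior plus a random encoder with PD noise."""
    prior = random_prior(rng, n)
    A = rng.standard_normal((k, n))
    B = rng.standard_normal((k, k))
    C = B @ B.T / k + 0.1 * np.eye(k)
    return prior, Encoder(A, C)


def kalman_gain_recursion(
    enc: Encoder, prior: KinematicPrior, steps: int = 500
) -> np.ndarray:
    """Independent oracle: the time-varying Kalman filter's gain after `steps`
    predict/update cycles starting from the stationary prior covariance.

    Standard recursion, written directly from the textbook update -- kept
    free of any code path it is used to check.
    """
    from coadapt.statespace import solve_lyapunov

    P, Q, A, C = prior.P, prior.Q, enc.A, enc.C
    Sigma_pred = solve_lyapunov(prior)  # prediction-error covariance at t=0
    K = None
    for _ in range(steps):
        S = A @ Sigma_pred @ A.T + C
        K = Sigma_pred @ A.T @ np.linalg.inv(S)
        Sigma_post = Sigma_pred - K @ A @ Sigma_pred
        Sigma_pred = P @ Sigma_post @ P.T + Q
    return K
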