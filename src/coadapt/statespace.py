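"""AR(1) kinematic prior: representation, stationary covariance, sampling.

The intended-kinematics process is a zero-mean first-order autoregression

    x_t = P x_{t-1} + z_t,      z_t ~ N(0, Q),

with an n-dimensional state (cursor position in the tasks considered here).
Stationarity requires the spectral radius of P to be strictly below one; the
stationary covariance Sigma_x solves the discrete Lyapunov equation
Sigma_x = P Sigma_x P^T + Q.

Time is a unitless step index; when mapped to task wall-clock one step is
0.1 s (the 10 Hz sample rate of the cursor tasks).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._linalg import as_matrix, check_psd, psd_sqrt, spectral_radius, symmetrize, ar1_filter
from .exceptions import StationarityError, ValidationError

__all__ = ["KinematicPrior", "solve_lyapunov", "lyapunov_iteration", "sample_trajectory"]


@dataclass(frozen=True)
class KinematicPrior:
    """AR(1) prior over intended kinematics: transition P and process noise Q.

    Q is symmetrized on construction (asymmetry beyond 1e-12 rejected) and small
    negative eigenvalues (>= -1e-10) are clipped to zero.  Construction fails if
    the spectral radius of P is not strictly below 1.
    """

    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        P = as_matrix(self.P, "P")
        if P.shape[0] != P.shape[1]:
            raise ValidationError(f"P must be square, got {P.shape}")
        Q = check_psd(self.Q, "Q")
        if Q.shape != P.shape:
            raise ValidationError(f"Q shape {Q.shape} does not match P shape {P.shape}")
        rho = spectral_radius(P)
        if rho >= 1.0:
            raise StationarityError(
                f"spectral radius of P is {rho:.6f} >= 1; the prior is non-stationary"
            )
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "Q", Q)

    @property
    def n(self) -> int:
        """State dimension."""
        return self.P.shape[0]

    @classmethod
    def isotropic(cls, n: int = 1, rho: float = 0.99, q: float = 0.01) -> "KinematicPrior":
        """Position-only prior P = rho*I, Q = q*I (the cursor-task default)."""
        return cls(rho * np.eye(n), q * np.eye(n))

    def to_dict(self) -> dict:
        return {"P": self.P.tolist(), "Q": self.Q.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "KinematicPrior":
        return cls(np.asarray(d["P"], dtype=float), np.asarray(d["Q"], dtype=float))


def solve_lyapunov(prior: KinematicPrior) -> np.ndarray:
    """Stationary covariance Sigma_x = P Sigma_x P^T + Q.

    Solved in closed form by vectorizing the Lyapunov equation
    (``scipy.linalg.solve_discrete_lyapunov``).  The result is validated
    against the fixed-point residual to 1e-9 relative.
    """
    method = "direct" if prior.n <= 30 else None
    Sigma = symmetrize(sla.solve_discrete_lyapunov(prior.P, prior.Q, method=method))
    resid = np.linalg.norm(Sigma - prior.P @ Sigma @ prior.P.T - prior.Q, "fro")
    if resid >= 1e-9 * (1.0 + np.linalg.norm(Sigma, "fro")):
        raise RuntimeError(f"Lyapunov solution residual too large: {resid:.3e}")
    return Sigma


def lyapunov_iteration(prior: KinematicPrior, tol: float = 1e-14, maxiter: int = 2_000_000) -> np.ndarray:
    """Matrix-recursion solution of the Lyapunov equation (reference/oracle path).

    Iterates Sigma <- P Sigma P^T + Q from Sigma = Q to convergence.
    """
    Sigma = prior.Q.copy()
    for _ in range(maxiter):
        nxt = symmetrize(prior.P @ Sigma @ prior.P.T + prior.Q)
        if np.abs(nxt - Sigma).max() <= tol * (1.0 + np.abs(nxt).max()):
            return nxt
        Sigma = nxt
    raise RuntimeError("Lyapunov iteration did not converge")  # pragma: no cover


def sample_trajectory(
    prior: KinematicPrior,
    T: int,
    seed: int | np.random.Generator | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Sample T steps of the AR(1) prior, shape (T, n).

    x_0 is drawn from the stationary distribution N(0, Sigma_x) unless given
    explicitly; subsequent steps follow x_t = P x_{t-1} + z_t.
    """
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = prior.n
    if x0 is None:
        x0 = psd_sqrt(solve_lyapunov(prior)) @ rng.standard_normal(n)
    else:
        x0 = np.asarray(x0, dtype=float).reshape(n)
    if T == 1:
        return x0[None, :].copy()
    Lq = psd_sqrt(prior.Q)
    z = rng.standard_normal((T - 1, n)) @ Lq.T
    rest = ar1_filter(prior.P, z, x0)
    return np.vstack([x0[None, :], rest])
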