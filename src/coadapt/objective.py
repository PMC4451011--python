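"""Analytic steady-state evaluation of the decoding error and full objective.

For an arbitrary (not necessarily optimal) encoder A and decoder (F, G), the
coupled intention/cursor process

    x_t    = P x_{t-1} + z_t
    xhat_t = F A P x_{t-1} + G xhat_{t-1} + F A z_t + F eps_t

is a linear AR(1) in the augmented state s_t = [x_t; xhat_t] with block
transition M = [[P, 0], [F A P, G]].  Its stationary second moments solve an
augmented discrete Lyapunov equation, from which the steady-state mean
squared error

    E(A, F, G) = E[(xhat_t - x_t)^T (xhat_t - x_t)]
               = tr(Shh - 2 Sxh + Sxx)

is exact and cheap -- no simulation.  The penalized objective is

    L(A, F, G) = E(A, F, G) + lambda * G(A)

with G the joint (trace-of-quotient) or SNR penalty.  ``empirical_mse``
provides the long-run simulation estimate used as an independent check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._linalg import psd_sqrt, sample_gaussian, spectral_radius, symmetrize, ar1_filter
from .encoding import Encoder, penalty as _penalty
from .exceptions import InstabilityError, ValidationError
from .statespace import KinematicPrior, solve_lyapunov

__all__ = [
    "JointMoments",
    "ObjectiveValue",
    "augmented_system",
    "stationary_joint_moments",
    "lagged_cross_moment",
    "mse_objective",
    "mse_expanded",
    "full_objective",
    "empirical_mse",
]


@dataclass(frozen=True)
class JointMoments:
    """Stationary second moments of (x_t, xhat_t).

    Sxx = E[x x^T], Sxh = E[x xhat^T], Shh = E[xhat xhat^T]; the stacked
    2n x 2n block matrix is symmetric PSD.
    """

    Sxx: np.ndarray
    Sxh: np.ndarray
    Shh: np.ndarray

    def block(self) -> np.ndarray:
        return np.block([[self.Sxx, self.Sxh], [self.Sxh.T, self.Shh]])


@dataclass(frozen=True)
class ObjectiveValue:
    """mse + lambda * penalty = total, with the pieces kept separate."""

    mse: float
    penalty: float
    lam: float

    @property
    def total(self) -> float:
        return self.mse + self.lam * self.penalty

    def to_dict(self) -> dict:
        return {"mse": self.mse, "penalty": self.penalty, "lambda": self.lam, "total": self.total}


def augmented_system(
    A: np.ndarray, F: np.ndarray, G: np.ndarray, prior: KinematicPrior, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Block transition M and innovation covariance W of the coupled process."""
    n = prior.n
    A = np.asarray(A, dtype=float).reshape(-1, n)
    F = np.asarray(F, dtype=float).reshape(n, -1)
    G = np.asarray(G, dtype=float).reshape(n, n)
    FA = F @ A
    M = np.block([[prior.P, np.zeros((n, n))], [FA @ prior.P, G]])
    QAF = prior.Q @ FA.T
    W = np.block([[prior.Q, QAF], [QAF.T, FA @ prior.Q @ FA.T + F @ C @ F.T]])
    return M, symmetrize(W)


def stationary_joint_moments(
    A: np.ndarray, F: np.ndarray, G: np.ndarray, prior: KinematicPrior, C: np.ndarray
) -> JointMoments:
    """Solve the augmented Lyapunov equation S = M S M^T + W at stationarity."""
    M, W = augmented_system(A, F, G, prior, C)
    rho = spectral_radius(M)
    if rho >= 1.0:
        raise InstabilityError(
            f"augmented intention/cursor system is unstable (spectral radius {rho:.4f}); "
            "the decoder recursion G is divergent"
        )
    S = symmetrize(sla.solve_discrete_lyapunov(M, W, method="direct"))
    resid = np.linalg.norm(S - M @ S @ M.T - W, "fro")
    if resid >= 1e-9 * (1.0 + np.linalg.norm(S, "fro")):  # pragma: no cover
        raise RuntimeError(f"augmented Lyapunov residual too large: {resid:.3e}")
    n = prior.n
    return JointMoments(Sxx=S[:n, :n], Sxh=S[:n, n:], Shh=S[n:, n:])


def lagged_cross_moment(moments: JointMoments, prior: KinematicPrior) -> np.ndarray:
    """E[x_t xhat_{t-1}^T] = P E[x_{t-1} xhat_{t-1}^T] = P Sxh (z_t indep. of xhat_{t-1})."""
    return prior.P @ moments.Sxh


def mse_objective(
    A: np.ndarray, F: np.ndarray, G: np.ndarray, prior: KinematicPrior, C: np.ndarray
) -> float:
    """Steady-state MSE tr(Shh - 2 Sxh + Sxx) from the augmented Lyapunov solve."""
    m = stationary_joint_moments(A, F, G, prior, C)
    return float(np.trace(m.Shh) - 2.0 * np.trace(m.Sxh) + np.trace(m.Sxx))


def mse_expanded(
    A: np.ndarray, F: np.ndarray, G: np.ndarray, prior: KinematicPrior, C: np.ndarray
) -> float:
    """Term-by-term expansion of the steady-state MSE using lagged moments.

    Writing xhat_t = (FA) x_t + F eps_t + G xhat_{t-1}, the error decomposes as

        tr((FA - I) Sxx (FA - I)^T) + 2 tr((FA - I) E[x_t xhat_{t-1}^T] G^T)
        + tr(F C F^T) + tr(G Shh G^T).

    Kept as a cross-check of the contemporaneous formulation.
    """
    n = prior.n
    A = np.asarray(A, dtype=float).reshape(-1, n)
    F = np.asarray(F, dtype=float).reshape(n, -1)
    G = np.asarray(G, dtype=float).reshape(n, n)
    m = stationary_joint_moments(A, F, G, prior, C)
    L = lagged_cross_moment(m, prior)
    FAI = F @ A - np.eye(n)
    return float(
        np.trace(FAI @ m.Sxx @ FAI.T)
        + 2.0 * np.trace(FAI @ L @ G.T)
        + np.trace(F @ C @ F.T)
        + np.trace(G @ m.Shh @ G.T)
    )


def full_objective(
    A: np.ndarray,
    F: np.ndarray,
    G: np.ndarray,
    prior: KinematicPrior,
    C: np.ndarray,
    lam: float,
    penalty_kind: str = "joint",
    Sigma_y: np.ndarray | None = None,
) -> ObjectiveValue:
    """L = E(A, F, G) + lambda * penalty(A).

    ``Sigma_y`` (optional) fixes the covariance in the joint penalty at a
    calibration value instead of the model-implied A Sigma_x A^T + C.
    """
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    mse = mse_objective(A, F, G, prior, C)
    enc = Encoder(np.asarray(A, dtype=float).reshape(-1, prior.n), C)
    pen = _penalty(enc, solve_lyapunov(prior), penalty_kind, Sigma_y)
    return ObjectiveValue(mse=mse, penalty=pen, lam=float(lam))


def empirical_mse(
    A: np.ndarray,
    F: np.ndarray,
    G: np.ndarray,
    prior: KinematicPrior,
    C: np.ndarray,
    T: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
    n_batches: int = 100,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the steady-state MSE from a T-step simulation.

    Simulates the coupled process from a stationary start and time-averages
    the squared error.  Returns ``(mse, se)`` where ``se`` is a batch-means
    standard error (batches much longer than the mixing time).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = prior.n
    A = np.asarray(A, dtype=float).reshape(-1, n)
    F = np.asarray(F, dtype=float).reshape(n, -1)
    G = np.asarray(G, dtype=float).reshape(n, n)
    k = A.shape[0]
    M, _ = augmented_system(A, F, G, prior, C)
    if spectral_radius(M) >= 1.0:
        raise InstabilityError("cannot simulate an unstable augmented system")
    m0 = stationary_joint_moments(A, F, G, prior, C)
    s0 = psd_sqrt(m0.block()) @ rng.standard_normal(2 * n)
    FA = F @ A
    z = sample_gaussian(prior.Q, T, rng)
    eps = sample_gaussian(C, T, rng)
    w = np.hstack([z, z @ FA.T + eps @ F.T])
    del z, eps
    s = ar1_filter(M, w, s0)
    err = s[:, n:] - s[:, :n]
    sq = np.einsum("ij,ij->i", err, err)
    usable = (T // n_batches) * n_batches
    means = sq[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(sq.mean()), float(means.std(ddof=1) / np.sqrt(n_batches))
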