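"""Steady-state Kalman filter decoder.

For the linear-Gaussian model (AR(1) prior, linear encoder) the Kalman gain
converges to a fixed point, giving the time-invariant decoder

    xhat_t = F y_t + G xhat_{t-1},

with F = Sigma_SS A^T (A Sigma_SS A^T + C)^{-1},  G = P - F A P, and
Sigma_SS the steady-state one-step prediction error covariance solving the
discrete algebraic Riccati equation

    Sigma_SS = P (Sigma_SS - Sigma_SS A^T (A Sigma_SS A^T + C)^{-1} A Sigma_SS) P^T + Q.

The default solve is scipy's dedicated DARE routine; a fixed-point iteration
of the equation above serves as fallback and as an independent oracle in
tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._linalg import as_matrix, spectral_radius, symmetrize
from .encoding import Encoder
from .exceptions import ConvergenceError, ValidationError
from .statespace import KinematicPrior, solve_lyapunov

__all__ = ["SSKFDecoder", "solve_sskf", "riccati_iteration", "decode_step", "decode_sequence"]

_RICCATI_TOL = 1e-12
_RICCATI_MAXITER = 100_000


@dataclass(frozen=True)
class SSKFDecoder:
    """Fixed decoder: gain F (n x k), recursion G (n x n), and Sigma_SS (n x n)."""

    F: np.ndarray
    G: np.ndarray
    Sigma_SS: np.ndarray

    def __post_init__(self) -> None:
        F = as_matrix(self.F, "F")
        G = as_matrix(self.G, "G")
        S = as_matrix(self.Sigma_SS, "Sigma_SS")
        if G.shape[0] != G.shape[1] or G.shape[0] != F.shape[0]:
            raise ValidationError(f"inconsistent decoder shapes F{F.shape}, G{G.shape}")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "Sigma_SS", symmetrize(S))

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def k(self) -> int:
        return self.F.shape[1]

    def to_dict(self) -> dict:
        return {"F": self.F.tolist(), "G": self.G.tolist(), "Sigma_SS": self.Sigma_SS.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SSKFDecoder":
        return cls(
            np.asarray(d["F"], dtype=float),
            np.asarray(d["G"], dtype=float),
            np.asarray(d["Sigma_SS"], dtype=float),
        )


def _gain_from_sigma(Sigma: np.ndarray, enc: Encoder) -> np.ndarray:
    S_innov = enc.A @ Sigma @ enc.A.T + enc.C
    return np.linalg.solve(S_innov.T, (Sigma @ enc.A.T).T).T


def _riccati_residual(Sigma: np.ndarray, enc: Encoder, prior: KinematicPrior) -> float:
    A, C, P, Q = enc.A, enc.C, prior.P, prior.Q
    K = np.linalg.solve((A @ Sigma @ A.T + C).T, (Sigma @ A.T).T).T
    rhs = P @ (Sigma - K @ A @ Sigma) @ P.T + Q
    return float(np.linalg.norm(Sigma - rhs, "fro"))


def riccati_iteration(
    enc: Encoder,
    prior: KinematicPrior,
    tol: float = _RICCATI_TOL,
    maxiter: int = _RICCATI_MAXITER,
) -> np.ndarray:
    """Fixed-point iteration of the Riccati equation starting from Sigma_x.

    Symmetrizes after every step.  Raises ConvergenceError (naming the final
    residual) if the iteration cap is hit.
    """
    A, C, P, Q = enc.A, enc.C, prior.P, prior.Q
    Sigma = solve_lyapunov(prior)
    for _ in range(maxiter):
        K = np.linalg.solve((A @ Sigma @ A.T + C).T, (Sigma @ A.T).T).T
        nxt = symmetrize(P @ (Sigma - K @ A @ Sigma) @ P.T + Q)
        if np.abs(nxt - Sigma).max() <= tol * (1.0 + np.abs(nxt).max()):
            return nxt
        Sigma = nxt
    raise ConvergenceError(
        "Riccati fixed-point iteration did not converge within "
        f"{maxiter} iterations (residual {_riccati_residual(Sigma, enc, prior):.3e})"
    )


def solve_sskf(enc: Encoder, prior: KinematicPrior, method: str = "dare") -> SSKFDecoder:
    """Solve for the steady-state Kalman filter decoder.

    ``method='dare'`` (default) uses ``scipy.linalg.solve_discrete_are`` with
    the fixed-point iteration as fallback; ``method='iterate'`` forces the
    iteration.  The two agree to well within 1e-7.
    """
    if enc.n != prior.n:
        raise ValidationError(f"encoder dimension {enc.n} != prior dimension {prior.n}")
    Sigma = None
    if method == "dare":
        try:
            Sigma = symmetrize(sla.solve_discrete_are(prior.P.T, enc.A.T, prior.Q, enc.C))
        except (np.linalg.LinAlgError, ValueError):
            Sigma = None
    elif method != "iterate":
        raise ValidationError(f"unknown method {method!r}")
    if Sigma is None or _riccati_residual(Sigma, enc, prior) > 1e-8 * (
        1.0 + np.linalg.norm(Sigma, "fro")
    ):
        Sigma = riccati_iteration(enc, prior)
    F = _gain_from_sigma(Sigma, enc)
    G = prior.P - F @ enc.A @ prior.P
    dec = SSKFDecoder(F=F, G=G, Sigma_SS=Sigma)
    rho = spectral_radius(G)
    if rho >= 1.0:  # pragma: no cover - cannot happen for a converged SSKF
        raise ConvergenceError(f"SSKF recursion matrix unstable (spectral radius {rho:.4f})")
    return dec


def decode_step(dec: SSKFDecoder, y: np.ndarray, xhat_prev: np.ndarray) -> np.ndarray:
    """One decoder update: xhat_t = F y_t + G xhat_{t-1} (pure function)."""
    y = np.asarray(y, dtype=float).reshape(-1)
    xhat_prev = np.asarray(xhat_prev, dtype=float).reshape(-1)
    if y.shape[0] != dec.k:
        raise ValidationError(f"y has length {y.shape[0]}, expected {dec.k}")
    if xhat_prev.shape[0] != dec.n:
        raise ValidationError(f"xhat_prev has length {xhat_prev.shape[0]}, expected {dec.n}")
    return dec.F @ y + dec.G @ xhat_prev


def decode_sequence(dec: SSKFDecoder, ys: np.ndarray, xhat0: np.ndarray | None = None) -> np.ndarray:
    """Apply the decoder along a sequence of observations; returns (T, n)."""
    ys = np.atleast_2d(np.asarray(ys, dtype=float))
    if ys.shape[0] == 0:
        raise ValidationError("ys must be nonempty")
    if ys.shape[1] != dec.k:
        raise ValidationError(f"ys has {ys.shape[1]} channels, expected {dec.k}")
    xhat = np.zeros(dec.n) if xhat0 is None else np.asarray(xhat0, dtype=float).reshape(dec.n)
    out = np.empty((ys.shape[0], dec.n))
    for t in range(ys.shape[0]):
        xhat = dec.F @ ys[t] + dec.G @ xhat
        out[t] = xhat
    return out
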