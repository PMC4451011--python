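"""Linear-Gaussian encoding model and the encoder resource penalties.

The encoder maps intention x_t (n-dim) to neural activity y_t (k channels):

    y_t = A x_t + eps_t,    eps_t ~ N(0, C).

In the BCI framing A is what the user learns; C is the channel noise.  Two
penalties constrain how much signal the encoder may place in the population:

* ``penalty_joint`` -- trace-of-quotient tr(Sigma_y^{-1} A Sigma_x A^T), the
  fraction of total neural covariance that is signal.  By default Sigma_y is
  the model-implied A Sigma_x A^T + C; passing a fixed ``Sigma_y`` (e.g. the
  empirical covariance from a calibration session) instead penalizes
  deviation of the encoded signal from the native covariance structure,
  which is what makes low-noise channels genuinely cheaper to use.
* ``penalty_snr`` -- tr(C^{-1} A Sigma_x A^T), total signal-to-noise ratio;
  unbounded above, which is why the unconstrained MMSE problem degenerates
  to infinitely strong encoding.

Quotients are evaluated with symmetric solves (Cholesky), never explicit
inverses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import linalg as sla

from ._linalg import as_matrix, symmetrize
from .exceptions import ValidationError

__all__ = [
    "Encoder",
    "NeuralStatistics",
    "neural_response",
    "neural_statistics",
    "penalty_joint",
    "penalty_snr",
    "penalty",
]


@dataclass(frozen=True)
class Encoder:
    """Observation matrix A (k x n) and strictly positive definite noise C (k x k)."""

    A: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        A = as_matrix(self.A, "A")
        C = as_matrix(self.C, "C")
        if C.shape[0] != C.shape[1]:
            raise ValidationError(f"C must be square, got {C.shape}")
        if C.shape[0] != A.shape[0]:
            raise ValidationError(
                f"A has {A.shape[0]} rows but C is {C.shape[0]} x {C.shape[1]}"
            )
        scale = max(1.0, float(np.abs(C).max()))
        if np.abs(C - C.T).max() > 1e-12 * scale:
            raise ValidationError("C is not symmetric")
        C = symmetrize(C)
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            raise ValidationError("C must be strictly positive definite") from None
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)

    @property
    def k(self) -> int:
        """Number of neural channels."""
        return self.A.shape[0]

    @property
    def n(self) -> int:
        """Kinematic dimension encoded."""
        return self.A.shape[1]

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "C": self.C.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Encoder":
        return cls(np.asarray(d["A"], dtype=float), np.asarray(d["C"], dtype=float))


class NeuralStatistics(NamedTuple):
    """Second moments of the neural population: signal and total covariance."""

    Sigma_sig: np.ndarray  # A Sigma_x A^T, rank <= n
    Sigma_y: np.ndarray    # Sigma_sig + C


def neural_statistics(enc: Encoder, Sigma_x: np.ndarray) -> NeuralStatistics:
    Sigma_sig = symmetrize(enc.A @ Sigma_x @ enc.A.T)
    return NeuralStatistics(Sigma_sig, Sigma_sig + enc.C)


def neural_response(
    enc: Encoder,
    x: np.ndarray,
    rng: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Simulate y = A x + eps.  `x` may be a single n-vector or a (T, n) batch.

    ``noise=False`` disables the Gaussian noise draw (the noiseless intuition
    cases); C itself must always stay positive definite.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != enc.n:
        raise ValidationError(f"x has dimension {X.shape[1]}, expected {enc.n}")
    Y = X @ enc.A.T
    if noise:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        Y = Y + gen.standard_normal((X.shape[0], enc.k)) @ np.linalg.cholesky(enc.C).T
    return Y[0] if single else Y


def penalty_joint(
    enc: Encoder, Sigma_x: np.ndarray, Sigma_y: np.ndarray | None = None
) -> float:
    """tr(Sigma_y^{-1} A Sigma_x A^T).

    With the model-implied Sigma_y (default) every generalized eigenvalue of
    (Sigma_sig, Sigma_y) lies in [0, 1), so the value sits in [0, min(k, n)).
    With a fixed calibration Sigma_y the quotient is quadratic in A.
    """
    Sigma_sig = enc.A @ Sigma_x @ enc.A.T
    if Sigma_y is None:
        Sigma_y = Sigma_sig + enc.C
    cf = sla.cho_factor(symmetrize(np.asarray(Sigma_y, dtype=float)), lower=True)
    return float(np.trace(sla.cho_solve(cf, symmetrize(Sigma_sig))))


def penalty_snr(enc: Encoder, Sigma_x: np.ndarray) -> float:
    """tr(C^{-1} A Sigma_x A^T): total SNR; nonnegative, unbounded above."""
    try:
        cf = sla.cho_factor(enc.C, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover - Encoder guarantees PD
        raise ValidationError("C is singular") from None
    return float(np.trace(sla.cho_solve(cf, symmetrize(enc.A @ Sigma_x @ enc.A.T))))


def penalty(
    enc: Encoder,
    Sigma_x: np.ndarray,
    kind: str = "joint",
    Sigma_y: np.ndarray | None = None,
) -> float:
    """Dispatch on penalty kind ('joint' or 'snr')."""
    if kind == "joint":
        return penalty_joint(enc, Sigma_x, Sigma_y)
    if kind == "snr":
        return penalty_snr(enc, Sigma_x)
    raise ValidationError(f"unknown penalty kind {kind!r}")
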