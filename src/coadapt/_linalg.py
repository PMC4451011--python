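"""Small linear-algebra helpers used throughout the package.

These are private: symmetrization, PSD square roots, spectral radii, and a
fast sampler for linear recursions s_t = M s_{t-1} + w_t (vector AR(1)).
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .exceptions import ValidationError

# Condition-number cutoff above which the modal (eigendecomposition) AR
# sampler is considered unreliable and the plain loop is used instead.
_MODAL_COND_MAX = 1e8


def symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def spectral_radius(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M)))) if M.size else 0.0


def as_matrix(M, name: str = "matrix") -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim == 0:
        A = A.reshape(1, 1)
    if A.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got ndim={A.ndim}")
    if not np.all(np.isfinite(A)):
        raise ValidationError(f"{name} contains non-finite entries")
    return A


def check_psd(S: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    """Symmetrize and validate positive semidefiniteness.

    Asymmetry beyond 1e-12 (relative) is rejected; eigenvalues in
    [-tol, 0) are tolerated and clipped to zero.
    """
    S = as_matrix(S, name)
    if S.shape[0] != S.shape[1]:
        raise ValidationError(f"{name} must be square, got {S.shape}")
    scale = max(1.0, float(np.abs(S).max()))
    if np.abs(S - S.T).max() > 1e-12 * scale:
        raise ValidationError(f"{name} is not symmetric")
    S = symmetrize(S)
    w, V = np.linalg.eigh(S)
    if w.min() < -tol * scale:
        raise ValidationError(
            f"{name} is not positive semidefinite (min eigenvalue {w.min():.3e})"
        )
    if w.min() < 0.0:
        S = symmetrize((V * np.clip(w, 0.0, None)) @ V.T)
    return S


def psd_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (eigh-based, negatives clipped)."""
    w, V = np.linalg.eigh(symmetrize(S))
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


def sample_gaussian(cov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw `size` samples from N(0, cov); returns (size, d). Handles singular cov."""
    L = psd_sqrt(cov)
    return rng.standard_normal((size, cov.shape[0])) @ L.T


def ar1_filter(M: np.ndarray, w: np.ndarray, s0: np.ndarray) -> np.ndarray:
    """Run s_t = M s_{t-1} + w_t for t = 1..T.

    Parameters
    ----------
    M : (d, d) transition matrix.
    w : (T, d) innovations.
    s0 : (d,) initial state (state at t=0; not included in output).

    Returns
    -------
    (T, d) array with row t-1 holding s_t.

    Uses a modal decomposition of M so each mode becomes a scalar AR(1)
    evaluated by ``scipy.signal.lfilter``; falls back to a plain loop when
    M is defective or badly conditioned.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    d = M.shape[0]
    s0 = np.asarray(s0, dtype=float).reshape(d)
    try:
        lam, V = np.linalg.eig(M)
        if np.linalg.cond(V) < _MODAL_COND_MAX:
            u = np.linalg.solve(V, w.T)          # (d, T), possibly complex
            u0 = np.linalg.solve(V, s0)
            out = np.empty_like(u)
            for i in range(d):
                zi = np.array([lam[i] * u0[i]])
                out[i], _ = signal.lfilter([1.0], [1.0, -lam[i]], u[i], zi=zi)
            s = (V @ out).T
            return np.ascontiguousarray(s.real)
    except np.linalg.LinAlgError:  # pragma: no cover - defective M is rare
        pass
    s = np.empty_like(w)
    prev = s0
    for t in range(w.shape[0]):  # pragma: no cover - fallback path
        prev = M @ prev + w[t]
        s[t] = prev
    return s
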