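"""Canonical 1-DOF simulated examples with interpretable optima.

Two k-channel "electrode" settings where the signal and noise covariances
are specified directly (they are sufficient statistics for the
optimization) and the optimal encoder-decoder pair is easy to interpret:

* example 1 -- equal signal power on every channel, noise low on channels
  2 and 5 (1-indexed): the optimal pair transmits essentially all
  information along those two high-SNR channels.
* example 2 -- rank-1 signal covariance with power decreasing across
  channels, same noise as example 1: encoding favours high-signal
  dimensions and decoding favours high-signal, low-noise ones (channel 2
  is decoded more strongly than channel 1).

The penalty uses the fixed total covariance Sigma_y = Sigma_sig + C, i.e.
encoded activity is constrained against the native covariance structure.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .exceptions import ValidationError
from .optimize import OptimizerConfig, OptimizationResult, canonicalize_solution, coordinate_descent
from .statespace import KinematicPrior

__all__ = ["ExampleSpec", "make_example", "optimize_example", "LOW_NOISE_CHANNELS"]

LOW_NOISE_CHANNELS = (1, 4)  # 0-indexed channels 2 and 5


class ExampleSpec(NamedTuple):
    prior: KinematicPrior
    Sigma_sig: np.ndarray
    C: np.ndarray
    Sigma_y: np.ndarray


def make_example(example: int, k: int = 6, noise_high: float = 1.0, noise_low: float = 0.1) -> ExampleSpec:
    """Build the signal/noise covariances for example 1 or 2.

    The 1-D prior has unit stationary variance (rho = 0.99) so signal power
    per channel reads directly off Sigma_sig's diagonal.
    """
    if k < 5:
        raise ValidationError("need k >= 5 so channels 2 and 5 exist")
    rho = 0.99
    prior = KinematicPrior(np.array([[rho]]), np.array([[1.0 - rho**2]]))
    c = np.full(k, noise_high)
    c[list(LOW_NOISE_CHANNELS)] = noise_low
    C = np.diag(c)
    if example == 1:
        Sigma_sig = np.eye(k)
    elif example == 2:
        amp = np.sqrt(0.75) ** np.arange(k)  # signal power decays 0.75x per channel
        Sigma_sig = np.outer(amp, amp)
    else:
        raise ValidationError(f"unknown example {example!r} (expected 1 or 2)")
    return ExampleSpec(prior, Sigma_sig, C, Sigma_sig + C)


def optimize_example(
    example: int,
    k: int = 6,
    lam: float = 1.0,
    seed: int | None = 0,
    n_restarts: int = 3,
) -> OptimizationResult:
    """Run the joint optimization for an example and canonicalize signs."""
    spec = make_example(example, k)
    cfg = OptimizerConfig(
        lam=lam, penalty_kind="joint", Sigma_y_cal=spec.Sigma_y, seed=seed, n_restarts=n_restarts
    )
    return canonicalize_solution(coordinate_descent(spec.prior, spec.C, cfg))
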