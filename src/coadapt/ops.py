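"""Online-prosthesis-simulator (OPS) emulator.

The OPS is a human-in-the-loop psychophysics platform in which overt
movements drive synthetic noisy neural channels that are decoded in real
time, so the whole "BCI" is transparent and controllable.  This module
replaces the human with a simulated user so the entire closed loop runs on
the desk:

* three canonical *signal cases* (k = 6 channels) specify which
  movement/intention features drive which channels and where the noise is
  high vs low;
* a *simulated user* holds an encoding matrix A_user mapping 1-D intention
  (current target position) to the driven features; it may be frozen, or
  adapt by line-searched gradient steps on the same penalized MSE objective
  the joint optimizer uses (idealized learning against a fixed decoder);
* closed-loop *sessions* run the pinball (point-to-point reaching) or
  tracing (pursuit tracking) task at 10 steps/s and record everything;
* evaluation: target-acquisition metrics, cursor autocorrelation, encoder
  estimation by regression, and one-sided unpaired t-tests between decoder
  arms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.tsa.stattools import acf as _sm_acf

from .encoding import Encoder
from .exceptions import InstabilityError, ValidationError
from .objective import full_objective
from .optimize import (
    OptimizerConfig,
    OptimizationResult,
    canonicalize_encoder,
    canonicalize_solution,
    coordinate_descent,
    optimize_encoder_given_decoder,
    grad_objective_wrt_A,
)
from .sskf import SSKFDecoder, solve_sskf
from .statespace import KinematicPrior, sample_trajectory, solve_lyapunov

__all__ = [
    "SignalCase",
    "TaskSpec",
    "SimulatedUser",
    "SessionTrace",
    "build_signal_case",
    "run_closed_loop_session",
    "user_learning_update",
    "train_user",
    "rls_motor_imitation_init",
    "estimate_encoder_regression",
    "compare_encoders",
    "pinball_metrics",
    "compare_decoders",
    "cursor_acf",
    "precompute_decoder",
    "motor_imitation_decoder",
    "run_case_comparison",
    "OPS_LAMBDA",
]

# Default task prior: position-only AR(1) at 10 Hz, transition just under 1
# to discourage drift, small process noise matched to task movement rates.
DEFAULT_PRIOR = KinematicPrior.isotropic(1, 0.99, 0.01)

# Penalty weight for OPS pre-computation and user learning.  Crudely tuned
# once to the synthetic-activity scale: at this value the optimized encoder
# puts approximately the native per-channel signal power (that of a heavily
# used channel) into its preferred channel, i.e. SNR ~ 10 on a low-noise
# channel.  Held fixed across cases and arms.
OPS_LAMBDA = 0.01

# High:low channel noise, as a multiple of the signal power of a heavily
# used channel (high comparable to signal, low = 1/10 of it).
_NOISE_HIGH_FRAC = 1.0
_NOISE_LOW_FRAC = 0.1


@dataclass(frozen=True)
class SignalCase:
    """Mapping from movement/intention features to k = 6 neural channels.

    ``mixing`` is k x m (one driven channel per feature; remaining channels
    are pure noise); ``noise_var`` holds per-channel noise variances in the
    high/low pattern of the case; ``motor_features`` are the indices of the
    features a naive motor-imitation user drives (horizontal movement).
    """

    case_id: int
    mixing: np.ndarray
    noise_var: np.ndarray
    feature_names: tuple[str, ...]
    motor_features: tuple[int, ...]
    low_noise_channels: tuple[int, ...]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.noise_var) <= 0):
            raise ValidationError("noise variances must be strictly positive")

    @property
    def k(self) -> int:
        return self.mixing.shape[0]

    @property
    def m(self) -> int:
        return self.mixing.shape[1]

    def noise_cov(self) -> np.ndarray:
        return np.diag(self.noise_var)

    def calibration_sigma_y(self, sigma_x2: float) -> np.ndarray:
        """Native neural covariance during free calibration movement.

        All features are assumed driven independently with the stationary
        intention variance, as when the user 'moves around freely'.
        """
        return self.mixing @ (sigma_x2 * np.eye(self.m)) @ self.mixing.T + self.noise_cov()

    def motor_imitation_encoder(self, gain: float = 1.0) -> Encoder:
        """Biomimetic scheme: intention drives the horizontal feature(s) only."""
        b = np.zeros((self.m, 1))
        for f in self.motor_features:
            b[f, 0] = gain
        return Encoder(self.mixing @ b, self.noise_cov())


def build_signal_case(
    case_id: int, prior: KinematicPrior = DEFAULT_PRIOR
) -> tuple[SignalCase, Encoder]:
    """Construct one of the three canonical k = 6 signal cases.

    Returns the case together with the motor-imitation probe encoder (the
    naive both-hands-horizontal control scheme used to initialize the
    baseline decoder).

    Case 1: channels driven by right-hand horizontal / vertical position;
            noise low on the vertical channel only.
    Case 2: channels driven by the hands' summed horizontal position and by
            the distance between hands; the distance channel alone has low
            noise.
    Case 3: channels driven by each hand's horizontal and vertical position
            independently; noise low on the two vertical channels.
    Remaining channels are pure noise at the high level.
    """
    k = 6
    sigma_x2 = float(solve_lyapunov(prior)[0, 0])
    high = _NOISE_HIGH_FRAC * sigma_x2
    low = _NOISE_LOW_FRAC * sigma_x2
    if case_id == 1:
        names = ("rhand_horiz", "rhand_vert")
        low_ch = (1,)
        motor = (0,)
    elif case_id == 2:
        names = ("hands_sum_horiz", "hands_distance")
        low_ch = (1,)
        motor = (0,)
    elif case_id == 3:
        names = ("rhand_horiz", "rhand_vert", "lhand_horiz", "lhand_vert")
        low_ch = (1, 3)
        motor = (0, 2)
    else:
        raise ValidationError(f"unknown signal case {case_id!r} (expected 1, 2 or 3)")
    m = len(names)
    mixing = np.zeros((k, m))
    mixing[:m, :m] = np.eye(m)
    noise = np.full(k, high)
    noise[list(low_ch)] = low
    case = SignalCase(
        case_id=case_id,
        mixing=mixing,
        noise_var=noise,
        feature_names=names,
        motor_features=motor,
        low_noise_channels=low_ch,
    )
    # both hands move together horizontally: each motor feature at unit gain
    return case, case.motor_imitation_encoder(1.0)


@dataclass(frozen=True)
class TaskSpec:
    """Task geometry and timing.  Times in seconds; workspace is 1-D."""

    kind: str = "pinball"
    workspace: tuple[float, float] = (-1.0, 1.0)
    sample_rate: float = 10.0
    hold_time: float = 1.0
    timeout: float = 15.0
    session_length: float = 180.0
    halo_fraction: float = 0.075

    def __post_init__(self) -> None:
        if self.kind not in ("pinball", "tracing"):
            raise ValidationError(f"unknown task kind {self.kind!r}")
        if not (self.hold_time < self.timeout < self.session_length):
            raise ValidationError("need hold_time < timeout < session_length")
        if self.halo_fraction <= 0:
            raise ValidationError("halo radius must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_steps(self) -> int:
        return int(round(self.session_length * self.sample_rate))

    @property
    def hold_steps(self) -> int:
        return int(round(self.hold_time * self.sample_rate))

    @property
    def timeout_steps(self) -> int:
        return int(round(self.timeout * self.sample_rate))

    @property
    def halo_radius(self) -> float:
        lo, hi = self.workspace
        return self.halo_fraction * (hi - lo)


@dataclass(frozen=True)
class SimulatedUser:
    """Stand-in for the human: encoding A_user plus a learning rule.

    ``update_rule='gradient'`` takes line-searched gradient steps on the
    penalized MSE objective at fixed decoder (idealized optimal learning);
    ``'frozen'`` (or learning_rate = 0) keeps A_user fixed.  The penalty
    context (lam / kind / calibration covariance) is the user's constraint
    on learnable encodings.
    """

    A: np.ndarray
    learning_rate: float = 0.05
    update_rule: str = "frozen"
    lam: float = OPS_LAMBDA
    penalty_kind: str = "joint"
    Sigma_y_cal: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if not np.all(np.isfinite(A)):
            raise ValidationError("A_user must be finite")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.update_rule not in ("gradient", "frozen"):
            raise ValidationError(f"unknown update rule {self.update_rule!r}")
        object.__setattr__(self, "A", A)


@dataclass
class SessionTrace:
    """Per-step record of one closed-loop session plus acquisition events."""

    time: np.ndarray          # seconds, strictly increasing at dt
    target: np.ndarray        # (T,)
    x: np.ndarray             # intention, (T, n)
    y: np.ndarray             # neural activity, (T, k)
    xhat: np.ndarray          # decoded cursor, (T, n)
    in_halo: np.ndarray       # bool (T,)
    events: list              # [(kind, time_s)], kind in {'acquire', 'miss'}
    seed: int | None
    decoder_id: str
    task: TaskSpec
    case_id: int | None = None

    def to_csv(self, path: str | Path) -> None:
        """Write the step table as CSV and a JSON sidecar with metadata."""
        path = Path(path)
        k = self.y.shape[1]
        n = self.xhat.shape[1]
        cols = {"step": np.arange(len(self.time)), "time_s": self.time, "target": self.target}
        for j in range(n):
            cols[f"x_int_{j+1}"] = self.x[:, j]
        for j in range(k):
            cols[f"y_{j+1}"] = self.y[:, j]
        for j in range(n):
            cols[f"xhat_{j+1}"] = self.xhat[:, j]
        cols["in_halo"] = self.in_halo.astype(int)
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "decoder_id": self.decoder_id,
            "case_id": self.case_id,
            "events": [[kind, float(t)] for kind, t in self.events],
            "task": {
                "kind": self.task.kind,
                "workspace": list(self.task.workspace),
                "sample_rate": self.task.sample_rate,
                "hold_time": self.task.hold_time,
                "timeout": self.task.timeout,
                "session_length": self.task.session_length,
                "halo_fraction": self.task.halo_fraction,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SessionTrace":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as e:
            raise ValidationError(f"malformed trace CSV {path}: {e}") from None
        required = {"time_s", "target", "in_halo"}
        if not required.issubset(df.columns):
            raise ValidationError(f"trace CSV {path} is missing columns {required - set(df.columns)}")
        meta = json.loads(path.with_suffix(".json").read_text())
        t = meta["task"]
        task = TaskSpec(
            kind=t["kind"], workspace=tuple(t["workspace"]), sample_rate=t["sample_rate"],
            hold_time=t["hold_time"], timeout=t["timeout"],
            session_length=t["session_length"], halo_fraction=t["halo_fraction"],
        )
        xcols = sorted(c for c in df.columns if c.startswith("x_int_"))
        ycols = sorted(c for c in df.columns if c.startswith("y_"))
        hcols = sorted(c for c in df.columns if c.startswith("xhat_"))
        return cls(
            time=df["time_s"].to_numpy(),
            target=df["target"].to_numpy(),
            x=df[xcols].to_numpy(),
            y=df[ycols].to_numpy(),
            xhat=df[hcols].to_numpy(),
            in_halo=df["in_halo"].to_numpy().astype(bool),
            events=[(kind, float(t)) for kind, t in meta["events"]],
            seed=meta["seed"],
            decoder_id=meta["decoder_id"],
            task=task,
            case_id=meta.get("case_id"),
        )


def user_learning_update(
    user: SimulatedUser,
    dec: SSKFDecoder,
    prior: KinematicPrior,
    C: np.ndarray,
    max_backtracks: int = 30,
) -> SimulatedUser:
    """One line-searched gradient step on the user's objective at fixed decoder.

    Armijo backtracking from an initial step of ``learning_rate / (1 + |g|)``;
    guarantees the objective does not increase (no-step fallback).
    """
    if user.update_rule == "frozen" or user.learning_rate == 0.0:
        return user
    A = user.A
    g = grad_objective_wrt_A(
        A, dec.F, dec.G, prior, C, user.lam, user.penalty_kind, user.Sigma_y_cal
    )
    gnorm = float(np.linalg.norm(g))
    if gnorm < 1e-10:
        return user
    f0 = full_objective(
        A, dec.F, dec.G, prior, C, user.lam, user.penalty_kind, user.Sigma_y_cal
    ).total
    step = user.learning_rate / (1.0 + gnorm)
    for _ in range(max_backtracks):
        A_try = A - step * g
        f_try = full_objective(
            A_try, dec.F, dec.G, prior, C, user.lam, user.penalty_kind, user.Sigma_y_cal
        ).total
        if f_try <= f0 - 1e-4 * step * gnorm**2:
            return replace(user, A=A_try)
        step *= 0.5
    return user


def train_user(
    user: SimulatedUser,
    dec: SSKFDecoder,
    prior: KinematicPrior,
    C: np.ndarray,
    n_updates: int = 1000,
) -> SimulatedUser:
    """Repeatedly apply learning updates (the free-exploration phase, condensed)."""
    u = user if user.update_rule == "gradient" else replace(user, update_rule="gradient")
    for _ in range(n_updates):
        nxt = user_learning_update(u, dec, prior, C)
        if np.array_equal(nxt.A, u.A):
            break
        u = nxt
    return u


def run_closed_loop_session(
    user: SimulatedUser,
    dec: SSKFDecoder,
    case: SignalCase,
    task: TaskSpec,
    seed: int | None = None,
    prior: KinematicPrior = DEFAULT_PRIOR,
    noise: bool = True,
    learn_every: int = 10,
    decoder_id: str = "decoder",
) -> SessionTrace:
    """Run one closed-loop session of the pinball or tracing task.

    Each step: intention = current target position; neural activity
    y = A_user x + eps; cursor xhat = F y + G xhat_prev; then the
    acquisition / timeout bookkeeping.  A learning user takes a gradient
    step every ``learn_every`` steps.  Bitwise reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    T = task.n_steps
    n = dec.n
    k = case.k
    C = case.noise_cov()
    lo, hi = task.workspace
    halo = task.halo_radius
    noise_chol = np.sqrt(case.noise_var)  # diagonal C

    if task.kind == "tracing":
        targets_path = sample_trajectory(prior, T, rng)[:, 0]
    else:
        current_target = rng.uniform(lo, hi)

    time_s = np.arange(T) / task.sample_rate
    target_arr = np.empty(T)
    x_arr = np.empty((T, n))
    y_arr = np.empty((T, k))
    xhat_arr = np.empty((T, n))
    in_halo_arr = np.zeros(T, dtype=bool)
    events: list[tuple[str, float]] = []

    xhat = np.zeros(n)
    hold = 0
    steps_on_target = 0
    u = user
    for t in range(T):
        if task.kind == "tracing":
            current_target = targets_path[t]
        target_arr[t] = current_target
        x = np.full(n, current_target)
        eps = rng.standard_normal(k) * noise_chol if noise else np.zeros(k)
        y = u.A @ x + eps
        xhat = dec.F @ y + dec.G @ xhat
        if np.max(np.abs(xhat)) > 1e3:
            raise InstabilityError(
                f"decoded cursor diverged at step {t} (|xhat| = {np.max(np.abs(xhat)):.2e})"
            )
        x_arr[t] = x
        y_arr[t] = y
        xhat_arr[t] = xhat
        inside = abs(float(xhat[0]) - current_target) <= halo
        in_halo_arr[t] = inside
        if task.kind == "pinball":
            steps_on_target += 1
            hold = hold + 1 if inside else 0
            if hold >= task.hold_steps:
                events.append(("acquire", time_s[t]))
                current_target = rng.uniform(lo, hi)
                hold = 0
                steps_on_target = 0
            elif steps_on_target >= task.timeout_steps:
                events.append(("miss", time_s[t]))
                current_target = rng.uniform(lo, hi)
                hold = 0
                steps_on_target = 0
        if u.update_rule == "gradient" and learn_every > 0 and (t + 1) % learn_every == 0:
            u = user_learning_update(u, dec, prior, C)
    return SessionTrace(
        time=time_s,
        target=target_arr,
        x=x_arr,
        y=y_arr,
        xhat=xhat_arr,
        in_halo=in_halo_arr,
        events=events,
        seed=seed,
        decoder_id=decoder_id,
        task=task,
        case_id=case.case_id,
    )


# ---------------------------------------------------------------------------
# encoder estimation
# ---------------------------------------------------------------------------


def rls_motor_imitation_init(
    probe_intentions: np.ndarray,
    probe_neural: np.ndarray,
    delta: float = 1e8,
) -> np.ndarray:
    """Recursive least squares fit of the encoding from an open-loop probe.

    The motor-imitation protocol: the user traces a moving target without
    feedback, giving supervised (intention, neural) pairs; RLS estimates the
    k x n encoding online.  ``delta`` is the prior-precision initialization
    (covariance init delta * I); at these sample sizes the final estimate
    coincides with batch least squares to ~1e-8.
    """
    X = np.atleast_2d(np.asarray(probe_intentions, dtype=float))
    Y = np.atleast_2d(np.asarray(probe_neural, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and Y.shape[0] > 1:
        X = X.T
    T, n = X.shape
    k = Y.shape[1]
    if Y.shape[0] != T:
        raise ValidationError("probe intention/neural lengths differ")
    if T < k * n:
        raise ValidationError(f"need at least k*n = {k*n} probe samples, got {T}")
    if np.linalg.matrix_rank(X) < n:
        raise ValidationError("rank-deficient probe: intentions do not span the state space")
    P = delta * np.eye(n)
    theta = np.zeros((n, k))
    for t in range(T):
        x = X[t]
        Px = P @ x
        denom = 1.0 + float(x @ Px)
        gain = Px / denom
        theta = theta + np.outer(gain, Y[t] - x @ theta)
        P = P - np.outer(gain, Px)
    return theta.T  # (k, n)


def estimate_encoder_regression(trace: SessionTrace) -> np.ndarray:
    """OLS of neural activity on target position (the intention proxy).

    Assumes the user aims the cursor straight at the target; both sides are
    demeaned (zero-mean convention).  Returns the k x n coefficient matrix.
    """
    k = trace.y.shape[1]
    n = trace.xhat.shape[1]
    tgt = np.column_stack([trace.target] * n) if n > 1 else trace.target[:, None]
    if len(trace.time) < k * n:
        raise ValidationError("trace too short for encoder regression")
    X = tgt - tgt.mean(axis=0)
    if np.linalg.matrix_rank(X) < n or float(np.var(trace.target)) < 1e-12:
        raise ValidationError("degenerate target variance; cannot regress")
    Y = trace.y - trace.y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef.T


def compare_encoders(A_est: np.ndarray, A_opt: np.ndarray) -> float:
    """Pearson correlation of sign-canonicalized, flattened channel weights."""
    a = canonicalize_encoder(A_est).ravel()
    b = canonicalize_encoder(A_opt).ravel()
    if a.shape != b.shape:
        raise ValidationError(f"encoder shapes differ: {a.shape} vs {b.shape}")
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        raise ValidationError("zero-variance encoder weights; correlation undefined")
    return float(sstats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def pinball_metrics(trace: SessionTrace) -> dict:
    """Acquisition counts and timings for a pinball-session trace.

    Inter-acquisition times are the gaps between consecutive acquisitions,
    with the session start as the initial reference.
    """
    if trace.task.kind != "pinball":
        raise ValidationError(f"pinball metrics on a {trace.task.kind!r} trace")
    acq_times = [t for kind, t in trace.events if kind == "acquire"]
    misses = sum(1 for kind, _ in trace.events if kind == "miss")
    duration = trace.task.session_length
    inter = np.diff(np.concatenate([[0.0], acq_times])) if acq_times else np.array([])
    return {
        "targets_acquired": len(acq_times),
        "targets_per_time": len(acq_times) / duration,
        "inter_acquisition_times": inter,
        "misses": misses,
    }


def compare_decoders(traces_motor, traces_precomputed) -> dict:
    """One-sided unpaired t-test on pooled inter-acquisition times.

    H1: the pre-computed decoder acquires faster (smaller gaps).  Accepts
    sequences of pinball SessionTraces or raw arrays of times.
    """
    def _pool(traces):
        if len(traces) and isinstance(traces[0], SessionTrace):
            parts = [pinball_metrics(tr)["inter_acquisition_times"] for tr in traces]
            return np.concatenate([p for p in parts if len(p)]) if parts else np.array([])
        return np.asarray(traces, dtype=float)

    t_mi = _pool(list(traces_motor))
    t_pre = _pool(list(traces_precomputed))
    if len(t_mi) < 2 or len(t_pre) < 2:
        raise ValidationError(
            f"need >= 2 inter-acquisition samples per arm, got {len(t_mi)} and {len(t_pre)}"
        )
    res = sstats.ttest_ind(t_pre, t_mi, equal_var=True, alternative="less")
    return {
        "t_stat": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < 0.05),
        "n_motor": int(len(t_mi)),
        "n_precomputed": int(len(t_pre)),
        "mean_motor": float(t_mi.mean()),
        "mean_precomputed": float(t_pre.mean()),
    }


def cursor_acf(trace, max_lag: int = 30) -> np.ndarray:
    """Sample autocorrelation of the decoded cursor position, lags 0..max_lag.

    Faster falloff = more responsive, less oversmoothed control.
    """
    x = trace.xhat[:, 0] if isinstance(trace, SessionTrace) else np.asarray(trace, dtype=float)
    if len(x) <= max_lag:
        raise ValidationError(f"trace length {len(x)} <= max_lag {max_lag}")
    if float(np.var(x)) < 1e-15:
        raise ValidationError("constant cursor; ACF undefined")
    return _sm_acf(x, nlags=max_lag, fft=True)


# ---------------------------------------------------------------------------
# decoder construction and the end-to-end comparison
# ---------------------------------------------------------------------------


def precompute_decoder(
    case: SignalCase,
    prior: KinematicPrior = DEFAULT_PRIOR,
    lam: float = OPS_LAMBDA,
    seed: int | None = 0,
    config: OptimizerConfig | None = None,
) -> OptimizationResult:
    """Jointly optimized encoder-decoder pair for a signal case.

    Uses the calibration covariance in the joint penalty (the constraint is
    deviation from the native neural covariance) and canonicalizes signs.
    """
    sigma_x2 = float(solve_lyapunov(prior)[0, 0])
    cfg = config or OptimizerConfig(
        lam=lam,
        penalty_kind="joint",
        Sigma_y_cal=case.calibration_sigma_y(sigma_x2),
        seed=seed,
        n_restarts=3,
    )
    res = coordinate_descent(prior, case.noise_cov(), cfg)
    return canonicalize_solution(res)


def motor_imitation_decoder(
    case: SignalCase,
    prior: KinematicPrior = DEFAULT_PRIOR,
    seed: int | None = 0,
    probe_steps: int = 400,
) -> tuple[np.ndarray, SSKFDecoder]:
    """Baseline decoder fit to the user's naive biomimetic control scheme.

    Open-loop probe: the user traces an AR(1) target with horizontal
    movements (no feedback); RLS estimates the encoding; the SSKF for that
    estimate is the motor-imitation decoder.
    """
    rng = np.random.default_rng(seed)
    enc_mi = case.motor_imitation_encoder()
    X = sample_trajectory(prior, probe_steps, rng)
    eps = rng.standard_normal((probe_steps, case.k)) * np.sqrt(case.noise_var)
    Y = X @ enc_mi.A.T + eps
    A_hat = rls_motor_imitation_init(X, Y)
    dec = solve_sskf(Encoder(A_hat, case.noise_cov()), prior)
    return A_hat, dec


def run_case_comparison(
    case_id: int = 1,
    n_sessions: int = 20,
    seed: int = 0,
    lam: float = OPS_LAMBDA,
    prior: KinematicPrior = DEFAULT_PRIOR,
    task: TaskSpec | None = None,
    n_learn_updates: int = 600,
    max_lag: int = 30,
) -> dict:
    """Full two-arm experiment on one signal case.

    For each decoder arm (motor-imitation vs pre-computed): condense the
    free-exploration phase into ``n_learn_updates`` simulated-user learning
    steps from the native motor-imitation encoding, then run ``n_sessions``
    pinball testing sessions with the learned (frozen) encoder.  Returns
    metrics, the acquisition-time t-test, cursor ACFs, and learned-encoder
    correlations against the optimal encoder for each presented decoder.
    """
    task = task or TaskSpec()
    ss = np.random.SeedSequence(seed)
    s_pre, s_mi, *s_sessions = ss.spawn(2 + 2 * n_sessions)
    case, probe_enc = build_signal_case(case_id, prior)
    C = case.noise_cov()
    sigma_x2 = float(solve_lyapunov(prior)[0, 0])
    Sy_cal = case.calibration_sigma_y(sigma_x2)

    opt = precompute_decoder(case, prior, lam, seed=int(s_pre.generate_state(1)[0] % 2**31))
    mi_A_hat, mi_dec = motor_imitation_decoder(
        case, prior, seed=int(s_mi.generate_state(1)[0] % 2**31)
    )

    cfg_user = OptimizerConfig(lam=lam, penalty_kind="joint", Sigma_y_cal=Sy_cal)
    # optimal encoder *for the presented decoder* (what ideal learning attains)
    optimal_for = {
        "precomputed": opt.A,
        "motor": optimize_encoder_given_decoder(
            probe_enc.A, mi_dec.F, mi_dec.G, prior, C, cfg_user
        ).A,
    }
    decoders = {"precomputed": opt.decoder, "motor": mi_dec}

    report: dict = {"case_id": case_id, "lambda": lam, "n_sessions": n_sessions}
    traces: dict[str, list[SessionTrace]] = {}
    for a, arm in enumerate(("motor", "precomputed")):
        dec = decoders[arm]
        user0 = SimulatedUser(
            A=probe_enc.A, update_rule="gradient", lam=lam,
            penalty_kind="joint", Sigma_y_cal=Sy_cal, learning_rate=0.5,
        )
        learned = train_user(user0, dec, prior, C, n_updates=n_learn_updates)
        frozen = replace(learned, update_rule="frozen")
        arm_traces = []
        for i in range(n_sessions):
            sd = int(s_sessions[a * n_sessions + i].generate_state(1)[0] % 2**31)
            arm_traces.append(
                run_closed_loop_session(
                    frozen, dec, case, task, seed=sd, prior=prior, decoder_id=arm
                )
            )
        traces[arm] = arm_traces
        mets = [pinball_metrics(tr) for tr in arm_traces]
        acfs = np.array([cursor_acf(tr, max_lag) for tr in arm_traces])
        report[arm] = {
            "targets_per_time": float(np.mean([m["targets_per_time"] for m in mets])),
            "targets_per_min": float(np.mean([m["targets_per_time"] for m in mets]) * 60),
            "misses": float(np.mean([m["misses"] for m in mets])),
            "acf_mean": acfs.mean(axis=0).tolist(),
            "acf_lag1": float(acfs.mean(axis=0)[1]),
            "G_scalar": float(dec.G[0, 0]),
            "learned_encoder": learned.A.ravel().tolist(),
            "corr_learned_vs_optimal": compare_encoders(learned.A, optimal_for[arm]),
        }
    report["ttest"] = compare_decoders(traces["motor"], traces["precomputed"])
    report["corr_precomputed_learned_vs_optimal"] = report["precomputed"]["corr_learned_vs_optimal"]
    report["_traces"] = traces
    return report
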