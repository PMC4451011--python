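# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## Model and objective

The package works entirely in the zero-mean linear-Gaussian setting.
Intended kinematics `x_t` (dimension n) follow a stationary AR(1) process
with transition `P` (spectral radius < 1) and process noise `Q`; neural
activity `y_t` (k channels) is `A x_t + eps_t` with noise covariance `C`
required strictly positive definite.  Noiseless intuition cases are
exercised through a noise-disabled simulation flag, never through singular
`C`, so every expression involving `C^{-1}` or `(A S A' + C)^{-1}` stays
well-posed.

The decoder class is the steady-state Kalman filter `xhat_t = F y_t +
G xhat_{t-1}`.  For fixed `A` the optimal `(F, G)` follow from the
discrete algebraic Riccati equation; the design problem is to optimize the
encoder too, under a resource penalty, minimizing

    L(A, F, G) = E_ss + lambda * G(A),

where `E_ss` is the stationary mean squared decoding error.  `E_ss` is
evaluated exactly: the coupled process `s_t = (x_t, xhat_t)` is linear
AR(1) with block transition `M = [[P, 0], [F A P, G]]` (block triangular,
so its stability depends only on `P` and `G`, never on `A`), and its
stationary covariance solves a 2n x 2n discrete Lyapunov equation.  The
error is a trace of that covariance.  A term-by-term expansion using the
lagged cross moment `E[x_t xhat_{t-1}'] = P E[x xhat']` is implemented as
a cross-check, and a long-run simulation estimator (`empirical_mse`, with
batch-means standard errors) provides the independent Monte-Carlo check
used in the tests.

## The penalty and the native-covariance question

Two penalties are provided.  `G_snr = tr(C^{-1} A Sigma_x A')` is total
SNR; without it the MMSE problem degenerates to infinitely strong encoding.
`G_joint = tr(Sigma_y^{-1} A Sigma_x A')` is the trace-of-quotient form,
and it comes in two flavours depending on what `Sigma_y` means:

* **model-implied** (`Sigma_y = A Sigma_x A' + C`, the default when no
  calibration covariance is given): the penalty is the fraction of total
  neural variance that is signal, bounded by min(k, n).
* **calibrated** (`Sigma_y` fixed at an empirical/native covariance): the
  penalty charges encoded signal against the channel structure the
  population natively exhibits, i.e. it penalizes encodings whose activity
  deviates from the native covariance.

The distinction matters.  For 1-D control both the SNR penalty and the
model-implied quotient depend on `A` only through the scalar
`Sigma_x A' C^{-1} A` — exactly the quantity the error depends on — so the
objective is flat across channel *allocations* of equal total SNR, and
"encode on the low-noise channels" cannot emerge from the optimization.
With a calibrated `Sigma_y` the cost of a unit of SNR on channel j scales
as `c_j / Sigma_y_jj`, which is what makes quiet channels genuinely cheap.
All pre-computed OPS decoders and the interpretable covariance examples
therefore use the calibrated form, with `Sigma_y` built from the
calibration-phase signal-plus-noise covariance; the model-implied form
remains available and is what the generic optimizer uses when no
calibration covariance exists.

A related caveat: with the model-implied quotient the penalty saturates,
so for some instances the infimum is approached as the encoder gain grows
without bound (the objective value converges while parameters drift).
Multi-seed runs still agree in objective value to high precision — which
is the claim the tests assert — but parameter-space comparisons
(penalty-matched dominance) are only well-posed under the calibrated or
SNR penalties, and are tested there.

## Optimization

Coordinate descent mirrors idealized co-adaptation: an encoder step (the
"user") followed by an exact decoder step (the "machine").

* **Decoder step.**  `scipy.linalg.solve_discrete_are` on the dual
  filtering form, validated by residual; an Eq.-style fixed-point
  iteration (tolerance 1e-12, cap 1e5, symmetrized every step) is the
  fallback and the independent oracle in tests.  This step is the exact
  MSE minimizer over decoders and leaves the penalty untouched, so it
  never increases the objective.
* **Encoder step.**  L-BFGS with the analytic gradient.  The gradient of
  the stationary error with respect to `A` is computed by an adjoint
  Lyapunov solve: with `S = M S M' + W` and error `tr(K S)`, the adjoint
  `Lam = M' Lam M + K` gives the full derivative through both the
  transition (`F A P` block) and the noise-injection terms (`F A` in `W`).
  Central finite differences are the ground truth the implementation is
  validated against (relative error < 1e-5 across penalties).  The step
  is accepted only if the objective decreased, so the per-iteration trace
  is monotone by construction.  Plain Armijo backtracking gradient descent
  is retained as an alternative inner method and as the simulated user's
  single-step learning rule.
* **Initialization and restarts.**  Encoder entries are i.i.d. normal,
  rescaled so the initial joint penalty lands in a mid-band fraction of n
  (a sane order of magnitude); 5 seeded restarts by default, best final
  objective kept, all finals reported.  Stopping: relative objective
  change below 1e-8 or 500 outer iterations.
* **Sign indeterminacy.**  `L(A, F, G) = L(-A, -F, G)` exactly.
  Canonicalization flips encoder columns and decoder rows jointly (and
  conjugates `G`) so each encoder column's largest-magnitude entry is
  positive; the objective is asserted unchanged to 1e-12.  This flip is a
  symmetry only when `P` and `Q` commute with the sign pattern — true for
  the position-only `P ∝ I` priors used throughout — and the routine
  raises if the assertion fails.

The static-decoder ("robust coding") solution `xhat_t = F y_t` alternates
the closed-form Wiener gain with the same encoder step on the marginal
(i.i.d.) objective.  It is the `P -> 0` limit of the full problem, and the
two agree in objective value to ~1e-4 relative at `P = 1e-6 I` in the
tests.

## The OPS emulator

The emulator replaces the human of an online prosthesis simulator with a
simulated user, keeping the rest of the pipeline: intention -> driven
features -> linear mixing into k = 6 channels -> independent Gaussian
channel noise -> decoder -> cursor.

* **Signal cases.**  Three canonical cases map movement features to
  channels one-to-one (case 1: right-hand horizontal/vertical, low noise
  on the vertical channel; case 2: hands-sum and hands-distance, low noise
  on the distance channel; case 3: each hand's horizontal/vertical, low
  noise on the two vertical channels); remaining channels are pure noise.
  High noise equals the signal power of a heavily used channel; low noise
  is one tenth of it (10:1 in power, configurable).
* **Prior.**  Position-only, `P = 0.99 I`, `Q = 0.01 I`, at 10 steps/s —
  transition just under 1 to discourage drift, process noise matched to
  task movement rates.  One time step = 0.1 s.
* **Tasks.**  Pinball: uniform random targets on [-1, 1], halo radius
  0.075 of workspace width, 1.0 s hold to acquire, 15 s timeout, 180 s
  sessions.  Tracing: the target follows the AR(1) prior.  These defaults
  resolve "approximately" protocol values to exact numbers and are exposed
  in the task config.
* **Simulated intention** is the current target position, which makes the
  user model and the regression-based encoder estimator self-consistent.
* **Simulated user.**  Holds `A_user`; learns (when enabled) by a
  line-searched gradient step on the same penalized objective at fixed
  decoder, every 10 steps in closed loop or in a condensed pre-session
  learning phase.  The motor-imitation initial scheme drives only the
  horizontal feature(s).
* **Penalty weight.**  `lambda = 0.01` for the OPS, chosen once so the
  optimized encoder carries roughly the native signal power of a heavily
  used channel (SNR ~ 10 on a low-noise channel, a realistic single-unit
  scale); held fixed across cases and arms.  No automatic Lagrange
  tuning.
* **Decoder arms.**  Motor-imitation: open-loop probe (tracing without
  feedback), recursive least squares encoder estimate (prior-precision
  initialization 1e8; matches batch least squares to 1e-8), then the SSKF
  for that estimate.  Pre-computed: joint optimization with the
  calibrated penalty.  Evaluation: targets per unit time, inter-acquisition
  times compared by one-sided unpaired t-tests (significance 0.05), cursor
  autocorrelation (statsmodels ACF), and learned-vs-optimal encoder
  correlations after sign canonicalization.

## What the synthetic experiments show — and what they do not

The emulator satisfies the modeling assumptions by construction: linear
encoding, Gaussian noise, intention equal to target position, and a user
that literally descends the design objective.  Passing tests therefore
establish internal consistency — the pre-computed decoder is learnable by
an idealized learner and outperforms the motor-imitation baseline *within
the model* — not behavioral fidelity of human learning, nonstationary
neural statistics, or model mismatch in real recordings.  The gradient
user is an idealization; human exploration has no specified algorithm.
Session counts (20 per arm) and problem sizes (k up to 200 for optimizer
invariance, 1e6-step simulations for Monte-Carlo checks) were chosen as
the package's own desk-scale study conditions.

## Numerical notes and degenerate inputs

* Covariances are symmetrized on construction; asymmetry beyond 1e-12
  relative is rejected; eigenvalues in [-1e-10, 0) are clipped.
* Lyapunov equations are solved in closed form (vectorized); residuals
  are validated (1e-9 relative) and a matrix-recursion oracle backs the
  tests.  AR(1) sampling and long simulations use a modal decomposition so
  each mode is a scalar recursion (`scipy.signal.lfilter`), with a plain
  loop fallback for defective transitions.
* An unstable `G` (spectral radius >= 1) raises an explicit instability
  error from the moments code; a diverging closed-loop cursor (|xhat| >
  1e3) aborts the session with a diagnostic.
* Zero-variance cursors, degenerate targets, rank-deficient probes and
  insufficient acquisition samples all raise explicit validation errors
  rather than returning NaN.
* t-tests use the pooled equal-variance form; two identical samples give
  the p = 0.5 null boundary, and zero-variance separated samples give
  p = 0 (infinite t), both exercised in tests.

## Known limitations

Means are never modeled (zero-mean convention throughout).  Structured
priors (velocity blocks) are accepted but not specially supported; all
shipped experiments use `P ∝ I`.  The OPS tasks are 1-D, as in the
motivating experiments, though the core machinery is n-dimensional.
Nonlinear observation models (Poisson spiking, signal-dependent noise,
activity with its own dynamics) are out of scope.
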