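"""Closed-loop OPS emulator: signal cases, sessions, learning, metrics."""
from dataclasses import replace

import numpy as np
import pytest

from coadapt.encoding import Encoder
from coadapt.exceptions import ValidationError
from coadapt.objective import full_objective, mse_objective
from coadapt.ops import (
    DEFAULT_PRIOR,
    OPS_LAMBDA,
    SessionTrace,
    SimulatedUser,
    TaskSpec,
    build_signal_case,
    compare_decoders,
    compare_encoders,
    cursor_acf,
    estimate_encoder_regression,
    motor_imitation_decoder,
    pinball_metrics,
    precompute_decoder,
    rls_motor_imitation_init,
    run_closed_loop_session,
    train_user,
    user_learning_update,
)
from coadapt.sskf import solve_sskf
from coadapt.statespace import KinematicPrior, sample_trajectory, solve_lyapunov


class TestSignalCases:
    @pytest.mark.parametrize("case_id", [1, 2, 3])
    def test_six_channels_with_positive_noise(self, case_id):
        case, probe = build_signal_case(case_id)
        assert case.k == 6
        assert np.all(case.noise_var > 0)
        assert probe.A.shape == (6, 1)

    def test_case1_single_low_noise_vertical_channel(self):
        case, _ = build_signal_case(1)
        low = np.flatnonzero(case.noise_var == case.noise_var.min())
        assert list(low) == [1]  # the vertical-feature channel
        assert case.feature_names[1] == "rhand_vert"

    def test_case2_hands_distance_channel_unique_minimum(self):
        case, _ = build_signal_case(2)
        low = np.flatnonzero(case.noise_var == case.noise_var.min())
        assert list(low) == [1]
        assert case.feature_names[1] == "hands_distance"

    def test_case3_low_noise_on_both_vertical_channels(self):
        case, _ = build_signal_case(3)
        low = np.flatnonzero(case.noise_var == case.noise_var.min())
        assert list(low) == [1, 3]

    def test_unknown_case_rejected(self):
        with pytest.raises(ValidationError):
            build_signal_case(4)

    def test_motor_imitation_drives_high_noise_channels_only(self):
        for cid in (1, 2, 3):
            case, probe = build_signal_case(cid)
            driven = np.flatnonzero(probe.A.ravel() != 0)
            assert set(driven).isdisjoint(case.low_noise_channels)


class TestClosedLoopSession:
    def test_determinism(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        user = SimulatedUser(A=probe.A)
        task = TaskSpec(session_length=30.0)
        a = run_closed_loop_session(user, dec, case, task, seed=42)
        b = run_closed_loop_session(user, dec, case, task, seed=42)
        np.testing.assert_array_equal(a.xhat, b.xhat)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.events == b.events

    def test_noiseless_convergence_to_constant_target(self):
        """With noise disabled and a matched optimal pair, the cursor follows
        a deterministic linear recursion converging toward the target."""
        case, _ = build_signal_case(1)
        opt = precompute_decoder(case, seed=0)
        user = SimulatedUser(A=opt.A)
        task = TaskSpec(session_length=30.0, timeout=25.0)
        tr = run_closed_loop_session(user, opt.decoder, case, task, seed=1, noise=False)
        tgt = tr.target[0]
        first_event = int(tr.events[0][1] * task.sample_rate) if tr.events else 50
        err = np.abs(tr.xhat[: min(50, first_event), 0] - tgt)
        assert len(err) >= 5
        assert np.all(np.diff(err) <= 1e-12)  # monotone geometric approach

    def test_frozen_tracing_error_matches_analytic_mse(self):
        """A long frozen-user tracing session reproduces the analytic
        steady-state MSE within 3 batch-means standard errors."""
        case, probe = build_signal_case(1)
        C = case.noise_cov()
        dec = solve_sskf(Encoder(probe.A, C), DEFAULT_PRIOR)
        user = SimulatedUser(A=probe.A)
        task = TaskSpec(kind="tracing", session_length=10_000.0)
        tr = run_closed_loop_session(user, dec, case, task, seed=5)
        sq = (tr.xhat[:, 0] - tr.x[:, 0]) ** 2
        batches = sq[: (len(sq) // 100) * 100].reshape(100, -1).mean(axis=1)
        se = batches.std(ddof=1) / 10
        analytic = mse_objective(probe.A, dec.F, dec.G, DEFAULT_PRIOR, C)
        assert abs(sq.mean() - analytic) < 3 * se

    def test_csv_roundtrip_preserves_metrics(self, tmp_path):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        user = SimulatedUser(A=probe.A)
        tr = run_closed_loop_session(user, dec, case, TaskSpec(session_length=60.0), seed=3)
        tr.to_csv(tmp_path / "t.csv")
        back = SessionTrace.from_csv(tmp_path / "t.csv")
        m1, m2 = pinball_metrics(tr), pinball_metrics(back)
        assert m1["targets_acquired"] == m2["targets_acquired"]
        assert m1["misses"] == m2["misses"]
        np.testing.assert_allclose(back.xhat, tr.xhat, atol=1e-12)


class TestUserLearning:
    def test_frozen_and_zero_rate_are_identity(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        u1 = SimulatedUser(A=probe.A, update_rule="frozen")
        assert user_learning_update(u1, dec, DEFAULT_PRIOR, case.noise_cov()) is u1
        u2 = SimulatedUser(A=probe.A, update_rule="gradient", learning_rate=0.0)
        assert user_learning_update(u2, dec, DEFAULT_PRIOR, case.noise_cov()) is u2

    def test_update_never_increases_objective(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        C = case.noise_cov()
        sy = case.calibration_sigma_y(float(solve_lyapunov(DEFAULT_PRIOR)[0, 0]))
        u = SimulatedUser(
            A=probe.A, update_rule="gradient", learning_rate=0.5, lam=OPS_LAMBDA, Sigma_y_cal=sy
        )
        for _ in range(20):
            f0 = full_objective(u.A, dec.F, dec.G, DEFAULT_PRIOR, C, u.lam, u.penalty_kind, sy).total
            u = user_learning_update(u, dec, DEFAULT_PRIOR, C)
            f1 = full_objective(u.A, dec.F, dec.G, DEFAULT_PRIOR, C, u.lam, u.penalty_kind, sy).total
            assert f1 <= f0

    def test_already_optimal_user_stays_put(self):
        case, _ = build_signal_case(1)
        opt = precompute_decoder(case, seed=0)
        sy = case.calibration_sigma_y(float(solve_lyapunov(DEFAULT_PRIOR)[0, 0]))
        u = SimulatedUser(
            A=opt.A, update_rule="gradient", learning_rate=0.5, lam=OPS_LAMBDA, Sigma_y_cal=sy
        )
        u2 = train_user(u, opt.decoder, DEFAULT_PRIOR, case.noise_cov(), n_updates=5)
        assert np.abs(u2.A - opt.A).max() < 1e-4

    def test_gradient_user_learns_optimal_encoder(self):
        """Starting from the naive motor-imitation scheme, repeated updates
        against the fixed pre-computed decoder approach the optimal encoder
        (canonicalized correlation > 0.95 within 1e3 updates)."""
        case, probe = build_signal_case(1)
        opt = precompute_decoder(case, seed=0)
        sy = case.calibration_sigma_y(float(solve_lyapunov(DEFAULT_PRIOR)[0, 0]))
        u = SimulatedUser(
            A=probe.A, update_rule="gradient", learning_rate=0.5, lam=OPS_LAMBDA, Sigma_y_cal=sy
        )
        learned = train_user(u, opt.decoder, DEFAULT_PRIOR, case.noise_cov(), n_updates=1000)
        assert compare_encoders(learned.A, opt.A) > 0.95


class TestCase3Comparison:
    def test_precomputed_beats_motor_imitation_on_case3(self):
        """The two-arm performance gap also holds on signal case 3 (both
        hands' vertical channels quiet): more targets per unit time for the
        pre-computed decoder, significant on inter-acquisition times."""
        from coadapt.ops import run_case_comparison

        rep = run_case_comparison(case_id=3, n_sessions=8, seed=0)
        assert rep["precomputed"]["targets_per_time"] > rep["motor"]["targets_per_time"]
        assert rep["ttest"]["p_value"] < 0.05


class TestEncoderEstimation:
    def test_rls_recovers_noiseless_encoding_exactly(self, rng):
        A = rng.standard_normal((6, 1))
        X = rng.standard_normal((50, 1))
        Y = X @ A.T
        A_hat = rls_motor_imitation_init(X, Y)
        np.testing.assert_allclose(A_hat, A, atol=1e-6)

    def test_rls_matches_batch_least_squares(self, rng):
        X = rng.standard_normal((200, 2))
        Y = rng.standard_normal((200, 5))
        A_rls = rls_motor_imitation_init(X, Y)
        A_batch, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert np.abs(A_rls - A_batch.T).max() < 1e-8

    def test_rls_insufficient_or_degenerate_probe_rejected(self, rng):
        with pytest.raises(ValidationError):
            rls_motor_imitation_init(rng.standard_normal((3, 1)), rng.standard_normal((3, 6)))
        X = np.zeros((40, 2))
        X[:, 0] = rng.standard_normal(40)  # second dimension never excited
        with pytest.raises(ValidationError):
            rls_motor_imitation_init(X, rng.standard_normal((40, 6)))

    def test_regression_recovers_frozen_user_noiselessly(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        user = SimulatedUser(A=probe.A)
        tr = run_closed_loop_session(
            user, dec, case, TaskSpec(session_length=60.0), seed=2, noise=False
        )
        A_hat = estimate_encoder_regression(tr)
        np.testing.assert_allclose(A_hat, probe.A, atol=1e-10)

    def test_regression_consistent_under_noise(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        user = SimulatedUser(A=probe.A)
        tr = run_closed_loop_session(
            user, dec, case, TaskSpec(session_length=10_000.0), seed=4
        )
        A_hat = estimate_encoder_regression(tr)
        assert np.abs(A_hat - probe.A).max() < 0.05 * max(1.0, np.abs(probe.A).max())

    def test_shuffled_target_gives_near_zero_coefficients(self):
        case, probe = build_signal_case(1)
        dec = motor_imitation_decoder(case, seed=0)[1]
        user = SimulatedUser(A=probe.A)
        tr = run_closed_loop_session(user, dec, case, TaskSpec(session_length=600.0), seed=6)
        rng = np.random.default_rng(0)
        tr_shuf = replace_target(tr, rng.permutation(tr.target))
        A_hat = estimate_encoder_regression(tr_shuf)
        assert np.abs(A_hat).max() < 0.1

    def test_compare_encoders_symmetries(self, rng):
        A = rng.standard_normal((6, 1))
        assert compare_encoders(A, A) == pytest.approx(1.0)
        assert compare_encoders(A, -A) == pytest.approx(1.0)  # canonicalized first
        rs = [abs(compare_encoders(A, rng.standard_normal((6, 1)))) for _ in range(50)]
        assert np.median(rs) < 0.6

    def test_compare_encoders_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            compare_encoders(np.ones((4, 1)), np.ones((4, 1)))


def replace_target(tr: SessionTrace, new_target: np.ndarray) -> SessionTrace:
    return SessionTrace(
        time=tr.time, target=new_target, x=tr.x, y=tr.y, xhat=tr.xhat,
        in_halo=tr.in_halo, events=tr.events, seed=tr.seed,
        decoder_id=tr.decoder_id, task=tr.task, case_id=tr.case_id,
    )


def _fixture_trace(events, session_length=60.0, T=600, kind="pinball", xhat=None):
    task = TaskSpec(kind=kind, session_length=session_length, timeout=15.0, hold_time=1.0)
    rng = np.random.default_rng(0)
    xhat = rng.standard_normal((T, 1)) if xhat is None else xhat
    return SessionTrace(
        time=np.arange(T) / 10.0,
        target=np.zeros(T),
        x=np.zeros((T, 1)),
        y=rng.standard_normal((T, 2)),
        xhat=xhat,
        in_halo=np.zeros(T, dtype=bool),
        events=events,
        seed=0,
        decoder_id="fixture",
        task=task,
    )


class TestMetrics:
    def test_pinball_metrics_hand_computed_fixture(self):
        tr = _fixture_trace([("acquire", 30.0), ("acquire", 60.0)])
        m = pinball_metrics(tr)
        assert m["targets_acquired"] == 2
        np.testing.assert_allclose(m["inter_acquisition_times"], [30.0, 30.0])
        assert m["targets_per_time"] == pytest.approx(2 / 60.0)  # 2 per minute
        assert m["misses"] == 0

    def test_pinball_metrics_no_acquisitions(self):
        tr = _fixture_trace([("miss", 15.0), ("miss", 30.0)])
        m = pinball_metrics(tr)
        assert m["targets_acquired"] == 0
        assert m["targets_per_time"] == 0.0
        assert m["misses"] == 2

    def test_wrong_task_kind_rejected(self):
        tr = _fixture_trace([], kind="tracing")
        with pytest.raises(ValidationError):
            pinball_metrics(tr)

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_ttest_textbook_oracle(self):
        """Pre-computed arm uniformly faster: one-sided p below 0.05 (the
        degenerate zero-variance case gives t = -inf, p = 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rep = compare_decoders([20.0, 20.0, 20.0], [10.0, 10.0, 10.0])
        assert rep["p_value"] < 0.05 and rep["significant"]
        rep2 = compare_decoders([18.0, 20.0, 22.0], [9.0, 10.0, 11.0])
        # textbook pooled two-sample t: t = (10-20)/sqrt(s2p*(2/3)), df=4
        from scipy import stats

        s2p = (np.var([18, 20, 22], ddof=1) + np.var([9, 10, 11], ddof=1)) / 2
        t_expect = (10 - 20) / np.sqrt(s2p * (2 / 3))
        assert rep2["t_stat"] == pytest.approx(t_expect)
        assert rep2["p_value"] == pytest.approx(stats.t.cdf(t_expect, 4))

    def test_ttest_identical_samples_at_null_boundary(self):
        rep = compare_decoders([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep["p_value"] == pytest.approx(0.5)
        assert not rep["significant"]

    def test_ttest_swap_reverses_tail(self):
        a, b = [5.0, 6.0, 7.0], [6.0, 7.0, 9.0]
        p1 = compare_decoders(a, b)["p_value"]
        p2 = compare_decoders(b, a)["p_value"]
        assert p1 + p2 == pytest.approx(1.0)

    def test_ttest_insufficient_samples_rejected(self):
        with pytest.raises(ValidationError):
            compare_decoders([1.0], [1.0, 2.0])


class TestCursorACF:
    def test_lag_zero_is_one(self):
        tr = _fixture_trace([])
        acf = cursor_acf(tr, max_lag=5)
        assert acf[0] == pytest.approx(1.0)

    def test_ar1_cursor_matches_closed_form(self):
        """A synthetic AR(1) cursor with coefficient 0.6 has ACF 0.6^tau."""
        g = 0.6
        prior = KinematicPrior(np.array([[g]]), np.array([[1 - g**2]]))
        x = sample_trajectory(prior, 100_000, seed=8)[:, 0]
        acf = cursor_acf(x, max_lag=10)
        taus = np.arange(11)
        assert np.abs(acf - g**taus).max() < 0.02

    def test_white_noise_acf_within_independence_bound(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100_000)
        acf = cursor_acf(x, max_lag=10)
        assert np.abs(acf[1:]).max() < 3 / np.sqrt(len(x))

    def test_constant_cursor_rejected(self):
        tr = _fixture_trace([], xhat=np.ones((600, 1)))
        with pytest.raises(ValidationError):
            cursor_acf(tr)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            cursor_acf(np.arange(10.0), max_lag=20)
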