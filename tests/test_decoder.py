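"""CCA frequency recognition and the accumulation/threshold decision rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import linalg as sla
from scipy.optimize import minimize

from ssvep_speller import (
    Command,
    CorrelationProfile,
    DecisionConfig,
    DecisionState,
    ReferenceSet,
    SimConfig,
    canonical_correlation,
    classify_frequency,
    correlation_profile,
    decision_update,
    map_command_to_frequency,
    map_frequency_to_command,
    reference_matrix,
    run_decoder,
    simulate_ssvep_epoch,
)
from ssvep_speller.decoder import batch_correlation_profiles
from ssvep_speller.preprocess import FilterChain, SignalWindow, apply_filter_chain, detrend

FS = 200.0


def cca_eig_oracle(X, Y):
    """Independent leading-correlation solver: generalized eigenproblem
    Sxy Syy^-1 Syx w = rho^2 Sxx w (dense eigh route)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc
    syy = Yc.T @ Yc
    sxy = Xc.T @ Yc
    m = sxy @ np.linalg.solve(syy, sxy.T)
    vals = sla.eigh(m, sxx, eigvals_only=True)
    return float(np.sqrt(np.clip(vals[-1], 0.0, 1.0)))


def cca_direct_oracle(X, Y, seed=0):
    """Brute-force maximization of |corr(X wx, Y wy)| over the weights."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def neg_corr(w):
        wx, wy = w[: X.shape[1]], w[X.shape[1] :]
        a, b = Xc @ wx, Yc @ wy
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            return 0.0
        return -abs(float(a @ b) / (na * nb))

    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(8):
        w0 = rng.standard_normal(X.shape[1] + Y.shape[1])
        res = minimize(neg_corr, w0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = max(best, -res.fun)
    return best


class TestReferenceMatrix:
    def test_first_row_is_sin0_cos0(self):
        y = reference_matrix(12.0, FS, 300)
        assert y.shape == (300, 2)
        assert np.allclose(y[0], [0.0, 1.0])

    def test_columns_orthogonal_over_integer_cycles(self):
        # 10 Hz over 1.5 s = 15 full cycles
        y = reference_matrix(10.0, FS, 300)
        assert abs(y[:, 0] @ y[:, 1]) / 300 < 1e-10

    def test_second_harmonic_oscillates_at_double_frequency(self):
        y = reference_matrix(6.67, FS, 300, n_harmonics=2)
        zc = int(np.sum(np.diff(np.sign(y[:, 2])) != 0))
        expected = 2 * int(13.34 * 1.5)
        assert abs(zc - expected) <= 1

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            reference_matrix(60.0, FS, 300, n_harmonics=2)


class TestCanonicalCorrelation:
    def test_perfect_correlation_with_own_column(self):
        y = reference_matrix(10.0, FS, 300)
        res = canonical_correlation(y[:, :1], y)
        assert abs(res.rho - 1.0) < 1e-9

    def test_rho_bound_and_weights_consistency(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 2))
        Y = reference_matrix(7.5, FS, 300)
        res = canonical_correlation(X, Y)
        assert 0.0 <= res.rho <= 1.0
        a = (X - X.mean(0)) @ res.w_x
        b = (Y - Y.mean(0)) @ res.w_y
        r = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert abs(r - res.rho) < 1e-9

    def test_invariance_under_invertible_mixing(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 2))
        Y = reference_matrix(10.0, FS, 300)
        A = np.array([[1.3, -0.4], [0.2, 0.9]])
        r1 = canonical_correlation(X, Y).rho
        r2 = canonical_correlation(X @ A, Y).rho
        assert abs(r1 - r2) < 1e-9

    def test_agrees_with_generalized_eigen_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = rng.integers(20, 50)
            c = rng.integers(1, 4)
            m = rng.integers(1, 4)
            X = rng.standard_normal((n, c))
            Y = rng.standard_normal((n, m))
            assert abs(canonical_correlation(X, Y).rho - cca_eig_oracle(X, Y)) < 1e-6

    def test_agrees_with_direct_optimization_oracle(self):
        rng = np.random.default_rng(4)
        for seed in range(3):
            X = rng.standard_normal((40, 2))
            Y = rng.standard_normal((40, 2))
            assert abs(canonical_correlation(X, Y).rho - cca_direct_oracle(X, Y, seed)) < 1e-6

    def test_rank_deficient_input_does_not_crash(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x])  # duplicated column
        Y = reference_matrix(10.0, FS, 100)
        res = canonical_correlation(X, Y)
        assert 0.0 <= res.rho <= 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            canonical_correlation(np.zeros((4, 2)), np.zeros((4, 3)))


class TestCorrelationProfile:
    def test_high_snr_epoch_peaks_at_attended_frequency(self):
        refs = ReferenceSet(300)
        chain = FilterChain()
        for seed in range(10):
            ep = simulate_ssvep_epoch(SimConfig(seed=seed).with_snr(3.0), 10.0, 3.0)
            filt, _ = apply_filter_chain(ep.samples, chain, FS)
            w = detrend(SignalWindow(filt[-300:], FS))
            prof = correlation_profile(w, refs)
            assert classify_frequency(prof) == 10.0

    def test_single_channel_max_equals_joint(self):
        rng = np.random.default_rng(0)
        refs = ReferenceSet(300)
        w = SignalWindow(rng.standard_normal((300, 1)), FS)
        a = correlation_profile(w, refs, mode="per_channel_max").rho_by_freq
        b = correlation_profile(w, refs, mode="joint").rho_by_freq
        assert np.max(np.abs(a - b)) < 1e-9

    def test_length_mismatch_rejected(self):
        refs = ReferenceSet(300)
        with pytest.raises(ValueError):
            correlation_profile(SignalWindow(np.zeros((200, 2)), FS), refs)

    def test_batch_path_matches_per_window_path(self):
        """The vectorized stream decoder equals windowed CCA exactly."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((900, 2))
        refs = ReferenceSet(300)
        batch = batch_correlation_profiles(x, FS, refs)
        for i in [0, 17, 60]:
            w = detrend(SignalWindow(x[i * 10 : i * 10 + 300], FS))
            ref_prof = correlation_profile(w, refs)
            assert np.max(np.abs(ref_prof.rho_by_freq - batch[i].rho_by_freq)) < 1e-9

    def test_accuracy_monotone_in_snr(self):
        """Single-window classification accuracy is non-decreasing in SNR
        (2-point slack over 40 epochs/level)."""
        refs = ReferenceSet(300)
        chain = FilterChain()
        acc = []
        for snr in [0.5, 1.5, 3.0]:
            hits = 0
            for seed in range(40):
                ep = simulate_ssvep_epoch(SimConfig(seed=seed).with_snr(snr), 7.5, 2.0)
                filt, _ = apply_filter_chain(ep.samples, chain, FS)
                prof = correlation_profile(detrend(SignalWindow(filt[-300:], FS)), refs)
                hits += classify_frequency(prof) == 7.5
            acc.append(hits / 40)
        assert acc[1] >= acc[0] - 0.05 and acc[2] >= acc[1] - 0.05
        assert acc[2] > acc[0]


class TestClassifyFrequency:
    def test_argmax_and_tie_break(self):
        p = CorrelationProfile(0.0, [0.1, 0.2, 0.6, 0.2, 0.1])
        assert classify_frequency(p) == 8.57
        tie = CorrelationProfile(0.0, [0.5, 0.5, 0.1, 0.1, 0.1])
        assert classify_frequency(tie) == 6.67

    def test_matches_exhaustive_comparison(self):
        rng = np.random.default_rng(0)
        freqs = (6.67, 7.5, 8.57, 10.0, 12.0)
        for _ in range(20):
            rho = rng.uniform(0, 1, 5)
            p = CorrelationProfile(0.0, rho)
            best = max(range(5), key=lambda k: (rho[k], -k))
            assert classify_frequency(p) == freqs[best]


class TestCommandMapping:
    def test_fixed_bijection(self):
        assert map_frequency_to_command(6.67) == Command.UP
        assert map_frequency_to_command(12.0) == Command.SELECT
        for cmd in (Command.UP, Command.RIGHT, Command.DOWN, Command.LEFT, Command.SELECT):
            assert map_frequency_to_command(map_command_to_frequency(cmd)) == cmd

    def test_unknown_frequency_rejected(self):
        with pytest.raises(ValueError):
            map_frequency_to_command(9.0)


def profiles_from_matrix(rho, hop=0.05, t0=1.5):
    return [CorrelationProfile(t0 + i * hop, row) for i, row in enumerate(rho)]


class TestDecisionRule:
    def test_single_valid_candidate_emits_once_then_refractory(self):
        """12 Hz at rho 0.4 in 12/30 updates -> SELECT once; persisting
        correlations during the 1 s ignore interval emit nothing."""
        rho = np.full((90, 5), 0.1)
        rho[::2, 4] = 0.4  # 12 Hz above threshold in 15 of each 30 updates
        state = DecisionState(DecisionConfig())
        emitted = []
        for p in profiles_from_matrix(rho):
            cmd = decision_update(state, p)
            if cmd is not None:
                emitted.append((p.t_s, cmd))
        assert emitted[0][1] == Command.SELECT
        ts = [t for t, _ in emitted]
        assert all(b - a >= 1.0 - 1e-9 for a, b in zip(ts, ts[1:]))

    def test_all_below_threshold_emits_nothing(self):
        rho = np.full((30, 5), 0.2)
        assert run_decoder(profiles_from_matrix(rho)) == []

    def test_below_consistency_count_emits_nothing(self):
        rho = np.full((30, 5), 0.1)
        rho[:8, 4] = 0.9  # only 8 of 30 hits < required 9
        assert run_decoder(profiles_from_matrix(rho)) == []

    def test_nine_of_thirty_is_sufficient(self):
        rho = np.full((30, 5), 0.1)
        rho[:9, 4] = 0.4
        ems = run_decoder(profiles_from_matrix(rho))
        assert [e.command for e in ems] == [Command.SELECT]

    def test_highest_mean_wins_over_higher_count(self):
        """10 Hz: mean 0.35 in 10 hits vs 12 Hz: mean 0.30 in 11 hits -> LEFT."""
        rho = np.full((30, 5), 0.1)
        rho[:10, 3] = 0.35
        rho[:11, 4] = 0.30
        ems = run_decoder(profiles_from_matrix(rho))
        assert [e.command for e in ems] == [Command.LEFT]
        assert abs(ems[0].mean_rho - 0.35) < 1e-12

    def test_tie_breaks_to_lowest_frequency(self):
        rho = np.full((30, 5), 0.1)
        rho[:10, 0] = 0.4
        rho[:10, 2] = 0.4
        ems = run_decoder(profiles_from_matrix(rho))
        assert [e.command for e in ems] == [Command.UP]

    def test_out_of_order_profiles_rejected(self):
        state = DecisionState()
        decision_update(state, CorrelationProfile(1.0, [0.1] * 5))
        with pytest.raises(ValueError):
            decision_update(state, CorrelationProfile(0.5, [0.1] * 5))

    def test_run_length_counting_is_stricter(self):
        rho = np.full((30, 5), 0.1)
        rho[::3, 4] = 0.9  # 10 scattered hits, longest run = 1
        assert run_decoder(profiles_from_matrix(rho), DecisionConfig(counting="run")) == []
        assert len(run_decoder(profiles_from_matrix(rho), DecisionConfig(counting="window"))) == 1
        consec = np.full((30, 5), 0.1)
        consec[5:14, 4] = 0.9  # 9 consecutive hits
        assert len(run_decoder(profiles_from_matrix(consec), DecisionConfig(counting="run"))) == 1

    @given(seed=st.integers(0, 200))
    def test_rate_limit_on_arbitrary_streams(self, seed):
        """Emission timestamps are never closer than the ignore interval."""
        rng = np.random.default_rng(seed)
        rho = rng.uniform(0, 0.6, size=(120, 5))
        ems = run_decoder(profiles_from_matrix(rho))
        ts = [e.t_s for e in ems]
        assert all(b - a >= 1.0 - 1e-9 for a, b in zip(ts, ts[1:]))
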