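"""Design matrices, trial selection, OLS, and the sequential fitting chain."""

import numpy as np
import pytest

import kernelvar as kv
from kernelvar.glm import ResidualTrial, stack_interaction_design
from kernelvar.core import lag_grid


class TestBaselineCorrect:
    def test_constant_trace_becomes_zero(self, grid):
        assert np.allclose(kv.baseline_correct(np.full(26, 3.7), grid), 0.0)

    def test_zero_mean_baseline_unchanged(self, grid):
        y = np.zeros(26)
        y[0], y[1], y[2] = 1.0, -2.0, 1.0   # baseline bins sum to zero
        y[10] = 5.0
        assert np.allclose(kv.baseline_correct(y, grid), y)

    def test_ramp_shifts_by_baseline_mean(self, grid):
        y = grid.times.copy()
        corrected = kv.baseline_correct(y, grid)
        # baseline bins hold -1.0, -0.9, -0.8 -> mean -0.9
        assert np.allclose(corrected, y + 0.9)
        assert abs(corrected[:3].mean()) < 1e-12

    def test_window_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            kv.baseline_correct(np.zeros(26), grid, window=(-2.0, -1.5))


def _trial(grid, e_times=(), b_times=()):
    n = grid.n_bins
    x_stim = np.zeros(n); x_stim[grid.stim_bin] = 1
    x_e = np.zeros(n); x_b = np.zeros(n)
    for t in e_times:
        x_e[grid.bin_of(t)] = 1
    for t in b_times:
        x_b[grid.bin_of(t)] = 1
    return kv.TrialRecord(x_stim=x_stim, x_e=x_e, x_b=x_b,
                          y=np.zeros(n), pupil_increase=0.1, gain=1.0)


class TestSelectTrials:
    def test_zero_event_dataset_is_all_clean(self, grid):
        trials = [_trial(grid) for _ in range(5)]
        sel = kv.select_trials(trials, grid)
        assert sel.clean_ids == list(range(5))
        assert not sel.discarded_ids

    def test_baseline_saccade_is_discarded(self, grid):
        sel = kv.select_trials([_trial(grid, e_times=[-0.9])], grid)
        assert sel.discarded_ids == [0]
        assert not sel.clean_ids

    def test_constructed_ten_trial_partition(self, grid):
        """Hand-enumerated fixture covering every selection rule."""
        trials = [
            _trial(grid),                                    # 0 clean
            _trial(grid, e_times=[0.5]),                     # 1 isolated saccade
            _trial(grid, b_times=[0.3]),                     # 2 isolated body
            _trial(grid, e_times=[0.2], b_times=[0.4]),      # 3 interaction
            _trial(grid, e_times=[-0.9]),                    # 4 discarded
            _trial(grid, b_times=[-1.0]),                    # 5 discarded
            _trial(grid, e_times=[0.1, 1.0]),                # 6 two saccades: none
            _trial(grid, e_times=[-0.5], b_times=[1.0]),     # 7 interaction, and
            #   both events isolated from each other beyond the 1 s window
            _trial(grid),                                    # 8 clean
            _trial(grid, e_times=[0.0], b_times=[0.1, 1.2]), # 9 interaction
        ]
        sel = kv.select_trials(trials, grid, isolation_window=1.0)
        assert sel.clean_ids == [0, 8]
        assert sel.discarded_ids == [4, 5]
        assert sel.interaction_ids == [3, 7, 9]
        assert sel.isolated_saccade_ids == [1, 7]
        assert sel.isolated_body_ids == [2, 7]


class TestDesign1D:
    def test_single_event_places_ones_at_lagged_rows(self, grid):
        x = np.zeros(26); x[10] = 1
        dm = kv.build_design_1d(x, (0.0, 0.2), grid)
        assert dm.values.sum() == 3
        for j, lag in enumerate(dm.column_index):
            row = 10 + int(round(lag / grid.dt))
            assert dm.values[row, j] == 1

    def test_no_events_gives_zero_matrix(self, grid):
        dm = kv.build_design_1d(np.zeros(26), (-0.3, 2.0), grid)
        assert dm.values.sum() == 0
        assert dm.n_cols == 24

    def test_design_times_kernel_equals_brute_force_convolution(self, grid):
        """X @ k must equal the direct double loop over events and lags."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = (rng.uniform(size=26) < 0.15).astype(float)
            k = rng.normal(size=24)
            lag_bins = np.round(lag_grid((-0.3, 2.0), grid.dt) / grid.dt).astype(int)
            expected = np.zeros(26)
            for t0 in np.flatnonzero(x):
                for lb, w in zip(lag_bins, k):
                    if 0 <= t0 + lb < 26:
                        expected[t0 + lb] += w
            dm = kv.build_design_1d(x, (-0.3, 2.0), grid)
            assert np.allclose(dm.values @ k, expected)

    def test_overlapping_events_column_sums(self, grid):
        x = np.zeros(26); x[5] = 1; x[6] = 1
        dm = kv.build_design_1d(x, (0.0, 0.5), grid)
        # each admissible lag is hit once per event that stays in range
        lag_bins = [int(round(l / grid.dt)) for l in dm.column_index]
        for j, lb in enumerate(lag_bins):
            expected = sum(1 for t0 in (5, 6) if 0 <= t0 + lb < 26)
            assert dm.values[:, j].sum() == expected


class TestDesign2D:
    def test_one_pair_hits_single_diagonal(self, grid):
        x_b = np.zeros(26); x_b[8] = 1
        x_e = np.zeros(26); x_e[11] = 1
        dm = kv.build_design_2d(x_b, x_e, grid=grid)
        nz = np.flatnonzero(np.asarray(dm.values).sum(axis=0))
        for col in nz:
            tb, te = dm.column_index[col]
            # tau_b - tau_e must equal the event-time difference (s - b)
            assert (tb - te) == pytest.approx((11 - 8) * grid.dt)

    def test_empty_saccade_train_gives_zero_design(self, grid):
        x_b = np.zeros(26); x_b[8] = 1
        dm = kv.build_design_2d(x_b, np.zeros(26), grid=grid)
        assert np.asarray(dm.values).sum() == 0

    def test_matches_brute_force_triple_loop(self, grid):
        rng = np.random.default_rng(8)
        lag_bins = np.round(
            lag_grid(kv.INTERACTION_WINDOW, grid.dt) / grid.dt).astype(int)
        d = lag_bins.size
        for _ in range(4):
            x_b = (rng.uniform(size=26) < 0.1).astype(float)
            x_e = (rng.uniform(size=26) < 0.1).astype(float)
            expected = np.zeros((26, d * d))
            for t in range(26):
                for i, lb in enumerate(lag_bins):
                    for j, le in enumerate(lag_bins):
                        tb, te = t - lb, t - le
                        if 0 <= tb < 26 and 0 <= te < 26:
                            expected[t, i * d + j] = x_b[tb] * x_e[te]
            dm = kv.build_design_2d(x_b, x_e, grid=grid)
            assert np.array_equal(np.asarray(dm.values), expected)

    def test_two_pairs_same_lag_double_row_coverage(self, grid):
        x_b = np.zeros(26); x_b[[5, 15]] = 1
        x_e = np.zeros(26); x_e[[7, 17]] = 1
        one = kv.build_design_2d(
            np.eye(26)[5] * 0 + np.where(np.arange(26) == 5, 1.0, 0.0),
            np.where(np.arange(26) == 7, 1.0, 0.0), grid=grid)
        two = kv.build_design_2d(x_b, x_e, grid=grid)
        # on-diagonal columns (tau_b - tau_e = 2 bins) are hit in twice as
        # many rows when a second same-lag pair is added
        cols = [c for c, (tb, te) in enumerate(two.column_index)
                if round((tb - te) / grid.dt) == 2]
        rows_one = np.asarray(one.values)[:, cols].sum()
        rows_two = np.asarray(two.values)[:, cols].sum()
        assert rows_two > rows_one


class TestOLS:
    def test_identity_design_returns_response(self):
        y = np.arange(5.0)
        assert np.allclose(kv.ols_fit(np.eye(5), y), y)

    def test_exact_linear_model_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        w0 = rng.normal(size=6)
        w = kv.ols_fit(X, X @ w0)
        assert np.abs(w - w0).max() < 1e-10

    def test_hand_solved_4x2_system(self):
        X = np.array([[1.0, 0], [1, 1], [1, 2], [1, 3]])
        y = np.array([1.0, 2, 2, 4])
        # normal equations solved by hand: w = (0.9, 0.9)
        assert np.allclose(kv.ols_fit(X, y), [0.9, 0.9])

    def test_residual_orthogonal_to_columns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        w = kv.ols_fit(X, y)
        r = y - X @ w
        assert np.abs(X.T @ r).max() < 1e-8 * np.linalg.norm(y)

    def test_rank_deficiency_raises_naming_columns(self):
        X = np.zeros((10, 3))
        X[:, 0] = 1.0
        X[:, 2] = 2.0  # column 2 collinear with column 0, column 1 empty
        with pytest.raises(np.linalg.LinAlgError, match="offending columns"):
            kv.ols_fit(X, np.ones(10))
        w = kv.ols_fit(X, np.ones(10), allow_pinv=True)
        assert w.shape == (3,)


class TestSequentialFit:
    def test_noiseless_recovery_of_all_first_order_kernels(
            self, kernels, clean_sequential_fit):
        _, fit = clean_sequential_fit
        assert np.abs(fit.w_stim.weights - kernels.w_stim.weights).max() < 1e-6
        assert np.abs(fit.w_e.weights - kernels.w_e.weights).max() < 1e-6
        assert np.abs(fit.w_b.weights - kernels.w_b.weights).max() < 1e-6

    def test_movement_free_dataset_flags_insufficient_trials(self, grid):
        trials = [_trial(grid) for _ in range(10)]
        sel = kv.select_trials(trials, grid)
        fit = kv.sequential_fit(trials, sel, grid)
        assert fit.w_stim is not None
        assert fit.w_e is None and fit.w_b is None
        assert fit.flags["x_e"] == "insufficient trials"
        assert fit.flags["x_b"] == "insufficient trials"

    def test_fit_invariant_to_trial_order(self, grid, clean_animal,
                                          clean_sequential_fit):
        _, trials = clean_animal
        _, f1 = clean_sequential_fit
        rng = np.random.default_rng(0)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        f2 = kv.sequential_fit(shuffled, kv.select_trials(shuffled, grid, 2.5),
                               grid)
        assert np.allclose(f1.w_e.weights, f2.w_e.weights, atol=1e-9)
        assert np.allclose(f1.w_b.weights, f2.w_b.weights, atol=1e-9)

    def test_residuals_negative_where_suppression_planted(
            self, grid, kernels, clean_sequential_fit):
        _, fit = clean_sequential_fit
        # average residual at times covered by the suppressive region is < 0
        pooled = np.concatenate([rt.y for rt in fit.residual_trials])
        assert pooled.min() < -0.1
        assert pooled.mean() < 0


class TestInteractionKernel:
    def test_noiseless_recovery_at_unmasked_bins(self, kernels,
                                                 clean_sequential_fit):
        _, fit = clean_sequential_fit
        K = kv.fit_interaction_kernel(fit.residual_trials, method="ols")
        err = np.abs(K.weights - kernels.w_be.weights)[~K.mask]
        assert err.max() < 1e-6

    def test_mask_follows_min_trials_rule(self, clean_sequential_fit):
        _, fit = clean_sequential_fit
        K = kv.fit_interaction_kernel(fit.residual_trials, method="ols",
                                      min_trials=10)
        assert np.array_equal(K.mask, K.trial_counts < 10)
        # a bin supported by fewer than 10 trials is masked
        under = K.trial_counts < 10
        assert K.mask[under].all()

    def test_zero_residuals_give_zero_kernel(self, grid):
        trials = []
        for te, tb in [(5, 8), (12, 10), (15, 18), (20, 9)] * 4:
            x_e = np.zeros(26); x_e[te] = 1
            x_b = np.zeros(26); x_b[tb] = 1
            trials.append(ResidualTrial(0, x_b, x_e, np.zeros(26)))
        K = kv.fit_interaction_kernel(trials, method="ols", min_trials=1)
        assert np.allclose(K.weights, 0.0)

    def test_ols_estimate_unbiased_over_replicates(self, grid, kernels):
        """Mean OLS interaction estimate over noisy replicates stays within
        3 SE of the planted kernel at every unmasked bin.  Residuals are
        formed with the exact first-order responses so the check isolates the
        2D estimator."""
        spec = kv.AnimalSpec("a", n_trials=250, sigma_gain=0.0, sigma_noise=0.0)
        no_interaction = kv.GroundTruthKernels(
            kernels.w_stim, kernels.w_e, kernels.w_b,
            kv.Kernel2D(kernels.w_be.body_lags, kernels.w_be.saccade_lags,
                        np.zeros((21, 21))))
        rng = np.random.default_rng(0)
        estimates = []
        for rep in range(30):
            events = kv.generate_event_trains(spec, grid, rng_seed=rep)
            residuals = []
            for x_stim, x_e, x_b in events:
                if x_e.sum() < 1 or x_b.sum() < 1:
                    continue
                y = kv.simulate_trial(kernels, (x_stim, x_e, x_b), grid=grid)
                first = kv.simulate_trial(no_interaction, (x_stim, x_e, x_b),
                                          grid=grid)
                resid = y - first + rng.normal(0, 0.05, grid.n_bins)
                residuals.append(ResidualTrial(0, x_b, x_e, resid))
            K = kv.fit_interaction_kernel(residuals, method="ols",
                                          min_trials=5, allow_pinv=True)
            est = K.weights.copy()
            est[K.mask] = np.nan
            estimates.append(est)
        est = np.array(estimates)
        n_ok = np.sum(np.isfinite(est), axis=0)
        always = n_ok == len(estimates)
        mean = np.nanmean(est, axis=0)
        se = np.nanstd(est, axis=0, ddof=1) / np.sqrt(len(estimates))
        dev = np.abs(mean - kernels.w_be.weights)
        frac_within = np.mean(dev[always] <= 3 * se[always] + 1e-12)
        assert frac_within > 0.95
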