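"""ALD priors, evidence, posterior identities, and the staged optimizer."""

import numpy as np
import pytest
import scipy.stats

import kernelvar as kv
from kernelvar import ald
from kernelvar.ald import (
    ALDData,
    ConstraintSet,
    FreqDomainPrior,
    TimeDomainPrior,
    _params_to_theta,
    _theta_to_params,
)


def _grid_coords(n):
    f = np.arange(n) - n // 2
    g1, g2 = np.meshgrid(f, f, indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()]).astype(float)


class TestTimePrior:
    def test_center_attains_scale(self):
        p = TimeDomainPrior(nu=[2.0, 3.0], Psi=np.eye(2), rho=1.3)
        c = kv.prior_cov_time(p, np.array([[2.0, 3.0]]))
        assert c[0] == pytest.approx(np.exp(-1.3))

    def test_unit_offset_identity_psi(self):
        p = TimeDomainPrior(nu=[0.0, 0.0], Psi=np.eye(2), rho=0.0)
        c = kv.prior_cov_time(p, np.array([[1.0, 0.0]]))
        assert c[0] == pytest.approx(np.exp(-0.5))

    def test_correlated_psi_matches_elementwise_loop(self):
        """5x5 grid with the fixed 0.5 correlation, against a direct loop."""
        psi_d = np.array([2.0, 1.5])
        corr = 0.5
        Psi = np.outer(psi_d, psi_d) * np.array([[1, corr], [corr, 1.0]])
        p = TimeDomainPrior(nu=[2.0, 2.0], Psi=Psi, rho=0.7)
        coords = ald.lag_coords((5, 5))
        got = kv.prior_cov_time(p, coords)
        Pinv = np.linalg.inv(Psi)
        for i, chi in enumerate(coords):
            diff = chi - p.nu
            expected = np.exp(-0.5 * diff @ Pinv @ diff - p.rho)
            assert got[i] == pytest.approx(expected, rel=1e-12)

    def test_non_pd_psi_rejected(self):
        with pytest.raises(ValueError):
            TimeDomainPrior(nu=[0, 0], Psi=np.array([[1.0, 2.0], [2.0, 1.0]]),
                            rho=0.0)


class TestFreqPrior:
    def test_zero_shape_matrix_gives_uniform_prior(self):
        p = FreqDomainPrior(nu=[0.0, 0.0], M=np.zeros((2, 2)), rho=0.0)
        c = kv.prior_cov_freq(p, _grid_coords(5))
        assert np.allclose(c, 1.0)

    def test_on_ellipse_attains_scale(self):
        p = FreqDomainPrior(nu=[2.0, 1.0], M=np.eye(2), rho=0.4)
        c = kv.prior_cov_freq(p, np.array([[2.0, 1.0]]))
        assert c[0] == pytest.approx(np.exp(-0.4))

    def test_matches_elementwise_loop(self):
        M = np.array([[2.0, 1.0], [1.0, 2.0]])
        p = FreqDomainPrior(nu=[0.1, 0.1], M=M, rho=0.5)
        coords = _grid_coords(5)
        got = kv.prior_cov_freq(p, coords)
        for i, w in enumerate(coords):
            diff = np.abs(M @ w) - p.nu
            assert got[i] == pytest.approx(np.exp(-0.5 * diff @ diff - 0.5),
                                           rel=1e-12)

    def test_invariant_under_frequency_negation(self):
        p = FreqDomainPrior(nu=[0.3, 0.0], M=np.array([[1.0, 0.6], [0.6, 0.8]]),
                            rho=0.0)
        coords = _grid_coords(7)
        assert np.allclose(kv.prior_cov_freq(p, coords),
                           kv.prior_cov_freq(p, -coords))

    def test_asymmetric_m_rejected(self):
        with pytest.raises(ValueError):
            FreqDomainPrior(nu=[0, 0], M=np.array([[1.0, 0.2], [0.3, 1.0]]),
                            rho=0.0)


class TestFourierBasis:
    @pytest.mark.parametrize("shape", [(1, 1), (3, 3), (5, 5), (21, 21)])
    def test_orthonormality(self, shape):
        B, coords = kv.build_fourier_basis(shape)
        d = shape[0] * shape[1]
        assert B.shape == (d, d)
        assert np.abs(B.T @ B - np.eye(d)).max() < 1e-10
        assert np.abs(B @ B.T - np.eye(d)).max() < 1e-10

    def test_parseval_on_random_kernel(self):
        B, _ = kv.build_fourier_basis((5, 5))
        k = np.random.default_rng(0).normal(size=25)
        assert np.linalg.norm(B @ k) == pytest.approx(np.linalg.norm(k), abs=1e-10)

    def test_constant_kernel_loads_only_zero_frequency(self):
        B, coords = kv.build_fourier_basis((5, 5))
        c = B @ np.ones(25)
        zero = np.all(coords == 0, axis=1)
        assert np.abs(c[~zero]).max() < 1e-12
        assert c[zero][0] == pytest.approx(5.0)  # sqrt(d) * 1

    def test_trivial_1x1_basis(self):
        B, coords = kv.build_fourier_basis((1, 1))
        assert B.shape == (1, 1) and B[0, 0] == pytest.approx(1.0)


class TestCombinePriors:
    def test_identity_frequency_prior_returns_time_prior(self):
        B, _ = kv.build_fourier_basis((5, 5))
        ct = np.random.default_rng(1).uniform(0.1, 2.0, 25)
        C = kv.combine_priors(ct, np.ones(25), B).C
        assert np.abs(C - np.diag(ct)).max() < 1e-12

    def test_identity_time_prior_returns_rotated_frequency_prior(self):
        B, _ = kv.build_fourier_basis((5, 5))
        cf = np.random.default_rng(2).uniform(0.1, 2.0, 25)
        C = kv.combine_priors(np.ones(25), cf, B).C
        assert np.abs(C - B.T @ np.diag(cf) @ B).max() < 1e-12

    def test_symmetry_and_psd_against_dense_product(self):
        rng = np.random.default_rng(3)
        B, _ = kv.build_fourier_basis((3, 3))
        ct = rng.uniform(0.0, 1.5, 9)
        cf = rng.uniform(0.0, 1.5, 9)
        C = kv.combine_priors(ct, cf, B).C
        S = np.diag(np.sqrt(ct))
        dense = S @ B.T @ np.diag(cf) @ B @ S
        assert np.abs(C - dense).max() < 1e-12
        assert np.abs(C - C.T).max() < 1e-12
        evals = np.linalg.eigvalsh(C)
        assert evals.min() >= -1e-10 * max(evals.max(), 1.0)


class TestLogEvidence:
    def test_closed_form_identity_design_zero_response(self):
        n = 6
        s2, sp2 = 0.4, 1.7
        got = kv.log_evidence((s2, np.full(n, sp2)), np.eye(n), np.zeros(n))
        assert got == pytest.approx(-n / 2 * np.log(2 * np.pi * (s2 + sp2)))

    def test_vanishing_prior_collapses_to_noise_density(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        Y = rng.normal(size=12)
        s2 = 0.5
        got = kv.log_evidence((s2, np.full(4, 1e-14)), X, Y)
        want = scipy.stats.multivariate_normal.logpdf(Y, np.zeros(12),
                                                      s2 * np.eye(12))
        assert got == pytest.approx(want, abs=1e-6)

    def test_matches_direct_density_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, d = int(rng.integers(10, 50)), int(rng.integers(2, 25))
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=n)
            A = rng.normal(size=(d, d))
            C = A @ A.T * 0.3
            s2 = float(rng.uniform(0.1, 1.0))
            got = kv.log_evidence((s2, C), X, Y)
            want = scipy.stats.multivariate_normal.logpdf(
                Y, np.zeros(n), s2 * np.eye(n) + X @ C @ X.T)
            assert got == pytest.approx(want, abs=1e-8)

    def test_non_psd_prior_rejected_with_eigenvalue(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="eigenvalue"):
            kv.log_evidence((0.1, C), np.eye(2), np.zeros(2))


class TestPosterior:
    def test_isotropic_prior_matches_ridge(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 7))
        Y = rng.normal(size=40)
        s2, sp2 = 0.3, 1.2
        post = kv.posterior_fit((s2, np.full(7, sp2)), X, Y)
        assert np.abs(post.mu - kv.ridge_solve(X, Y, s2 / sp2)).max() < 1e-10

    def test_large_prior_approaches_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=50)
        post = kv.posterior_fit((0.2, np.full(5, 1e8)), X, Y)
        assert np.abs(post.mu - kv.ols_fit(X, Y)).max() < 1e-5

    def test_matches_dense_brute_force_solution(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=30)
        A = rng.normal(size=(6, 6))
        C = A @ A.T * 0.5 + 0.1 * np.eye(6)
        s2 = 0.4
        post = kv.posterior_fit((s2, C), X, Y)
        Lam = np.linalg.inv(X.T @ X / s2 + np.linalg.inv(C))
        mu = Lam @ X.T @ Y / s2
        assert np.abs(post.mu - mu).max() < 1e-9
        assert np.abs(post.Lambda - Lam).max() < 1e-9
        evals = np.linalg.eigvalsh(post.Lambda)
        assert evals.min() > 0


def _planted_dataset(rng, n_trials=60, shape=(9, 9), noise=0.25):
    """Rows with sparse binary designs and a smooth localized planted kernel."""
    d = shape[0] * shape[1]
    i, j = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    k0 = -np.exp(-((i - 3.0) ** 2 + (j - 3.5) ** 2) / 4.0).ravel()
    X = (rng.uniform(size=(n_trials * 8, d)) < 0.06).astype(float)
    Y = X @ k0 + rng.normal(0, noise, X.shape[0])
    return X, Y, k0


class TestFitALD:
    def test_fully_constrained_fit_returns_exact_values(self):
        rng = np.random.default_rng(9)
        X, Y, _ = _planted_dataset(rng)
        values = {
            "sigma2": 0.05, "nu_t1": 3.0, "nu_t2": 3.5, "psi1": 2.0,
            "psi2": 2.0, "psi_corr": 0.5, "rho_t": 0.0,
            "nu_f1": 0.0, "nu_f2": 0.0, "M11": 1.0, "M12": 0.2, "M22": 1.0,
            "rho_f": 0.0,
        }
        res = kv.fit_ald(X, Y, shape=(9, 9),
                         constraints=ConstraintSet.fix_all(values), seed=0)
        got = _theta_to_params(res.theta)
        for k, v in values.items():
            assert got[k] == pytest.approx(v)
        assert res.posterior.mu.shape == (81,)

    def test_recovers_planted_kernel_better_than_ols(self):
        rng = np.random.default_rng(10)
        X, Y, k0 = _planted_dataset(rng, noise=0.35)
        res = kv.fit_ald(X, Y, shape=(9, 9), seed=1)
        r_ald = np.corrcoef(res.posterior.mu, k0)[0, 1]
        w_ols = kv.ols_fit(X, Y, allow_pinv=True)
        r_ols = np.corrcoef(w_ols, k0)[0, 1]
        assert r_ald > 0.8
        assert r_ald > r_ols
        # evidence at the optimum is not worse than at any restart start
        for stage in res.trace:
            for rec in stage["restarts"]:
                assert rec["f"] >= rec["f0"] - 1e-9

    def test_zero_response_flags_flat_objective(self):
        rng = np.random.default_rng(11)
        X, _, _ = _planted_dataset(rng)
        res = kv.fit_ald(X, np.zeros(X.shape[0]), shape=(9, 9), seed=0)
        assert res.flags.get("flat_objective")


class TestRefitM:
    def test_self_consistent_when_population_equals_own_fit(self):
        rng = np.random.default_rng(12)
        X, Y, _ = _planted_dataset(rng)
        full = kv.fit_ald(X, Y, shape=(9, 9), seed=2)
        refit = kv.refit_M_only(X, Y, full.theta, shape=(9, 9), seed=3)
        # the refit explores from the same optimum: evidence cannot get worse
        assert refit.evidence_freq >= full.evidence_freq - 1e-6
        assert np.abs(refit.theta.m_entries - full.theta.m_entries).max() < 0.5

    def test_degenerate_zero_response_flagged(self):
        rng = np.random.default_rng(13)
        X, Y, _ = _planted_dataset(rng)
        full = kv.fit_ald(X, Y, shape=(9, 9), seed=4)
        res = kv.refit_M_only(X, np.zeros_like(Y), full.theta, shape=(9, 9))
        assert res.flags.get("flat_objective")
        assert np.allclose(res.posterior.mu, 0.0)

    def test_refits_preserve_across_condition_m_ranking(self):
        """Datasets with weak vs strong extra response scatter keep their
        full-fit ordering of the shape parameters after the M-only refit."""
        rng = np.random.default_rng(14)
        results = {}
        for label, gain_sd in (("low", 0.05), ("high", 0.6)):
            X, Y, k0 = _planted_dataset(rng, noise=0.05)
            gains = np.exp(rng.normal(0, gain_sd, X.shape[0]))
            Yg = (X @ k0) * gains + rng.normal(0, 0.05, X.shape[0])
            results[label] = (X, Yg, kv.fit_ald(X, Yg, shape=(9, 9), seed=5))
        pop = ald.population_average([results["low"][2].theta,
                                      results["high"][2].theta])
        refits = {}
        for label, (X, Yg, full) in results.items():
            base = _theta_to_params(pop)
            base["sigma2"] = full.theta.sigma2
            refits[label] = kv.refit_M_only(X, Yg, _params_to_theta(base),
                                            shape=(9, 9), seed=6)
        m_low = refits["low"].theta.m_entries
        m_high = refits["high"].theta.m_entries
        assert np.mean(m_high) > np.mean(m_low)


class TestInvariantsAndStability:
    def test_m_scaling_never_widens_prior(self):
        """With nu_f = 0, scaling M up shrinks the 0.02-threshold width."""
        M = np.array([[0.5, 0.3], [0.3, 0.5]])
        widths = []
        for c in np.linspace(1.0, 4.0, 10):
            p = FreqDomainPrior(nu=[0.0, 0.0], M=c * M, rho=0.0)
            widths.append(kv.freq_prior_width(kv.freq_prior_matrix(p, (21, 21))))
        assert np.all(np.diff(widths) <= 0)

    @pytest.mark.parametrize("which", ["M11", "M22"])
    def test_increasing_diagonal_entries_never_widens_prior(self, which):
        widths = []
        for v in np.linspace(0.3, 3.0, 10):
            m = {"M11": 0.5, "M12": 0.2, "M22": 0.5}
            m[which] = v
            p = FreqDomainPrior(nu=[0.0, 0.0],
                                M=np.array([[m["M11"], m["M12"]],
                                            [m["M12"], m["M22"]]]), rho=0.0)
            widths.append(kv.freq_prior_width(kv.freq_prior_matrix(p, (21, 21))))
        assert np.all(np.diff(widths) <= 0)

    def test_stability_screen_flags_wild_m_resamples(self):
        stable = np.array([[1.0, 0.5, 1.0]] * 10) + 0.01
        unstable = np.array([[1.0, 0.5, 1.0], [-1.0, 2.0, 0.1]] * 5)
        assert not kv.flag_unstable(stable)
        assert kv.flag_unstable(unstable)

    def test_combined_prior_symmetric(self):
        rng = np.random.default_rng(15)
        B, _ = kv.build_fourier_basis((5, 5))
        C = kv.combine_priors(rng.uniform(0, 1, 25), rng.uniform(0, 1, 25), B).C
        assert np.abs(C - C.T).max() < 1e-12
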