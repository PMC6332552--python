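"""Correlated-frailty likelihood, fits, and the boundary mixture LRT."""

import numpy as np
import pytest
from scipy import integrate, stats

from ldsim.frailty import (
    FrailtyData,
    StudyConfig,
    family_loglik,
    fit,
    lrt,
    lrt_pvalue,
    run_study,
    simulate_study_replicate,
)
from ldsim.meiosis import RecombinationParams

RHO, LAM = 3.0, 143.0


def _quad_marginal(t, d, X, B, beta, sigma2):
    """Adaptive-quadrature oracle for the marginal log-likelihood, n <= 3."""
    t = np.atleast_1d(np.asarray(t, float))
    d = np.atleast_1d(np.asarray(d, float))
    X = np.atleast_2d(np.asarray(X, float))
    n = len(t)
    Sig = sigma2 * np.asarray(B, float)
    Sinv = np.linalg.inv(Sig)
    det = np.linalg.det(2 * np.pi * Sig)
    z = t / LAM
    eta0 = X @ np.atleast_1d(beta)

    def dens(*b):
        b = np.asarray(b)
        eta = eta0 + b
        ll = np.sum(d * (np.log(RHO / LAM) + (RHO - 1) * np.log(z) + eta))
        ll -= np.sum(z**RHO * np.exp(eta))
        return np.exp(ll) * np.exp(-0.5 * b @ Sinv @ b) / np.sqrt(det)

    if n == 1:
        val = integrate.quad(dens, -8, 8, epsabs=1e-13)[0]
    elif n == 2:
        val = integrate.dblquad(lambda a, b: dens(b, a), -6, 6, -6, 6,
                                epsabs=1e-12)[0]
    else:
        val = integrate.tplquad(lambda a, b, c: dens(c, b, a), -5, 5, -5, 5,
                                -5, 5, epsabs=1e-10)[0]
    return np.log(val)


def _simulated_data(rare_fixture, n_families=60, beta_g=0.0, seed=1,
                    sigma2_gen=0.0):
    _, _, model, cms = rare_fixture
    cfg = StudyConfig(sigma2_gen=sigma2_gen)
    rng = np.random.default_rng(seed)
    data, _ = simulate_study_replicate(
        model, cms, np.array([5, 15, 25]), n_families, beta_g, cfg,
        RecombinationParams(), rng,
    )
    return data


class TestFamilyLoglik:
    def test_sigma0_equals_closed_form(self):
        """Degenerate frailty reduces to the independent Weibull PH loglik."""
        t = np.array([80.0, 70.0, 95.0])
        d = np.array([1.0, 0.0, 1.0])
        X = np.array([[1.0], [0.0], [1.0]])
        beta = np.array([0.5])
        eta = X @ beta
        z = t / LAM
        closed = np.sum(
            d * (np.log(RHO / LAM) + (RHO - 1) * np.log(z) + eta)
            - z**RHO * np.exp(eta)
        )
        got = family_loglik(t, d, X, np.eye(3), RHO, LAM, beta, 0.0)
        assert got == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize("sigma2", [0.2, 0.5])
    def test_single_member_matches_quadrature(self, sigma2):
        t, d, X, B = [80.0], [1.0], [[1.0]], np.eye(1)
        exact = _quad_marginal(t, d, X, B, [0.5], sigma2)
        got = family_loglik(t, d, X, B, RHO, LAM, [0.5], sigma2)
        assert got == pytest.approx(exact, rel=1e-4)

    def test_two_member_identity_B_factorizes(self):
        """With B = I the family marginal is the product of member marginals
        (to the order of the Laplace correction, well inside 1e-4)."""
        sigma2 = 0.8
        whole = family_loglik([80.0, 70.0], [1.0, 0.0], [[1.0], [0.0]],
                              np.eye(2), RHO, LAM, [0.5], sigma2)
        a = family_loglik([80.0], [1.0], [[1.0]], np.eye(1), RHO, LAM, [0.5],
                          sigma2)
        b = family_loglik([70.0], [0.0], [[0.0]], np.eye(1), RHO, LAM, [0.5],
                          sigma2)
        assert whole == pytest.approx(a + b, rel=1e-4)

    @pytest.mark.parametrize("size", [2, 3])
    def test_small_family_matches_quadrature(self, size):
        """Corrected-Laplace vs adaptive quadrature, <= 1e-3 relative."""
        t = [80.0, 70.0, 60.0][:size]
        d = [1.0, 0.0, 1.0][:size]
        X = [[1.0], [0.0], [1.0]][:size]
        B = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.25], [0.5, 0.25, 1.0]])
        B = B[:size, :size]
        for sigma2 in [0.3, 1.0]:
            exact = _quad_marginal(t, d, X, B, [0.5], sigma2)
            got = family_loglik(t, d, X, B, RHO, LAM, [0.5], sigma2)
            assert got == pytest.approx(exact, rel=1e-3)

    def test_non_psd_B_rejected(self):
        B = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            family_loglik([80.0, 70.0], [1, 0], [[1.0], [0.0]], B, RHO, LAM,
                          [0.5], 0.5)


class TestFit:
    def test_parameter_recovery_null(self, rare_fixture):
        """Estimates at 500 families cover the generating parameters."""
        data = _simulated_data(rare_fixture, n_families=500, seed=3)
        res = fit(data, null=True)
        assert res.converged
        assert res.rho_hat == pytest.approx(3.0, rel=0.15)
        assert res.lambda_hat == pytest.approx(143.0, rel=0.10)
        assert res.beta_hat[0] == pytest.approx(0.5, abs=0.25)

    def test_alternative_nests_null(self, rare_fixture):
        for seed in [1, 2]:
            data = _simulated_data(rare_fixture, n_families=80, seed=seed)
            f0 = fit(data, null=True)
            f1 = fit(data, null=False)
            assert f1.sigma2_hat >= 0.0
            assert f1.loglik >= f0.loglik - 1e-6

    def test_sigma2_recovered_under_alternative(self, rare_fixture):
        data = _simulated_data(rare_fixture, n_families=400, seed=9,
                               sigma2_gen=0.5)
        f0 = fit(data, null=True)
        f1 = fit(data, null=False)
        assert 0.15 < f1.sigma2_hat < 1.0
        assert lrt(f0, f1).statistic > 2.706  # clearly detected

    def test_all_censored_rejected(self):
        times = [np.array([50.0, 40.0])] * 3
        status = [np.zeros(2)] * 3
        X = [np.zeros((2, 1))] * 3
        B = [np.eye(2)] * 3
        with pytest.raises(ValueError, match="censored"):
            fit(FrailtyData(times, status, X, B), null=True)

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="two families"):
            fit(FrailtyData([np.array([50.0])], [np.ones(1)],
                            [np.ones((1, 1))], [np.eye(1)]), null=True)


class TestLrtPvalue:
    def test_mixture_reference_values(self):
        assert lrt_pvalue(0.0) == 1.0
        # 0.5 * P(chi2_1 >= 2.706) = 0.5 * 0.100
        assert lrt_pvalue(2.706) == pytest.approx(0.05, abs=1e-3)
        assert lrt_pvalue(3.841) == pytest.approx(0.025, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-0.1)

    def test_pvalues_in_unit_interval(self):
        for s in [1e-8, 0.5, 5.0, 50.0]:
            assert 0.0 < lrt_pvalue(s) <= 1.0


class TestRunStudy:
    def test_signal_strength_increases_lrt(self, rare_fixture):
        """Mean LRT statistic grows with the genotype effect size."""
        _, _, model, cms = rare_fixture
        rng = np.random.default_rng(77)
        causal = np.array([5, 15, 25])
        mean_stats = []
        for beta_g in [0.0, 1.0]:
            stats_b = []
            for _ in range(8):
                data, _ = simulate_study_replicate(
                    model, cms, causal, 80, beta_g, StudyConfig(),
                    RecombinationParams(), rng,
                )
                f0 = fit(data, null=True)
                f1 = fit(data, null=False)
                stats_b.append(max(0.0, 2 * (f1.loglik - f0.loglik)))
            mean_stats.append(np.mean(stats_b))
        assert mean_stats[1] > mean_stats[0]

    def test_zero_replicates_rejected(self, rare_fixture):
        _, _, model, cms = rare_fixture
        with pytest.raises(ValueError):
            run_study(StudyConfig(replicates=0), model, cms)

    def test_smoke_table_shape_and_determinism(self, rare_fixture):
        _, _, model, cms = rare_fixture
        cfg = StudyConfig(n_families=(20,), beta_g=(0.0, 1.0), replicates=3,
                          seed=5)
        t1 = run_study(cfg, model, cms)
        t2 = run_study(cfg, model, cms)
        assert list(t1.columns) == ["n_families", "beta_g", "replicates",
                                    "n_tested", "rejection_rate", "fit_failures"]
        assert len(t1) == 2
        assert t1.equals(t2)
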