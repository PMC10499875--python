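import math

import numpy as np
import pytest
from scipy import optimize

from sharederr import (
    ErrorGSDs,
    LQParams,
    build_realisation_set,
    erc_adjusted_loglik,
    fit_extended_rc,
    fit_mcml,
    fit_ml,
    fit_regression_calibration,
    grouped_loglik,
    mcml_loglik,
    profile_ci,
)
from sharederr.doses import RealisationSet


def make_rset(matrix: np.ndarray) -> RealisationSet:
    matrix = np.asarray(matrix, dtype=float)
    cov = (
        np.cov(matrix, rowvar=False)
        if matrix.shape[0] > 1
        else np.zeros((matrix.shape[1],) * 2)
    )
    if matrix.shape[0] > 1 and np.allclose(matrix, matrix[0]):
        cov = np.zeros_like(cov)
    return RealisationSet(matrix=matrix, mean_doses=matrix.mean(axis=0), covariance=cov)


def oracle_loglik(theta0, alpha, beta, d, c, n):
    """Independent grouped Poisson log-likelihood (no factorial constant)."""
    rates = np.exp(theta0) * n * (1 + alpha * d + beta * d**2)
    if np.any(rates <= 0):
        return -np.inf
    return float(np.sum(np.where(c > 0, c * np.log(rates), 0.0)) - rates.sum())


def oracle_profiled(alpha, beta, d, c, n):
    """Intercept profiled out in closed form: exp(t0) = sum(c)/sum(n*rr)."""
    rr = 1 + alpha * d + beta * d**2
    if np.min(rr) <= 0:
        return -np.inf
    t0 = math.log(c.sum() / np.dot(n, rr))
    return oracle_loglik(t0, alpha, beta, d, c, n)


class TestGroupedLoglik:
    d = np.array([0.0, 0.5, 1.0])
    n = np.array([100.0, 50.0, 25.0])
    c = np.array([10.0, 9.0, 11.0])

    def test_matches_direct_formula(self):
        params = LQParams(log_baseline=-2.0, alpha=0.3, beta=1.2)
        assert grouped_loglik(params, self.d, self.c, self.n) == pytest.approx(
            oracle_loglik(-2.0, 0.3, 1.2, self.d, self.c, self.n)
        )

    def test_intercept_only_mle_closed_form(self):
        # alpha = beta = 0: MLE of the baseline is log(total cases / total persons)
        fit = fit_ml(np.zeros(3), self.c, self.n, compute_ci=False)
        assert fit.params.log_baseline == pytest.approx(
            math.log(self.c.sum() / self.n.sum()), abs=1e-5
        )

    def test_zero_doses_make_coefficients_irrelevant(self):
        p1 = LQParams(-1.5, 0.1, 0.2)
        p2 = LQParams(-1.5, 5.0, -0.3)
        zeros = np.zeros(3)
        assert grouped_loglik(p1, zeros, self.c, self.n) == grouped_loglik(
            p2, zeros, self.c, self.n
        )

    def test_negative_rate_gives_minus_inf(self):
        params = LQParams(0.0, -2.0, 0.0)
        assert grouped_loglik(params, np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                              np.array([10.0, 10.0])) == -np.inf

    def test_two_group_score_equation_matches_grid(self):
        # beta fixed at 0: alpha-hat from the score equation agrees with a
        # dense grid search over the profiled log-likelihood
        d = np.array([0.0, 1.0])
        n = np.array([10.0, 10.0])
        c = np.array([5.0, 15.0])

        def score(alpha):
            # d/dalpha of profiled loglik at beta=0
            eps = 1e-6
            return (
                oracle_profiled(alpha + eps, 0.0, d, c, n)
                - oracle_profiled(alpha - eps, 0.0, d, c, n)
            ) / (2 * eps)

        root = optimize.brentq(score, 0.1, 50.0)
        grid = np.arange(0.5, 5.0, 1e-4)
        vals = [oracle_profiled(a, 0.0, d, c, n) for a in grid]
        assert root == pytest.approx(grid[int(np.argmax(vals))], abs=2e-4)
        # closed form for 2 groups: rate ratio 15/5 = 1 + alpha
        assert root == pytest.approx(2.0, abs=1e-6)


class TestFitML:
    def test_three_group_grid_oracle(self):
        d = np.array([0.0, 0.7, 1.8])
        n = np.array([200.0, 80.0, 40.0])
        c = np.array([20.0, 17.0, 30.0])
        fit = fit_ml(d, c, n, compute_ci=False)
        alphas = np.arange(-0.5, 3.0, 0.002)
        betas = np.arange(-0.5, 3.0, 0.002)
        vals = np.array(
            [[oracle_profiled(a, b, d, c, n) for b in betas] for a in alphas]
        )
        ia, ib = np.unravel_index(np.argmax(vals), vals.shape)
        # refine grid around the coarse optimum
        alphas2 = alphas[ia] + np.arange(-0.002, 0.002, 1e-5)
        betas2 = betas[ib] + np.arange(-0.002, 0.002, 1e-5)
        vals2 = np.array(
            [[oracle_profiled(a, b, d, c, n) for b in betas2] for a in alphas2]
        )
        ia2, ib2 = np.unravel_index(np.argmax(vals2), vals2.shape)
        assert fit.params.alpha == pytest.approx(alphas2[ia2], abs=1e-4)
        assert fit.params.beta == pytest.approx(betas2[ib2], abs=1e-4)

    def test_self_consistency_exact_counts(self, cohort):
        d = cohort.central_doses
        n = cohort.persons.astype(float)
        c = 0.05 * n * (1 + 0.25 * d + 2 * d**2)  # exactly proportional
        fit = fit_ml(d, c, n, compute_ci=False)
        assert fit.params.alpha == pytest.approx(0.25, abs=1e-4)
        assert fit.params.beta == pytest.approx(2.0, abs=1e-4)

    def test_parameter_recovery_large_counts(self, cohort, rng):
        d = cohort.central_doses
        n = cohort.persons.astype(float)
        expected = 100.0 * n * (1 + 0.25 * d + 2 * d**2)
        c = rng.poisson(expected).astype(float)
        fit = fit_ml(d, c, n, compute_ci=False)
        assert fit.params.alpha == pytest.approx(0.25, abs=0.05)
        assert fit.params.beta == pytest.approx(2.0, rel=0.05)

    def test_degenerate_all_cases_at_zero_dose(self):
        # with no cases outside the zero-dose group the likelihood pushes
        # the relative risk at the top dose to the positivity floor; the
        # fit must terminate there rather than diverge or crash
        d = np.array([0.0, 1.0, 2.0])
        n = np.array([50.0, 30.0, 20.0])
        c = np.array([40.0, 0.0, 0.0])
        fit = fit_ml(d, c, n)
        rr_top = 1 + fit.params.alpha * 2.0 + fit.params.beta * 4.0
        assert 0 <= rr_top < 1e-3


class TestProfileCI:
    d = np.array([0.01, 0.1, 0.5, 1.5, 2.0])
    n = np.array([2591.0, 334.0, 438.0, 102.0, 6.0])

    def test_interval_contains_mle(self):
        c = np.array([150.0, 25.0, 45.0, 25.0, 5.0])
        fit = fit_ml(self.d, c, self.n)
        assert fit.ci_alpha[0] <= fit.params.alpha <= fit.ci_alpha[1]
        assert fit.ci_beta[0] <= fit.params.beta <= fit.ci_beta[1]
        assert not any(fit.boundary_flags.values())

    def test_intercept_only_matches_poisson_lr_interval(self):
        # all doses zero: total count is Poisson with mean mu = e^t0 * sum(n);
        # the profile interval for t0 must match the closed-form
        # likelihood-ratio interval for a Poisson mean
        c = np.array([30.0, 20.0, 10.0])
        n = np.array([100.0, 60.0, 40.0])
        total, offset = c.sum(), n.sum()

        def lr(mu):
            return 2 * (total * math.log(total / mu) - total + mu) - 3.8414588206941

        mu_lo = optimize.brentq(lr, 1e-6, total)
        mu_hi = optimize.brentq(lr, total, 10 * total)
        lo, hi = profile_ci("log_baseline", np.zeros(3), c, n)
        assert lo == pytest.approx(math.log(mu_lo / offset), abs=1e-5)
        assert hi == pytest.approx(math.log(mu_hi / offset), abs=1e-5)

    def test_level_widens_interval(self):
        c = np.array([150.0, 25.0, 45.0, 25.0, 5.0])
        ci95 = profile_ci("beta", self.d, c, self.n, level=0.95)
        ci99 = profile_ci("beta", self.d, c, self.n, level=0.99)
        assert ci99[0] < ci95[0] and ci99[1] > ci95[1]


class TestERC:
    def test_reduces_to_grouped_when_covariance_zero(self, cohort):
        rset = make_rset(np.tile(cohort.central_doses, (10, 1)))
        cases = np.array([150.0, 25.0, 45.0, 25.0, 5.0])
        offsets = cohort.persons.astype(float)
        for alpha in (-0.2, 0.0, 0.3, 1.0):
            for beta in (-0.1, 0.5, 2.0, 5.0):
                params = LQParams(-2.6, alpha, beta)
                adj = erc_adjusted_loglik(params, rset, cases, offsets)
                base = grouped_loglik(params, rset.mean_doses, cases, offsets)
                assert adj == base

    def test_continuity_to_rc_in_small_covariance_limit(self, cohort, rng):
        gsds = ErrorGSDs(share_berkson=0.2, unshare_berkson=0.2)
        rset = build_realisation_set(cohort, gsds, 400, rng)
        cases = np.array([150.0, 25.0, 45.0, 25.0, 5.0])
        rc = fit_regression_calibration(rset, cases, cohort)
        scaled = RealisationSet(
            matrix=rset.matrix,
            mean_doses=rset.mean_doses,
            covariance=rset.covariance * 1e-8,
        )
        erc = fit_extended_rc(scaled, cases, cohort)
        assert erc.params.alpha == pytest.approx(rc.params.alpha, abs=1e-3)
        assert erc.params.beta == pytest.approx(rc.params.beta, abs=1e-3)

    def test_adjustment_changes_fit_under_real_covariance(self, cohort, rng):
        gsds = ErrorGSDs(share_berkson=0.5, unshare_berkson=0.2)
        rset = build_realisation_set(cohort, gsds, 500, rng)
        cases = np.array([150.0, 25.0, 45.0, 25.0, 5.0])
        rc = fit_regression_calibration(rset, cases, cohort)
        erc = fit_extended_rc(rset, cases, cohort)
        assert erc.params.beta != pytest.approx(rc.params.beta, abs=1e-6)


class TestMCML:
    cases = np.array([150.0, 25.0, 45.0, 25.0, 5.0])

    def test_single_realisation_equals_grouped(self, cohort):
        doses = np.array([[0.01, 0.12, 0.48, 1.4, 2.2]])
        rset = make_rset(doses)
        offsets = cohort.persons.astype(float)
        params = LQParams(-2.7, 0.3, 1.8)
        assert mcml_loglik(params, rset, self.cases, offsets) == pytest.approx(
            grouped_loglik(params, doses[0], self.cases, offsets)
        )

    def test_identical_realisations_equal_grouped(self, cohort):
        doses = np.array([0.01, 0.12, 0.48, 1.4, 2.2])
        rset = make_rset(np.tile(doses, (100, 1)))
        offsets = cohort.persons.astype(float)
        params = LQParams(-2.7, 0.3, 1.8)
        assert mcml_loglik(params, rset, self.cases, offsets) == pytest.approx(
            grouped_loglik(params, doses, self.cases, offsets)
        )

    def test_jensen_inequality(self, cohort, rng):
        gsds = ErrorGSDs(share_berkson=0.5, unshare_berkson=0.5)
        rset = build_realisation_set(cohort, gsds, 200, rng)
        offsets = cohort.persons.astype(float)
        for alpha, beta in [(0.25, 2.0), (0.0, 0.5), (0.5, 1.0)]:
            params = LQParams(-2.7, alpha, beta)
            marginal = mcml_loglik(params, rset, self.cases, offsets)
            per_row = np.mean(
                [
                    grouped_loglik(params, row, self.cases, offsets)
                    for row in rset.matrix
                ]
            )
            assert marginal >= per_row - 1e-9

    def test_logsumexp_stability_under_huge_spread(self, cohort):
        # realisations engineered so per-row log-likelihoods differ by
        # ~1000 log units; the marginal must be finite, near the best row
        offsets = cohort.persons.astype(float)
        good = np.array([0.01, 0.1, 0.5, 1.5, 2.0])
        bad = good * 60.0
        rset = make_rset(np.vstack([good, bad]))
        params = LQParams(-2.7, 0.25, 2.0)
        ll_good = grouped_loglik(params, good, self.cases, offsets)
        ll_bad = grouped_loglik(params, bad, self.cases, offsets)
        assert ll_good - ll_bad > 500
        marginal = mcml_loglik(params, rset, self.cases, offsets)
        assert np.isfinite(marginal)
        assert marginal == pytest.approx(ll_good + math.log(0.5), abs=1e-6)

    def test_infeasible_rows_contribute_zero(self, cohort):
        offsets = cohort.persons.astype(float)
        good = np.array([0.01, 0.1, 0.5, 1.5, 2.0])
        other = good * 1.5
        rset = make_rset(np.vstack([good, other]))
        # alpha strongly negative: the scaled row's relative risk goes
        # negative while the original stays feasible
        params = LQParams(-2.7, -0.4, 0.0)
        assert np.all(1 + params.alpha * good + params.beta * good**2 > 0)
        assert np.min(1 + params.alpha * other + params.beta * other**2) < 0
        marginal = mcml_loglik(params, rset, self.cases, offsets)
        expected = grouped_loglik(params, good, self.cases, offsets) + math.log(0.5)
        assert marginal == pytest.approx(expected)

    def test_fit_recovers_reasonable_estimates(self, cohort, rng):
        gsds = ErrorGSDs(share_berkson=0.2, unshare_berkson=0.2)
        rset = build_realisation_set(cohort, gsds, 300, rng)
        fit = fit_mcml(rset, self.cases, cohort)
        assert fit.converged
        assert fit.ci_alpha[0] <= fit.params.alpha <= fit.ci_alpha[1]
        assert fit.ci_beta[0] <= fit.params.beta <= fit.ci_beta[1]
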