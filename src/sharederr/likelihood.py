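"""Grouped Poisson linear-relative-risk likelihood and the four estimators.

The grouped model has expected cases per dose group

    r_k = exp(theta0) * N_k * (1 + alpha*d_k + beta*d_k^2)

with N_k the person-count offsets and d_k the working group doses.  The
log-likelihood (dropping the factorial constant) is
sum_k [c_k log r_k - r_k].  The intercept profiles out in closed form,
so maximisation and confidence-interval profiling are carried out over
(alpha, beta) only; profile-likelihood 95% intervals use the chi-square
threshold 3.841.

Four estimators share this machinery and differ only in the working doses
and likelihood:

* unadjusted      — group means of one surrogate-dose draw;
* RC              — realisation-averaged group-mean true doses;
* extended RC     — RC doses plus a second-order likelihood adjustment
                    driven by the between-realisation covariance of the
                    group-mean doses (reduces exactly to RC when that
                    covariance vanishes);
* MCML            — marginal likelihood: the average over dose
                    realisations of the likelihood, computed with
                    log-sum-exp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .cohort import Cohort
from .doses import RealisationSet, SurrogateDoseVector
from .outcomes import CaseCounts, collapse_to_groups

__all__ = [
    "LQParams",
    "FitResult",
    "grouped_loglik",
    "fit_ml",
    "profile_ci",
    "fit_unadjusted",
    "fit_regression_calibration",
    "erc_adjusted_loglik",
    "fit_extended_rc",
    "mcml_loglik",
    "fit_mcml",
]

#: positivity floor for relative risks at the working doses
RR_EPS = 1e-6

#: deterministic restart schedule for (alpha, beta)
_STARTS: tuple[tuple[float, float], ...] = (
    (0.1, 0.5),
    (0.25, 2.0),
    (0.0, 0.0),
    (1.0, 4.0),
    (-0.1, 1.0),
)

#: absolute cap on the coefficient search during profiling
_PROFILE_CAP = 1e4


@dataclass(frozen=True)
class LQParams:
    """Parameters of the grouped linear-quadratic relative-risk model."""

    log_baseline: float
    alpha: float
    beta: float


@dataclass
class FitResult:
    """Point estimates, profile-likelihood intervals and diagnostics."""

    method: str
    params: LQParams
    loglik: float
    ci_alpha: tuple[float, float] = (math.nan, math.nan)
    ci_beta: tuple[float, float] = (math.nan, math.nan)
    converged: bool = False
    boundary_flags: dict[str, bool] = field(default_factory=dict)

    def covers(self, target: str, value: float) -> bool:
        """Whether the profile CI for ``target`` contains ``value``.

        A CI side whose search failed or stopped at a constraint is
        counted as non-covering (conservative bookkeeping).
        """
        lo, hi = self.ci_alpha if target == "alpha" else self.ci_beta
        ok_lo = value >= lo and not self.boundary_flags.get(f"{target}_lower", False)
        ok_hi = value <= hi and not self.boundary_flags.get(f"{target}_upper", False)
        return ok_lo and ok_hi


def _as_array(values) -> np.ndarray:
    if isinstance(values, CaseCounts):
        return np.asarray(values.counts, dtype=float)
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# Likelihood objects (intercept profiled analytically where possible)
# ---------------------------------------------------------------------------


class _GroupedLik:
    """Grouped Poisson likelihood at a fixed working-dose vector."""

    def __init__(self, doses, cases, offsets):
        self.d = np.asarray(doses, dtype=float)
        self.c = _as_array(cases)
        self.n = np.asarray(offsets, dtype=float)
        self.c_total = float(self.c.sum())
        self._pos = self.c > 0
        # constant sum_k c_k log N_k, kept so logliks are comparable
        self._clogn = float(np.sum(self.c[self._pos] * np.log(self.n[self._pos])))
        self.d2 = self.d * self.d

    def relative_risks(self, alpha: float, beta: float) -> np.ndarray:
        return 1.0 + alpha * self.d + beta * self.d2

    def loglik(self, theta0: float, alpha: float, beta: float) -> float:
        rr = self.relative_risks(alpha, beta)
        if np.min(rr) <= 0.0:
            return -np.inf
        rates = np.exp(theta0) * self.n * rr
        return float(
            np.sum(self.c[self._pos] * np.log(rates[self._pos])) - rates.sum()
        )

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        """Log-likelihood maximised analytically over the intercept."""
        rr = self.relative_risks(alpha, beta)
        if np.min(rr) <= RR_EPS:
            return -np.inf, math.nan
        if self.c_total == 0.0:
            return 0.0, -np.inf
        s = float(np.dot(self.n, rr))
        theta0 = math.log(self.c_total / s)
        ll = (
            self.c_total * theta0
            + self._clogn
            + float(np.sum(self.c[self._pos] * np.log(rr[self._pos])))
            - self.c_total
        )
        return ll, theta0

    def other_lower_bound(self, target: str, value: float) -> float:
        """Feasibility lower bound for the nuisance coefficient.

        With ``target`` fixed at ``value``, positivity of every group
        relative risk constrains the other coefficient from below only.
        """
        d = self.d[self.d > 0]
        if d.size == 0:
            return -_PROFILE_CAP
        if target == "alpha":  # bound on beta
            return float(np.max((RR_EPS - 1.0 - value * d) / (d * d)))
        return float(np.max((RR_EPS - 1.0 - value * d * d) / d))


class _ERCLik(_GroupedLik):
    """Grouped likelihood plus the second-order covariance adjustment.

    The marginal likelihood E[L(theta; d)] over the group-mean dose
    distribution, expanded to second order around the RC dose vector dbar,
    gives

        l_ERC = l(theta; dbar)
                + log(1 + (1/2) [ grad_d l' C grad_d l + sum_k C_kk l''_k ])

    with C the between-realisation covariance of the group-mean doses and
    the dose derivatives taken at dbar.  The adjustment vanishes exactly
    when C = 0, recovering regression calibration.  Parameter regions
    where the bracket is non-positive are treated as infeasible (the
    expansion is no longer a valid likelihood there).
    """

    def __init__(self, doses, covariance, cases, offsets):
        super().__init__(doses, cases, offsets)
        self.cov = np.asarray(covariance, dtype=float)
        self.cov_diag = np.diag(self.cov).copy()
        self._has_cov = bool(np.any(self.cov != 0.0))

    def _adjustment(self, theta0: float, alpha: float, beta: float, rr: np.ndarray) -> float:
        """log(1 + x) with x the second-order correction; -inf if 1+x <= 0."""
        lam = math.exp(theta0)
        rates = lam * self.n * rr
        slope = alpha + 2.0 * beta * self.d
        rp = lam * self.n * slope
        rpp = 2.0 * beta * lam * self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rates > 0, self.c / rates, 0.0)
            lp = (ratio - 1.0) * rp
            lpp = np.where(rates > 0, self.c * (rpp * rates - rp * rp) / rates**2, 0.0) - rpp
        x = 0.5 * (float(lp @ self.cov @ lp) + float(np.dot(self.cov_diag, lpp)))
        if not np.isfinite(x) or 1.0 + x <= 0.0:
            return -np.inf
        return math.log1p(x)

    def loglik(self, theta0: float, alpha: float, beta: float) -> float:
        base = super().loglik(theta0, alpha, beta)
        if not np.isfinite(base) or not self._has_cov:
            return base
        rr = self.relative_risks(alpha, beta)
        return base + self._adjustment(theta0, alpha, beta, rr)

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        """Adjusted log-likelihood maximised over the intercept.

        In u = exp(theta0) the correction bracket is a quadratic
        q(u) = qa u^2 + qb u + qc, so the profiled objective
        l(u) = C log u + const - u S + log q(u) is smooth on the (at most
        two) intervals where q > 0; each is searched with bounded Brent.
        """
        if not self._has_cov:
            return super().profiled(alpha, beta)
        rr = self.relative_risks(alpha, beta)
        if np.min(rr) <= RR_EPS:
            return -np.inf, math.nan
        if self.c_total == 0.0:
            return 0.0, -np.inf
        c_tot = self.c_total
        s_tot = float(np.dot(self.n, rr))
        raw_slope = alpha + 2.0 * beta * self.d
        slope = raw_slope / rr
        curv = (2.0 * beta * rr - raw_slope * raw_slope) / (rr * rr)
        a_vec = self.c * slope
        b_vec = self.n * rr * slope
        a_ca = float(a_vec @ self.cov @ a_vec)
        a_cb = float(a_vec @ self.cov @ b_vec)
        b_cb = float(b_vec @ self.cov @ b_vec)
        d0 = float(np.dot(self.cov_diag, self.c * curv))
        d1 = 2.0 * beta * float(np.dot(self.cov_diag, self.n))
        qa = 0.5 * b_cb
        qb = -(a_cb + 0.5 * d1)
        qc = 1.0 + 0.5 * (a_ca + d0)
        const = self._clogn + float(np.sum(self.c[self._pos] * np.log(rr[self._pos])))

        def ll_u(u: float) -> float:
            q = qa * u * u + qb * u + qc
            if u <= 0.0 or q <= 0.0:
                return -math.inf
            return c_tot * math.log(u) + const - u * s_tot + math.log(q)

        def dll(u: float) -> float:
            q = qa * u * u + qb * u + qc
            return c_tot / u - s_tot + (2.0 * qa * u + qb) / q

        # feasible u-intervals where the bracket q(u) > 0; on each, ll -> -inf
        # at both ends, so the interior stationary point is the maximum.
        # Only the interval containing (or nearest to) the unadjusted
        # intercept u0 is searched: the expansion is a local approximation
        # around the RC fit, and any second feasible branch far from u0 is
        # an artifact of the quadratic bracket.
        u0 = c_tot / s_tot
        intervals: list[tuple[float, float | None]] = []
        disc = qb * qb - 4.0 * qa * qc
        if qa > 0.0 and disc > 0.0:
            r1 = (-qb - math.sqrt(disc)) / (2.0 * qa)
            r2 = (-qb + math.sqrt(disc)) / (2.0 * qa)
            low = (0.0, r1) if r1 > 0.0 else None
            high = (max(r2, 0.0), None)
            if low is not None and u0 <= r1:
                intervals.append(low)
            elif u0 >= r2 or low is None:
                intervals.append(high)
            else:  # u0 falls in the infeasible gap: take the nearer branch
                intervals.append(low if u0 - r1 <= r2 - u0 else high)
        elif qa == 0.0 and qb < 0.0:
            intervals.append((0.0, -qc / qb))
        else:
            intervals.append((0.0, None))
        best_u, best_ll = math.nan, -math.inf
        for lo, hi in intervals:
            # bracket the root of the score: positive near lo, negative near hi
            if hi is None:
                a = max(lo * (1.0 + 1e-9), 1e-12 * max(u0, 1e-300))
                b = max(2.0 * u0, 2.0 * a)
                ok = False
                for _ in range(200):
                    if dll(b) < 0.0:
                        ok = True
                        break
                    b *= 2.0
                if not ok:
                    continue
            else:
                a = lo + (hi - lo) * 1e-12 if lo > 0.0 else hi * 1e-15
                b = hi - (hi - lo) * 1e-12
            fa, fb = dll(a), dll(b)
            for _ in range(50):  # tighten ends if signs are not yet resolved
                if fa > 0.0:
                    break
                a = a * 1e-2 if lo == 0.0 else lo + (a - lo) * 0.01
                fa = dll(a)
            if fa <= 0.0 or fb >= 0.0:
                continue
            u_star = optimize.brentq(dll, a, b, xtol=1e-13 * max(b, 1.0), rtol=1e-14)
            val = ll_u(u_star)
            if val > best_ll:
                best_ll, best_u = val, u_star
        if not np.isfinite(best_ll):
            return -np.inf, math.nan
        return best_ll, math.log(best_u)


class _MCMLLik:
    """Marginal (Monte Carlo) likelihood over dose realisations.

    exp of the marginal log-likelihood is the weighted average over
    distinct realisation rows of the grouped likelihood at that row's
    group means.  Realisations with an infeasible relative risk contribute
    zero likelihood.  The intercept is profiled by a fixed-point iteration
    on its score equation (with a safeguarded 1-D fallback).
    """

    def __init__(self, rows, weights, cases, offsets):
        self.rows = np.asarray(rows, dtype=float)
        self.logw = np.log(np.asarray(weights, dtype=float))
        self.c = _as_array(cases)
        self.n = np.asarray(offsets, dtype=float)
        self.c_total = float(self.c.sum())
        self._pos = self.c > 0
        self._clogn = float(np.sum(self.c[self._pos] * np.log(self.n[self._pos])))
        self.rows2 = self.rows * self.rows
        self._n_sum = float(self.n.sum())
        self._nd = self.rows @ self.n
        self._nd2 = self.rows2 @ self.n

    def _row_terms(self, alpha: float, beta: float):
        rr = 1.0 + alpha * self.rows + beta * self.rows2
        feasible = rr.min(axis=1) > RR_EPS
        if not np.any(feasible):
            return None
        if self._pos.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                a = np.log(rr[:, self._pos]) @ self.c[self._pos]
            a = a[feasible]
        else:
            a = np.zeros(int(feasible.sum()))
        s = self._n_sum + alpha * self._nd[feasible] + beta * self._nd2[feasible]
        return self.logw[feasible] + a, s

    def loglik(self, theta0: float, alpha: float, beta: float) -> float:
        terms = self._row_terms(alpha, beta)
        if terms is None:
            return -np.inf
        base, s = terms
        z = base + self.c_total * theta0 + self._clogn - math.exp(theta0) * s
        zmax = z.max()
        return float(zmax + np.log(np.sum(np.exp(z - zmax))))

    def _profile_theta0(self, base: np.ndarray, s: np.ndarray) -> float:
        """Solve the intercept score equation C/phi = <S>_w by Newton in
        phi = exp(theta0); the weights w are the realisation posteriors."""
        if self.c_total == 0.0:
            return -np.inf
        c = self.c_total
        w0 = np.exp(base - base.max())
        phi = c * w0.sum() / float(np.dot(w0, s))
        for _ in range(100):
            z = base + c * math.log(phi) - phi * s
            w = np.exp(z - z.max())
            w /= w.sum()
            s_mean = float(np.dot(w, s))
            h = c / phi - s_mean
            # score tolerance chosen so the profiled log-likelihood is
            # accurate to ~1e-10 (quadratic in the intercept error)
            if abs(h) * phi < 1e-7 * c:
                return math.log(phi)
            s_var = float(np.dot(w, (s - s_mean) ** 2))
            hprime = -c / (phi * phi) + s_var
            step = h / hprime if hprime < 0 else -h * phi / c
            new = phi - step
            phi = new if new > 0 else phi / 2.0
        # safeguarded fallback: 1-D bounded maximisation around last iterate
        theta0 = math.log(phi)
        obj = lambda t: -(
            (lambda zz: zz.max() + np.log(np.sum(np.exp(zz - zz.max()))))(
                base + c * t - math.exp(t) * s
            )
        )
        res = optimize.minimize_scalar(
            obj, bounds=(theta0 - 10.0, theta0 + 10.0), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    def profiled(self, alpha: float, beta: float) -> tuple[float, float]:
        terms = self._row_terms(alpha, beta)
        if terms is None:
            return -np.inf, math.nan
        base, s = terms
        if self.c_total == 0.0:
            return 0.0, -np.inf
        theta0 = self._profile_theta0(base, s)
        z = base + self.c_total * theta0 + self._clogn - math.exp(theta0) * s
        zmax = z.max()
        return float(zmax + np.log(np.sum(np.exp(z - zmax)))), theta0

    def other_lower_bound(self, target: str, value: float) -> float:
        # at least one realisation row must stay feasible
        if target == "alpha":
            bounds = np.max((RR_EPS - 1.0 - value * self.rows) / self.rows2, axis=1)
        else:
            bounds = np.max((RR_EPS - 1.0 - value * self.rows2) / self.rows, axis=1)
        return float(bounds.min())


# ---------------------------------------------------------------------------
# Maximisation and profile intervals
# ---------------------------------------------------------------------------


def _maximise(lik) -> tuple[LQParams, float, bool]:
    """Nelder-Mead over (alpha, beta) with the intercept profiled, plus a
    deterministic restart schedule and a final polish restart."""

    def objective(x):
        ll, _ = lik.profiled(x[0], x[1])
        return -ll if np.isfinite(ll) else 1e15

    best = None
    for start in _STARTS:
        res = optimize.minimize(
            objective,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            break
    # polish: restart from the optimum to rebuild the simplex
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000, "maxfev": 4000},
    )
    if polish.fun <= best.fun:
        best = polish
    alpha, beta = float(best.x[0]), float(best.x[1])
    ll, theta0 = lik.profiled(alpha, beta)
    converged = bool(best.success or polish.success) and np.isfinite(ll)
    return LQParams(log_baseline=theta0, alpha=alpha, beta=beta), float(ll), converged


def _inner_profile(lik, target: str, value: float, warm: float) -> float:
    """max over the nuisance coefficient of the (intercept-profiled)
    log-likelihood, with ``target`` fixed at ``value``."""
    lo = lik.other_lower_bound(target, value) + 1e-9

    def f(o):
        if target == "alpha":
            ll, _ = lik.profiled(value, o)
        else:
            ll, _ = lik.profiled(o, value)
        return -ll if np.isfinite(ll) else 1e15

    hi = max(abs(warm) * 4.0 + 10.0, lo + 1.0)
    for _ in range(4):
        x, fval, _, _ = optimize.fminbound(
            f, lo, hi, xtol=1e-6, full_output=True, disp=0
        )
        if x < hi - 1e-3 * (hi - lo) or hi >= _PROFILE_CAP:
            break
        hi = min(hi * 10.0, _PROFILE_CAP)
    return -fval


def _profile_interval(
    lik, target: str, params: LQParams, ll_max: float, level: float
) -> tuple[tuple[float, float], dict[str, bool]]:
    threshold = float(chi2.ppf(level, 1))
    t_hat = params.alpha if target == "alpha" else params.beta
    o_hat = params.beta if target == "alpha" else params.alpha
    flags: dict[str, bool] = {}
    limits: dict[str, float] = {}

    for side, direction in (("lower", -1.0), ("upper", 1.0)):

        def g(t):
            inner = _inner_profile(lik, target, t, o_hat)
            # the profile cannot exceed the joint maximum; clipping guards
            # against small inner-optimiser inconsistencies near the MLE
            return 2.0 * (ll_max - min(inner, ll_max)) - threshold

        step = 0.25 * (abs(t_hat) + 0.2)
        prev_t = t_hat
        prev_g = g(t_hat)
        crossed = False
        if prev_g < 0.0:
            for _ in range(60):
                t = prev_t + direction * step
                if abs(t) > _PROFILE_CAP:
                    break
                g_t = g(t)
                if g_t >= 0.0:
                    limit = optimize.brentq(
                        g, min(prev_t, t), max(prev_t, t), xtol=1e-8
                    )
                    limits[side] = float(limit)
                    flags[f"{target}_{side}"] = False
                    crossed = True
                    break
                prev_t = t
                step *= 2.0
        if not crossed:
            limits[side] = float(prev_t)
            flags[f"{target}_{side}"] = True
    return (limits["lower"], limits["upper"]), flags


def _fit(lik, label: str, level: float = 0.95, compute_ci: bool = True) -> FitResult:
    params, ll, converged = _maximise(lik)
    result = FitResult(method=label, params=params, loglik=ll, converged=converged)
    if compute_ci and converged:
        ci_a, flags_a = _profile_interval(lik, "alpha", params, ll, level)
        ci_b, flags_b = _profile_interval(lik, "beta", params, ll, level)
        result.ci_alpha = ci_a
        result.ci_beta = ci_b
        result.boundary_flags = {**flags_a, **flags_b}
    elif compute_ci:
        result.boundary_flags = {
            "alpha_lower": True,
            "alpha_upper": True,
            "beta_lower": True,
            "beta_upper": True,
        }
    return result


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------


def grouped_loglik(params: LQParams, group_doses, cases, offsets) -> float:
    """Grouped Poisson linear-relative-risk log-likelihood (no factorial term)."""
    lik = _GroupedLik(group_doses, cases, offsets)
    return lik.loglik(params.log_baseline, params.alpha, params.beta)


def fit_ml(
    group_doses,
    cases,
    offsets,
    *,
    label: str = "ml",
    level: float = 0.95,
    compute_ci: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the grouped model at fixed working doses."""
    lik = _GroupedLik(group_doses, cases, offsets)
    return _fit(lik, label, level=level, compute_ci=compute_ci)


def profile_ci(
    target: str, group_doses, cases, offsets, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood interval for ``alpha``, ``beta`` or ``log_baseline``."""
    lik = _GroupedLik(group_doses, cases, offsets)
    params, ll, converged = _maximise(lik)
    if not converged:
        raise RuntimeError("maximum-likelihood fit did not converge")
    if target in ("alpha", "beta"):
        interval, _ = _profile_interval(lik, target, params, ll, level)
        return interval
    if target != "log_baseline":
        raise ValueError(f"unknown target {target!r}")
    # profile the intercept, maximising over (alpha, beta)
    threshold = float(chi2.ppf(level, 1))

    def inner(theta0: float) -> float:
        res = optimize.minimize(
            lambda x: -lik.loglik(theta0, x[0], x[1]),
            np.array([params.alpha, params.beta]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12},
        )
        return -float(res.fun)

    def g(theta0: float) -> float:
        return 2.0 * (ll - inner(theta0)) - threshold

    limits = []
    for direction in (-1.0, 1.0):
        step, prev = 0.25, params.log_baseline
        for _ in range(60):
            t = prev + direction * step
            if g(t) >= 0.0:
                limits.append(
                    optimize.brentq(g, min(prev, t), max(prev, t), xtol=1e-10)
                )
                break
            prev = t
            step *= 2.0
        else:
            raise RuntimeError("profile search for log_baseline failed")
    return (float(limits[0]), float(limits[1]))


def fit_unadjusted(
    surrogate: SurrogateDoseVector, cases, cohort: Cohort, level: float = 0.95
) -> FitResult:
    """Fit at the group means of a single surrogate-dose draw."""
    doses = collapse_to_groups(surrogate.doses, cohort)
    lik = _GroupedLik(doses, cases, cohort.persons)
    return _fit(lik, "unadjusted", level=level)


def fit_regression_calibration(
    realisations: RealisationSet, cases, cohort: Cohort, level: float = 0.95
) -> FitResult:
    """Fit at the realisation-averaged group-mean true doses."""
    lik = _GroupedLik(realisations.mean_doses, cases, cohort.persons)
    return _fit(lik, "rc", level=level)


def erc_adjusted_loglik(params: LQParams, realisations: RealisationSet, cases, offsets) -> float:
    """RC log-likelihood plus the second-order covariance adjustment."""
    lik = _ERCLik(realisations.mean_doses, realisations.covariance, cases, offsets)
    return lik.loglik(params.log_baseline, params.alpha, params.beta)


def fit_extended_rc(
    realisations: RealisationSet, cases, cohort: Cohort, level: float = 0.95
) -> FitResult:
    """Maximise the covariance-adjusted likelihood; profile CIs on it too."""
    lik = _ERCLik(
        realisations.mean_doses, realisations.covariance, cases, cohort.persons
    )
    return _fit(lik, "erc", level=level)


def mcml_loglik(params: LQParams, realisations: RealisationSet, cases, offsets) -> float:
    """log of the realisation-averaged likelihood (log-sum-exp, stable)."""
    rows, weights = realisations.unique_rows()
    lik = _MCMLLik(rows, weights, cases, offsets)
    return lik.loglik(params.log_baseline, params.alpha, params.beta)


def fit_mcml(
    realisations: RealisationSet, cases, cohort: Cohort, level: float = 0.95
) -> FitResult:
    """Maximise the marginal likelihood; profile CIs on it too.

    With a single distinct realisation row the marginal likelihood *is*
    the grouped likelihood at that row, so the fit is routed through the
    closed-form-intercept path and coincides bit-for-bit with RC in
    classical-only scenarios.
    """
    rows, weights = realisations.unique_rows()
    if rows.shape[0] == 1:
        lik = _GroupedLik(rows[0], cases, cohort.persons)
    else:
        lik = _MCMLLik(rows, weights, cases, cohort.persons)
    return _fit(lik, "mcml", level=level)
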