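"""Group-comparison regressions: beta (odds ratios) and negative binomial (rate ratios).

Relative frequencies are compositional percentages; after rescaling to
(0, 1) they are modelled by beta regression with a logit mean link and a
constant precision phi:

    y ~ Beta(mu * phi, (1 - mu) * phi),   logit(mu) = b0 + b1 * group

so exp(b1) is the odds ratio of the expected frequency between immunized
and control mice.  Absolute counts are modelled by NB2 negative-binomial
regression with a log link and dispersion k (variance mu + mu^2/k); exp(b1)
is the rate ratio.  Both likelihoods are maximized by quasi-Newton ascent
with analytic gradients; Wald standard errors come from the observed
information (finite differences of the analytic gradient at the optimum).
Two-sided p-values use the normal approximation of the z statistic.

Fits are produced pooled and, optionally, stratified by sex.  A classical
variance F-test for two samples is included for spread comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass
class RegressionFit:
    model: str  # "beta" | "negative_binomial"
    response: str
    stratum: str  # "all" | "F" | "M"
    coefficients: np.ndarray  # (intercept, group, ...)
    standard_errors: np.ndarray
    effect: float  # odds ratio (beta) or rate ratio (NB)
    z: float
    p: float
    precision_or_dispersion: float  # phi (beta) or k (NB)
    log_likelihood: float
    ll_null: float  # intercept-only log-likelihood (same dispersion family)
    converged: bool
    n: int

    @property
    def conf_int(self) -> tuple[float, float]:
        se = self.standard_errors[1]
        return (self.effect * np.exp(-1.96 * se), self.effect * np.exp(1.96 * se))


def squeeze_proportions(y_percent: np.ndarray, n: int) -> np.ndarray:
    """Map percentages in [0, 100] strictly inside (0, 1).

    The boundary-compression transform y' = (y/100 * (n-1) + 0.5) / n keeps
    interior values nearly unchanged while the beta likelihood stays finite
    at observed 0% and 100% cells.
    """
    y = np.asarray(y_percent, dtype=float)
    if np.any(y < 0) or np.any(y > 100):
        raise ValueError("percentages must lie in [0, 100]")
    return (y / 100.0 * (n - 1) + 0.5) / n


def _hessian_fd(grad, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps * max(1.0, abs(theta[j]))
        H[:, j] = (grad(theta + step) - grad(theta - step)) / (2 * step[j])
    return (H + H.T) / 2.0


def _beta_loglik_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    eta = X @ beta
    mu = special.expit(eta)
    a, b = mu * phi, (1.0 - mu) * phi
    ystar = np.log(y) - np.log1p(-y)  # logit(y)
    ll = np.sum(special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    mustar = special.digamma(a) - special.digamma(b)
    g_beta = X.T @ (phi * mu * (1.0 - mu) * (ystar - mustar))
    g_logphi = phi * np.sum(special.digamma(phi) - mu * special.digamma(a)
                            - (1.0 - mu) * special.digamma(b)
                            + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
    return ll, np.append(g_beta, g_logphi)


def _nb_loglik_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    beta, logk = theta[:-1], theta[-1]
    k = np.exp(logk)
    mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
    ll = np.sum(special.gammaln(y + k) - special.gammaln(k) - special.gammaln(y + 1.0)
                + k * (np.log(k) - np.log(k + mu)) + y * (np.log(mu) - np.log(k + mu)))
    g_beta = X.T @ ((y - mu) * k / (k + mu))
    dk = np.sum(special.digamma(y + k) - special.digamma(k)
                + np.log(k) + 1.0 - np.log(k + mu) - (y + k) / (k + mu))
    return ll, np.append(g_beta, k * dk)


def _maximize(loglik_grad, theta0: np.ndarray, X: np.ndarray, y: np.ndarray):
    def neg(theta):
        ll, g = loglik_grad(theta, X, y)
        return -ll, -g

    res = optimize.minimize(neg, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    # Newton polish: drive the gradient toward machine precision so the
    # optimum (and Wald quantities derived from it) is parameterization-exact
    theta = res.x
    ll, g = loglik_grad(theta, X, y)
    gnorm = np.linalg.norm(g, np.inf)
    for _ in range(40):
        if gnorm < 1e-12 * max(1.0, abs(ll)):
            break
        H = _hessian_fd(lambda t: loglik_grad(t, X, y)[1], theta)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        new = theta + step
        ll_new, g_new = loglik_grad(new, X, y)
        ok = np.isfinite(ll_new) and np.all(np.isfinite(g_new))
        if not ok or np.linalg.norm(g_new, np.inf) >= gnorm:
            break
        theta, ll, g = new, ll_new, g_new
        gnorm = np.linalg.norm(g, np.inf)
    res.x = theta
    res.fun = -ll
    return res


def _fit_one(model: str, y: np.ndarray, group: np.ndarray, response: str,
             stratum: str) -> RegressionFit:
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), group])

    if model == "beta":
        loglik_grad = _beta_loglik_grad
        m0, m1 = y[group == 0].mean(), y[group == 1].mean()
        b0 = special.logit(np.clip(m0, 1e-4, 1 - 1e-4))
        b1 = special.logit(np.clip(m1, 1e-4, 1 - 1e-4)) - b0
        v = max(y.var(), 1e-6)
        phi0 = max(y.mean() * (1 - y.mean()) / v - 1.0, 1.0)
        theta0 = np.array([b0, b1, np.log(phi0)])
        null0 = np.array([special.logit(np.clip(y.mean(), 1e-4, 1 - 1e-4)), np.log(phi0)])
    elif model == "negative_binomial":
        loglik_grad = _nb_loglik_grad
        m0 = max(y[group == 0].mean(), 0.5)
        m1 = max(y[group == 1].mean(), 0.5)
        v = max(y.var(), y.mean() + 1e-6)
        k0 = y.mean() ** 2 / max(v - y.mean(), 1e-6)
        k0 = float(np.clip(k0, 0.01, 1e4))
        theta0 = np.array([np.log(m0), np.log(m1) - np.log(m0), np.log(k0)])
        null0 = np.array([np.log(max(y.mean(), 0.5)), np.log(k0)])
    else:
        raise ValueError(f"unknown model {model!r}")

    res = _maximize(loglik_grad, theta0, X, y)
    theta = res.x
    ll = -res.fun
    # convergence is judged at the polished optimum, not by the quasi-Newton
    # stage's own status flag
    _, g_final = loglik_grad(theta, X, y)
    grad_ok = np.linalg.norm(g_final, np.inf) < 1e-4 * max(1.0, abs(ll))

    # intercept-only fit of the same family for the likelihood-ascent check
    X0 = X[:, :1]
    res0 = _maximize(loglik_grad, null0, X0, y)
    ll_null = -res0.fun

    H = _hessian_fd(lambda t: loglik_grad(t, X, y)[1], theta)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        se_ok = np.all(np.isfinite(se[:2])) and se[1] > 0
    except np.linalg.LinAlgError:
        se = np.full(theta.size, np.nan)
        se_ok = False

    z = theta[1] / se[1] if se_ok else float("nan")
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return RegressionFit(
        model=model,
        response=response,
        stratum=stratum,
        coefficients=theta[:-1],
        standard_errors=se[:-1],
        effect=float(np.exp(theta[1])),
        z=float(z),
        p=p,
        precision_or_dispersion=float(np.exp(theta[-1])),
        log_likelihood=float(ll),
        ll_null=float(ll_null),
        converged=bool(grad_ok and se_ok),
        n=n,
    )


def _strata(stratify_by_sex: bool, sex: Optional[np.ndarray]):
    yield "all", slice(None)
    if stratify_by_sex:
        if sex is None:
            raise ValueError("stratify_by_sex=True requires the sex vector")
        sex = np.asarray(sex)
        for s in ("F", "M"):
            yield s, sex == s


def _fit_strata(model: str, y, group, sex, stratify_by_sex, response) -> list[RegressionFit]:
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    fits = []
    for stratum, mask in _strata(stratify_by_sex, sex):
        ys, gs = y[mask], group[mask]
        if len(np.unique(gs)) < 2:
            import warnings
            warnings.warn(f"stratum {stratum!r} lacks both groups; skipped", stacklevel=3)
            continue
        fits.append(_fit_one(model, ys, gs, response, stratum))
    return fits


def fit_beta_regression(y, group, sex=None, stratify_by_sex: bool = False,
                        response: str = "") -> list[RegressionFit]:
    """Beta regression of proportions on group; exp(group coef) = odds ratio.

    ``y`` must lie strictly inside (0, 1) — rescale percentages with
    :func:`squeeze_proportions` first.  Returns the pooled fit, plus
    per-sex fits when ``stratify_by_sex``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("beta regression needs y strictly inside (0, 1)")
    return _fit_strata("beta", y, group, sex, stratify_by_sex, response)


def fit_negbin_regression(counts, group, sex=None, stratify_by_sex: bool = False,
                          response: str = "") -> list[RegressionFit]:
    """NB2 regression of counts on group; exp(group coef) = rate ratio."""
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(y, np.round(y)):
        import warnings
        warnings.warn("non-integer counts rounded before fitting", stacklevel=2)
        y = np.round(y)
    return _fit_strata("negative_binomial", y, group, sex, stratify_by_sex, response)


def wald_report(fits: list[RegressionFit]) -> pd.DataFrame:
    """Tidy significance table: effect, 95% CI, z, p and significance stars."""
    rows = []
    for f in fits:
        if not f.converged:
            continue
        lo, hi = f.conf_int
        stars = "**" if f.p < 0.01 else "*" if f.p < 0.05 else ""
        rows.append({
            "model": f.model, "response": f.response, "stratum": f.stratum,
            "effect": f.effect, "ci_low": lo, "ci_high": hi,
            "z": f.z, "p": f.p, "significance": stars, "n": f.n,
        })
    return pd.DataFrame(rows)


def f_test_variance(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided variance-ratio F-test.

    F is the larger sample variance over the smaller (so F >= 1) with
    degrees of freedom ordered to match; the two-sided p doubles the upper
    tail, capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        F, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    return float(F), float(p)


def regress_cohort(cohort, tissues=None, stratify_by_sex: bool = False) -> pd.DataFrame:
    """Fit every marker × tissue: beta for frequencies, NB for counts.

    Returns the concatenated Wald report over all converged fits.
    """
    from immunosig.synthetic import CohortDataset  # local import avoids a cycle

    assert isinstance(cohort, CohortDataset)
    meta = {m.mouse_id: m for m in cohort.mice}
    frames: dict[tuple[str, str, str], dict[str, float]] = {}
    for meas in cohort.measurements:
        if meas.value_type not in ("frequency_percent", "count"):
            continue
        if tissues is not None and meas.tissue not in tissues:
            continue
        frames.setdefault((meas.tissue, meas.marker, meas.value_type), {})[meas.mouse_id] = meas.value

    all_fits: list[RegressionFit] = []
    for (tissue, marker, vtype), values in sorted(frames.items()):
        ids = sorted(values)
        y = np.array([values[i] for i in ids])
        group = np.array([1 if meta[i].group == "immunized" else 0 for i in ids])
        sex = np.array([meta[i].sex for i in ids])
        if len(np.unique(group)) < 2 or y.size < 6:
            continue
        label = f"{tissue}:{marker}"
        try:
            if vtype == "frequency_percent":
                yp = squeeze_proportions(y, y.size)
                fits = fit_beta_regression(yp, group, sex, stratify_by_sex, response=label + "%")
            else:
                fits = fit_negbin_regression(y, group, sex, stratify_by_sex, response=label + "#")
        except (ValueError, np.linalg.LinAlgError):
            continue
        all_fits.extend(fits)
    return wald_report(all_fits)
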