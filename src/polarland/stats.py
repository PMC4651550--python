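"""Statistical procedures of the land-use comparison.

Everything operates either on module outputs or directly on printed summary
statistics (counts, means, SDs), so each published comparison can be
recomputed without the underlying location data: two-group binary logistic
regression from 2x2 counts, one-way ANOVA from group summaries, ordinary
least squares, conditional (stratified) logistic regression for the
use-availability design, AIC ranking and Pearson chi-square contingency
tests.  Wald inference throughout; significance is assessed at 0.05 without
multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp


@dataclass
class FitResult:
    """A fitted comparison: coefficients, test statistic, p-value, fit scores."""

    label: str
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    statistic: float | None = None
    statistic_name: str | None = None  # "F", "z", "chi2"
    df: tuple | None = None
    pvalue: float | None = None
    r2: float | None = None
    loglik: float | None = None
    n_params: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float | None:
        if self.loglik is None or self.n_params is None:
            return None
        return 2 * self.n_params - 2 * self.loglik

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coef": self.coef,
            "se": self.se,
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "df": self.df,
            "pvalue": self.pvalue,
            "r2": self.r2,
            "loglik": self.loglik,
            "aic": self.aic,
            "warnings": self.warnings,
        }


def logistic_two_group(k1: int, n1: int, k2: int, n2: int, label: str = "") -> FitResult:
    """Two-group binary logistic regression from counts.

    The slope is the log odds ratio of group 2 versus group 1 and its SE is
    the Woolf formula sqrt(1/k1 + 1/(n1-k1) + 1/k2 + 1/(n2-k2)); both equal
    the maximum-likelihood logistic-regression estimates on the expanded
    0/1 data.  Zero cells are flagged as (quasi-)separation and yield a
    non-finite estimate rather than a silently penalised one.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    if (k1 in (0, n1)) and (k2 in (0, n2)):
        raise ValueError("both groups degenerate: slope undefined")
    res = FitResult(label=label or "two-group logistic")
    cells = [k1, n1 - k1, k2, n2 - k2]
    if 0 in cells:
        # odds ratio diverges: +inf when group 1 odds vanish or group 2 odds
        # explode, -inf in the mirror cases
        sign = 1.0 if (k1 == 0 or n2 - k2 == 0) else -1.0
        res.coef["slope"] = sign * math.inf
        res.se["slope"] = math.inf
        res.warnings.append("zero cell: estimate is non-finite (separation)")
        return res
    slope = math.log((k2 / (n2 - k2)) / (k1 / (n1 - k1)))
    se = math.sqrt(sum(1.0 / c for c in cells))
    z = slope / se
    res.coef["intercept"] = math.log(k1 / (n1 - k1))
    res.coef["slope"] = slope
    res.se["slope"] = se
    res.statistic = z
    res.statistic_name = "z"
    res.pvalue = 2 * stats.norm.sf(abs(z))
    p1, p2 = k1 / n1, k2 / n2
    res.loglik = sum(
        k * math.log(p) + (n - k) * math.log(1 - p)
        for k, n, p in ((k1, n1, p1), (k2, n2, p2))
    )
    res.n_params = 2
    return res


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    label: str = "",
) -> FitResult:
    """One-way two-group ANOVA from group means, SDs and sizes.

    Uses the pooled variance; F on (1, n1+n2-2) df equals the square of the
    equal-variance two-sample t statistic.  The difference (group2 - group1)
    is reported with its pooled SE.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df2 = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df2
    diff = mean2 - mean1
    res = FitResult(label=label or "two-group ANOVA")
    if sp2 == 0:
        res.coef["diff"] = diff
        res.se["diff"] = 0.0
        res.statistic = math.inf if diff != 0 else 0.0
        res.statistic_name = "F"
        res.df = (1, df2)
        res.pvalue = 0.0 if diff != 0 else 1.0
        res.warnings.append("zero pooled variance")
        return res
    se_diff = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    F = (diff / se_diff) ** 2
    res.coef["diff"] = diff
    res.se["diff"] = se_diff
    res.statistic = F
    res.statistic_name = "F"
    res.df = (1, df2)
    res.pvalue = float(stats.f.sf(F, 1, df2))
    return res


def linear_regression(x, y, label: str = "") -> FitResult:
    """Ordinary least squares y = a + b x with Wald slope inference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df = n - 2
    s2 = ss_res / df if df > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se_b = math.sqrt(cov[1, 1])
    res = FitResult(label=label or "linear regression")
    res.coef = {"intercept": float(coef[0]), "slope": float(coef[1])}
    res.se = {"slope": se_b}
    if se_b > 0:
        tstat = coef[1] / se_b
        res.statistic = float(tstat**2)
        res.statistic_name = "F"
        res.df = (1, df)
        res.pvalue = float(stats.f.sf(res.statistic, 1, df))
    else:
        res.pvalue = 0.0
        res.warnings.append("exact fit: zero residual variance")
    res.r2 = r2
    return res


@dataclass
class UseAvailStratum:
    """One bear-year: the used coastal segment plus available segments.

    `covariates` has one row per record; exactly one record has used = 1.
    """

    stratum_id: str
    used: np.ndarray  # 0/1 per record
    covariates: np.ndarray  # (n_records, n_covariates)

    def __post_init__(self) -> None:
        self.used = np.asarray(self.used, int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
        if self.used.sum() != 1:
            raise ValueError("exactly one used record per stratum")


def _cl_nll_grad_hess(beta, strata):
    nll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    for s in strata:
        eta = s.covariates @ beta
        lse = logsumexp(eta)
        p = np.exp(eta - lse)
        xu = s.covariates[np.argmax(s.used)]
        nll -= float(xu @ beta - lse)
        xbar = p @ s.covariates
        grad -= xu - xbar
        xc = s.covariates - xbar
        hess += (xc * p[:, None]).T @ xc
    return nll, grad, hess


def conditional_logistic(
    strata: list[UseAvailStratum],
    names: list[str] | None = None,
    label: str = "",
) -> FitResult:
    """Conditional logistic regression for the use-availability design.

    Maximises the exact stratified conditional likelihood
    prod_s exp(x_used beta) / sum_j exp(x_j beta) by Newton iterations with
    analytic gradient and Hessian; Wald SEs come from the observed
    information.  Covariates with no within-stratum variation anywhere are
    unidentifiable and flagged.
    """
    if not strata:
        raise ValueError("no strata")
    p = strata[0].covariates.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    informative = [s for s in strata if len(s.used) >= 2]
    if not informative:
        raise ValueError("need at least one stratum with >= 2 alternatives")
    within_var = np.zeros(p)
    for s in informative:
        within_var += np.var(s.covariates, axis=0)
    res = FitResult(label=label or "conditional logistic")
    dead = np.nonzero(within_var == 0)[0]
    for j in dead:
        res.warnings.append(f"covariate {names[j]} constant within all strata: unidentifiable")
    live = np.nonzero(within_var > 0)[0]
    if len(live) == 0:
        for j in range(p):
            res.coef[names[j]] = float("nan")
            res.se[names[j]] = float("nan")
        return res

    sub = [
        UseAvailStratum(s.stratum_id, s.used, s.covariates[:, live])
        for s in informative
    ]
    beta = np.zeros(len(live))
    for _ in range(100):
        nll, grad, hess = _cl_nll_grad_hess(beta, sub)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta - step
        if np.max(np.abs(step)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    else:
        opt = optimize.minimize(
            lambda b: _cl_nll_grad_hess(b, sub)[0], beta, method="BFGS"
        )
        beta = opt.x
    nll, grad, hess = _cl_nll_grad_hess(beta, sub)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(len(live), np.nan)

    full_coef = np.full(p, np.nan)
    full_se = np.full(p, np.nan)
    full_coef[live] = beta
    full_se[live] = ses
    for j in range(p):
        res.coef[names[j]] = float(full_coef[j])
        res.se[names[j]] = float(full_se[j])
    res.loglik = -nll
    res.n_params = len(live)
    wald = (beta / ses) ** 2
    res.statistic = float(np.sum(wald))
    res.statistic_name = "chi2"
    res.df = (len(live),)
    res.pvalue = float(stats.chi2.sf(res.statistic, len(live)))
    return res


def aic_compare(fits: list[FitResult]) -> list[dict]:
    """Rank fits by AIC; ties break toward fewer parameters.

    Returns records with label, AIC, delta AIC and rank.
    """
    if not fits:
        return []
    for f in fits:
        if f.aic is None:
            raise ValueError(f"fit {f.label!r} has no log-likelihood/AIC")
    amin = min(f.aic for f in fits)
    order = sorted(fits, key=lambda f: (f.aic, f.n_params))
    return [
        {
            "label": f.label,
            "aic": f.aic,
            "delta_aic": f.aic - amin,
            "rank": i + 1,
            "n_params": f.n_params,
        }
        for i, f in enumerate(order)
    ]


def chi2_contingency(table, label: str = "") -> FitResult:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    res = FitResult(label=label or "contingency chi-square")
    res.statistic = float(chi2)
    res.statistic_name = "chi2"
    res.df = (int(dof),)
    res.pvalue = float(p)
    return res
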