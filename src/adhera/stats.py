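"""Adherence–outcome association models.

Follow-up is partitioned into possession-covered ("adherent") and uncovered
("non-adherent") person-periods.  Event counts are modeled with a
random-intercept Poisson regression — a log-linear model with a
log(person-days) offset and a patient-level normal random intercept, fitted
by adaptive Gauss–Hermite quadrature maximum likelihood — switching to a
negative-binomial response when the Pearson dispersion statistic exceeds a
threshold.  Period costs use a linear mixed model (REML); descriptive
group machinery provides ANOVA/Kruskal–Wallis with a normality gate,
Poisson/negative-binomial and logistic regressions across groups, and
standardized mean differences for covariate balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

ADHERENT_PERIOD = "adherent_period"
NONADHERENT_PERIOD = "nonadherent_period"


@dataclass(frozen=True)
class StatsConfig:
    quadrature_nodes: int = 15
    dispersion_threshold: float = 1.5
    alpha: float = 0.05


@dataclass
class AssociationResult:
    outcome: str
    effect: float  # rate ratio (count models) or mean cost difference (LMM)
    log_effect_se: float | None
    p_value: float
    family: str  # poisson_glmm | negbin_glmm | lmm | ols
    dispersion: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def rate_ratio(self) -> float:
        return self.effect


def build_person_periods(
    summaries,
    events: pd.DataFrame | None = None,
    costs: pd.DataFrame | None = None,
    followup_days: int = 365,
) -> pd.DataFrame:
    """Partition each patient's follow-up into adherent/non-adherent periods.

    ``summaries`` is the list of per-patient adherence summaries (their
    ``covered`` intervals drive the split).  ``events`` (patient_id,
    event_type, day) and ``costs`` (patient_id, day, cost) are assigned to
    the period containing their day; an event outside ``[0, followup)`` is
    an upstream bug and raises.  Person-days sum to ``followup_days`` for
    every patient.
    """
    event_types = (
        sorted(events["event_type"].unique()) if events is not None and len(events) else []
    )
    ev_groups = (
        dict(list(events.groupby("patient_id", sort=False))) if events is not None else {}
    )
    cost_groups = (
        dict(list(costs.groupby("patient_id", sort=False))) if costs is not None else {}
    )

    rows = []
    for s in summaries:
        periods: list[tuple[str, int, int]] = []
        cursor = 0
        for start, end in s.covered:
            if start > cursor:
                periods.append((NONADHERENT_PERIOD, cursor, start))
            periods.append((ADHERENT_PERIOD, start, end))
            cursor = end
        if cursor < followup_days:
            periods.append((NONADHERENT_PERIOD, cursor, followup_days))

        ev = ev_groups.get(s.patient_id)
        cs = cost_groups.get(s.patient_id)
        if ev is not None and len(ev):
            bad = ev[(ev["day"] < 0) | (ev["day"] >= followup_days)]
            if len(bad):
                raise ValueError(
                    f"event outside follow-up for patient {s.patient_id}: "
                    f"days {bad['day'].tolist()}"
                )
        for state, start, end in periods:
            rec = {
                "patient_id": s.patient_id,
                "state": state,
                "start": start,
                "end": end,
                "person_days": end - start,
            }
            for etype in event_types:
                if ev is None or not len(ev):
                    rec[f"count_{etype}"] = 0
                else:
                    sel = (
                        (ev["event_type"] == etype)
                        & (ev["day"] >= start)
                        & (ev["day"] < end)
                    )
                    rec[f"count_{etype}"] = int(sel.sum())
            if cs is not None and len(cs):
                sel = (cs["day"] >= start) & (cs["day"] < end)
                rec["cost"] = float(cs.loc[sel, "cost"].sum())
            elif costs is not None:
                rec["cost"] = 0.0
            rows.append(rec)
    return pd.DataFrame(rows)


def _aggregate_periods(periods: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Collapse to one row per patient × state (sufficient for the GLMM)."""
    col = outcome if outcome in periods.columns else f"count_{outcome}"
    if col not in periods.columns:
        raise KeyError(f"outcome {outcome!r} not found in the period table")
    agg = (
        periods.groupby(["patient_id", "state"], sort=True)
        .agg(count=(col, "sum"), person_days=("person_days", "sum"))
        .reset_index()
    )
    return agg[agg["person_days"] > 0]


def _poisson_logpmf(c, mu):
    return c * np.log(mu) - mu - gammaln(c + 1.0)


def _negbin_logpmf(c, mu, alpha):
    r = 1.0 / alpha
    return (
        gammaln(c + r)
        - gammaln(r)
        - gammaln(c + 1.0)
        + c * np.log(alpha * mu / (1.0 + alpha * mu))
        - r * np.log1p(alpha * mu)
    )


class _QuadratureGLMM:
    """Random-intercept count GLMM by adaptive Gauss–Hermite quadrature.

    Rows are grouped by ``patient``; the linear predictor is ``b0 + b1·x``
    with a log person-days offset and a normal random intercept per patient.
    """

    def __init__(self, count, x, log_offset, patient_index, n_patients,
                 family: str = "poisson", nodes: int = 15):
        self.c = np.asarray(count, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.off = np.asarray(log_offset, dtype=float)
        self.idx = np.asarray(patient_index)
        self.n_pat = n_patients
        self.family = family
        self.z, self.w = np.polynomial.hermite.hermgauss(nodes)

    def _patient_mode(self, eta0, sigma2, alpha):
        """Laplace mode and curvature of each patient's integrand."""
        u = np.zeros(self.n_pat)
        for _ in range(25):
            eta = eta0 + u[self.idx]
            mu = np.exp(eta)
            if self.family == "poisson":
                g_rows = self.c - mu
                h_rows = -mu
            else:
                denom = 1.0 + alpha * mu
                g_rows = (self.c - mu) / denom
                h_rows = -mu * (1.0 + alpha * self.c) / denom**2
            g = np.bincount(self.idx, g_rows, minlength=self.n_pat) - u / sigma2
            h = np.bincount(self.idx, h_rows, minlength=self.n_pat) - 1.0 / sigma2
            step = g / h
            u -= np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        return u, np.sqrt(-1.0 / h)

    def loglik(self, theta) -> float:
        b0, b1, log_sigma = theta[:3]
        sigma = np.exp(log_sigma)
        sigma2 = sigma**2
        alpha = np.exp(theta[3]) if self.family == "negbin" else 0.0
        eta0 = b0 + b1 * self.x + self.off
        u_hat, tau = self._patient_mode(eta0, sigma2, alpha)
        # u_q = u_hat + sqrt(2) tau z_q ; integrand weight sqrt(2) tau w_q e^{z^2}
        nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        eta = eta0[:, None] + nodes[self.idx]
        mu = np.exp(np.clip(eta, -700, 700))
        if self.family == "poisson":
            lp = _poisson_logpmf(self.c[:, None], mu)
        else:
            lp = _negbin_logpmf(self.c[:, None], mu, alpha)
        per_patient = np.zeros((self.n_pat, len(self.z)))
        for q in range(len(self.z)):
            per_patient[:, q] = np.bincount(self.idx, lp[:, q], minlength=self.n_pat)
        log_phi = -0.5 * nodes**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        log_w = (
            np.log(self.w)[None, :]
            + self.z[None, :] ** 2
            + np.log(np.sqrt(2.0) * tau)[:, None]
        )
        return float(logsumexp(per_patient + log_phi + log_w, axis=1).sum())

    def fit(self, theta0=None):
        k = 4 if self.family == "negbin" else 3
        if theta0 is None:
            base = np.log(max(self.c.sum(), 0.5) / np.exp(self.off).sum())
            theta0 = np.array([base, 0.0, np.log(0.5), np.log(0.5)])[:k]
        neg = lambda th: -self.loglik(th)  # noqa: E731
        res = minimize(
            neg,
            theta0,
            method="L-BFGS-B",
            bounds=[(None, None), (None, None), (-6.0, 3.0)]
            + ([(-6.0, 6.0)] if k == 4 else []),
        )
        return res


def _numeric_hessian(f, theta, eps=1e-4):
    k = len(theta)
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return hess


def fit_count_glmm(
    periods: pd.DataFrame,
    outcome: str,
    config: StatsConfig = StatsConfig(),
    family: str = "poisson",
) -> AssociationResult:
    """Rate ratio of non-adherent vs adherent person-time for one outcome.

    Fits ``count ~ adherence_state`` with a log person-days offset and a
    patient random intercept by adaptive-quadrature ML.  The returned
    ``effect`` is ``exp(state coefficient)``, the event-rate ratio in
    non-adherent relative to adherent periods.
    """
    agg = _aggregate_periods(periods, outcome)
    patients = pd.Categorical(agg["patient_id"])
    x = (agg["state"] == NONADHERENT_PERIOD).to_numpy(dtype=float)
    model = _QuadratureGLMM(
        agg["count"].to_numpy(),
        x,
        np.log(agg["person_days"].to_numpy(dtype=float)),
        patients.codes,
        len(patients.categories),
        family=family,
        nodes=config.quadrature_nodes,
    )
    if agg["count"].sum() == 0:
        return AssociationResult(
            outcome, np.nan, None, np.nan, f"{family}_glmm",
            converged=False, extra={"degenerate": "all-zero outcome"},
        )
    both = agg.groupby("patient_id")["state"].nunique()
    if (both == 2).sum() < 2:
        warnings.warn("fewer than 2 patients contribute both states")
    res = model.fit()
    theta = res.x
    hess = _numeric_hessian(lambda th: -model.loglik(th), theta)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    b1 = float(theta[1])
    zval = b1 / se if se and np.isfinite(se) and se > 0 else np.nan
    pval = 2 * sps.norm.sf(abs(zval)) if np.isfinite(zval) else np.nan
    if not res.success:
        warnings.warn(
            f"count GLMM did not converge (gradient norm "
            f"{np.linalg.norm(res.jac) if res.jac is not None else np.nan:.3g})"
        )
    extra = {"intercept": float(theta[0]), "sigma": float(np.exp(theta[2]))}
    if family == "negbin":
        extra["alpha"] = float(np.exp(theta[3]))
    return AssociationResult(
        outcome=outcome,
        effect=float(np.exp(b1)),
        log_effect_se=se,
        p_value=float(pval) if np.isfinite(zval) else np.nan,
        family=f"{family}_glmm",
        converged=bool(res.success),
        extra=extra | {"theta": theta, "loglik": -float(res.fun)},
    )


def pearson_dispersion(
    periods: pd.DataFrame, outcome: str, result: AssociationResult,
    config: StatsConfig = StatsConfig(),
) -> float:
    """Pearson χ²/df of the fitted Poisson GLMM, using EB conditional means.

    The denominator subtracts, besides the three structural parameters, the
    effective degrees of freedom spent by the empirical-Bayes random
    intercepts (per patient, the shrinkage weight of its posterior mode);
    without that correction the statistic is biased well below 1 under a
    correctly specified Poisson model.
    """
    agg = _aggregate_periods(periods, outcome)
    patients = pd.Categorical(agg["patient_id"])
    x = (agg["state"] == NONADHERENT_PERIOD).to_numpy(dtype=float)
    theta = result.extra["theta"]
    model = _QuadratureGLMM(
        agg["count"].to_numpy(),
        x,
        np.log(agg["person_days"].to_numpy(dtype=float)),
        patients.codes,
        len(patients.categories),
        nodes=config.quadrature_nodes,
    )
    sigma2 = np.exp(theta[2]) ** 2
    eta0 = theta[0] + theta[1] * x + model.off
    u_hat, _ = model._patient_mode(eta0, sigma2, 0.0)
    mu = np.exp(eta0 + u_hat[model.idx])
    info = np.bincount(model.idx, mu, minlength=model.n_pat)
    effective_re_df = float(np.sum(info / (info + 1.0 / sigma2)))
    df = max(len(agg) - 3 - effective_re_df, 1.0)
    return float(np.sum((model.c - mu) ** 2 / mu) / df)


def dispersion_switch(
    result: AssociationResult,
    periods: pd.DataFrame,
    config: StatsConfig = StatsConfig(),
) -> tuple[float, bool]:
    """Overdispersion check: Pearson χ²/df against the configured threshold."""
    stat = pearson_dispersion(periods, result.outcome, result, config)
    return stat, bool(stat > config.dispersion_threshold)


def fit_count_model(
    periods: pd.DataFrame, outcome: str, config: StatsConfig = StatsConfig()
) -> AssociationResult:
    """Poisson GLMM, switching to negative binomial on overdispersion."""
    res = fit_count_glmm(periods, outcome, config, family="poisson")
    if not res.converged and not np.isfinite(res.effect):
        return res
    stat, switch = dispersion_switch(res, periods, config)
    res.dispersion = stat
    if switch:
        nb = fit_count_glmm(periods, outcome, config, family="negbin")
        nb.dispersion = stat
        return nb
    return res


def fit_cost_lmm(
    periods: pd.DataFrame, config: StatsConfig = StatsConfig()
) -> AssociationResult:
    """Mean period-cost difference, non-adherent vs adherent (REML LMM).

    Falls back to fixed-effects-only OLS with a warning when the mixed fit
    is singular.
    """
    df = periods.copy()
    if "cost" not in df.columns:
        raise KeyError("periods need a 'cost' column")
    df["nonadherent"] = (df["state"] == NONADHERENT_PERIOD).astype(float)
    if df["cost"].nunique() == 1:
        return AssociationResult(
            "cost", 0.0, 0.0, np.nan, "lmm",
            extra={"note": "zero cost variance", "flagged": True},
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("cost ~ nonadherent", df, groups=df["patient_id"])
            fit = model.fit(reml=True)
        singular = (not fit.converged) or np.any(
            np.asarray(fit.cov_re).diagonal() < 1e-10
        )
        if not singular:
            return AssociationResult(
                "cost",
                float(fit.params["nonadherent"]),
                float(fit.bse["nonadherent"]),
                float(fit.pvalues["nonadherent"]),
                "lmm",
                extra={"re_var": float(np.asarray(fit.cov_re)[0, 0])},
            )
    except Exception:  # singular / numerical failure
        pass
    warnings.warn("singular mixed fit; falling back to fixed-effects OLS")
    ols = smf.ols("cost ~ nonadherent", df).fit()
    return AssociationResult(
        "cost",
        float(ols.params["nonadherent"]),
        float(ols.bse["nonadherent"]),
        float(ols.pvalues["nonadherent"]),
        "ols",
        extra={"fallback": True},
    )


@dataclass
class GroupComparison:
    method: str
    statistic: float
    df: float | None
    p_value: float
    excluded_groups: list = field(default_factory=list)


def group_compare(
    values,
    labels,
    kind: str,
    config: StatsConfig = StatsConfig(),
) -> GroupComparison:
    """Compare an outcome across adherence groups.

    ``kind='continuous'``: one-way ANOVA when every group passes a Shapiro
    normality check at α=0.05, otherwise Kruskal–Wallis.  ``kind='count'``:
    Poisson regression on group indicators (likelihood-ratio test), switched
    to negative binomial on Pearson overdispersion.  ``kind='binary'``:
    logistic regression likelihood-ratio test.  Groups with fewer than two
    observations are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = []
    names = []
    excluded = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if len(v) < 2:
            excluded.append(g)
            continue
        groups.append(v)
        names.append(g)
    if excluded:
        warnings.warn(f"excluding groups with n<2: {excluded}")
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")

    if kind == "continuous":
        normal = True
        for v in groups:
            sample = v if len(v) <= 5000 else v[:5000]
            if np.ptp(sample) == 0 or len(sample) < 3:
                continue
            if sps.shapiro(sample).pvalue < config.alpha:
                normal = False
                break
        if normal:
            stat, p = sps.f_oneway(*groups)
            stat = max(float(stat), 0.0)  # guard the degenerate all-equal case
            if not np.isfinite(p):
                n_obs = sum(len(v) for v in groups)
                p = sps.f.sf(stat, len(groups) - 1, n_obs - len(groups))
            return GroupComparison("anova", stat, float(len(groups) - 1), float(p), excluded)
        stat, p = sps.kruskal(*groups)
        return GroupComparison("kruskal_wallis", float(stat), float(len(groups) - 1), float(p), excluded)

    keep = np.isin(labels, names)
    y = values[keep]
    dummies = pd.get_dummies(pd.Series(labels[keep]).astype(str), drop_first=True)
    x_full = sm.add_constant(dummies.to_numpy(dtype=float))
    x_null = np.ones((len(y), 1))
    k_extra = x_full.shape[1] - 1

    if kind == "count":
        full = sm.GLM(y, x_full, family=sm.families.Poisson()).fit()
        disp = full.pearson_chi2 / full.df_resid if full.df_resid else 1.0
        fam_name = "poisson_regression"
        if disp > config.dispersion_threshold:
            aux = np.maximum((y - full.mu) ** 2 - full.mu, 0) / full.mu
            alpha = float(np.clip(sm.OLS(aux, full.mu).fit().params[0], 0.01, 10.0))
            family = sm.families.NegativeBinomial(alpha=alpha)
            fam_name = "negbin_regression"
        else:
            family = sm.families.Poisson()
        full = sm.GLM(y, x_full, family=family).fit()
        null = sm.GLM(y, x_null, family=family).fit()
    elif kind == "binary":
        full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit()
        null = sm.GLM(y, x_null, family=sm.families.Binomial()).fit()
        fam_name = "logistic_regression"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    lr = 2.0 * (full.llf - null.llf)
    p = sps.chi2.sf(max(lr, 0.0), k_extra)
    return GroupComparison(fam_name, float(lr), float(k_extra), float(p), excluded)


def _pair_smd_continuous(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    diff = abs(a.mean() - b.mean())
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means; SMD is infinite")
        return np.inf
    return float(diff / pooled)


def _pair_smd_categorical(a: pd.Series, b: pd.Series, levels) -> float:
    p1 = np.array([(a == lv).mean() for lv in levels[1:]])
    p2 = np.array([(b == lv).mean() for lv in levels[1:]])

    def cov(p):
        return np.diag(p) - np.outer(p, p)

    s = (cov(p1) + cov(p2)) / 2.0
    diff = p1 - p2
    if np.allclose(diff, 0):
        return 0.0
    try:
        return float(np.sqrt(diff @ np.linalg.solve(s, diff)))
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in categorical SMD; infinite")
        return np.inf


def compute_smd(values, labels) -> float:
    """Standardized mean difference across groups (max pairwise for >2).

    Numeric values use |mean₁ − mean₂| / pooled SD; categorical values use
    the Mahalanobis multinomial formulation (which reduces to the familiar
    two-proportion SMD for binary variables).
    """
    labels = np.asarray(labels)
    series = pd.Series(values)
    names = pd.unique(labels)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    numeric = pd.api.types.is_numeric_dtype(series)
    levels = sorted(series.unique().tolist(), key=str) if not numeric else None
    best = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = series[labels == names[i]]
            b = series[labels == names[j]]
            if numeric:
                smd = _pair_smd_continuous(
                    a.to_numpy(dtype=float), b.to_numpy(dtype=float)
                )
            else:
                smd = _pair_smd_categorical(a, b, levels)
            best = max(best, smd)
    return best
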