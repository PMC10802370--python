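"""Longitudinal statistics: FC-vs-age mixed models, growth and outcome
regressions, and multiplicity control.

The developmental model treats each connection's Fisher z as the dependent
variable with age as a categorical fixed effect (baseline = first visit,
one indicator per later visit), a random intercept per infant, and AR(1)
residual correlation across the ordered visits:

    z_ij = β0 + Σ_k β_k·1[age_ij = k] + b_i + ε_ij,
    b_i ~ N(0, σ_b²),  Corr(ε_ij, ε_ik) = ρ^|rank(j) − rank(k)|.

Estimation is restricted maximum likelihood; the age effect is a Wald
F-test on the age indicators with residual denominator degrees of freedom.
AR(1) distance is the rank of the visit in the canonical schedule, so a
skipped visit widens the gap. Only infants with at least two valid visits
enter the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .growth import delta_wlz

__all__ = [
    "LmmResult", "RegressionResult", "fit_fc_age_lmm", "bonferroni_threshold",
    "growth_fc_regression", "fdr_bh", "fc_outcome_regression",
]


@dataclass
class LmmResult:
    connection: str
    chromophore: str
    f_stat: float
    p_value: float                       # age-effect Wald F
    baseline: tuple[float, float, float]  # estimate, SE, p at the reference age
    changes: dict[float, tuple[float, float, float]]  # age → (estimate, SE, p)
    n_subjects: int
    n_obs: int
    sigma_b: float
    sigma_e: float
    rho: float
    converged: bool
    df_num: int = 0
    df_den: int = 0

    def to_row(self) -> dict:
        row = {"connection": self.connection, "chromophore": self.chromophore,
               "F": self.f_stat, "p": self.p_value,
               "baseline_beta": self.baseline[0], "baseline_se": self.baseline[1],
               "baseline_p": self.baseline[2],
               "n_subjects": self.n_subjects, "n_obs": self.n_obs}
        for age, (b, se, p) in self.changes.items():
            tag = f"change_{age:g}mo"
            row[f"{tag}_beta"], row[f"{tag}_se"], row[f"{tag}_p"] = b, se, p
        return row


@dataclass
class RegressionResult:
    outcome: str
    predictor: str
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    slope: float
    n: int
    covariates: tuple[str, ...] = ()
    p_fdr: float | None = None

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))

    def format(self) -> str:
        return (f"F({self.df[0]},{self.df[1]})={self.f_stat:.2f}, "
                f"p={self.p_value:.3g}, R^2={self.r_squared:.3f}")


def _reml_loglik(theta: np.ndarray, patterns: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                 p: int) -> float:
    """Negative REML log-likelihood. theta = (log σ_b², log σ_e², z(ρ)).

    ``patterns`` groups subjects sharing a visit pattern: (ranks, X, Y) with
    Y of shape (n_visits, n_subjects_in_pattern) — one Cholesky per pattern.
    """
    vb, ve = np.exp(np.clip(theta[0], -23, 8)), np.exp(np.clip(theta[1], -23, 8))
    rho = np.tanh(theta[2])
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    quad_parts = []
    for ranks, X, Y in patterns:
        m = Y.shape[1]
        R = rho ** np.abs(ranks[:, None] - ranks[None, :])
        V = vb + ve * R
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += m * 2 * np.log(np.diag(Lc)).sum()
        Xi = np.linalg.solve(Lc, X)
        Yi = np.linalg.solve(Lc, Y)
        xtvx += m * (Xi.T @ Xi)
        xtvy += Xi.T @ Yi.sum(axis=1)
        quad_parts.append((Xi, Yi))
    try:
        beta = np.linalg.solve(xtvx, xtvy)
        s, ld_xtvx = np.linalg.slogdet(xtvx)
        if s <= 0:
            return 1e12
    except np.linalg.LinAlgError:
        return 1e12
    quad = sum(float(np.sum((Yi - (Xi @ beta)[:, None]) ** 2)) for Xi, Yi in quad_parts)
    return 0.5 * (logdet + ld_xtvx + quad)


def _gls(theta: np.ndarray, patterns, p: int):
    vb, ve = np.exp(np.clip(theta[0], -23, 8)), np.exp(np.clip(theta[1], -23, 8))
    rho = np.tanh(theta[2])
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for ranks, X, Y in patterns:
        m = Y.shape[1]
        R = rho ** np.abs(ranks[:, None] - ranks[None, :])
        V = vb + ve * R
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            Vi = np.linalg.pinv(V)
        xtvx += m * (X.T @ Vi @ X)
        xtvy += X.T @ Vi @ Y.sum(axis=1)
    try:
        cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtvx)
    beta = cov @ xtvy
    return beta, cov


def fit_fc_age_lmm(fc: pd.DataFrame, connection: str, chromophore: str = "HbO2",
                   visit_ages: tuple[float, ...] | None = None,
                   min_visits: int = 2, fix_rho: float | None = None) -> LmmResult:
    """Fit the FC-vs-age mixed model for one connection.

    ``fc`` is the long table with columns subject, visit_age_months,
    connection, chromophore, z. Subjects with fewer than ``min_visits``
    valid visits are excluded before fitting.
    """
    d = fc[(fc["connection"] == connection) & (fc["chromophore"] == chromophore)].copy()
    if visit_ages is None:
        visit_ages = tuple(sorted(d["visit_age_months"].unique()))
    d = d[d["visit_age_months"].isin(visit_ages)]
    counts = d.groupby("subject")["visit_age_months"].nunique()
    keep = counts[counts >= min_visits].index
    d = d[d["subject"].isin(keep)]
    if d.empty or d["visit_age_months"].nunique() < 2:
        raise ValueError("need subjects with >=2 visits spanning >=2 age levels")

    ages = tuple(sorted(visit_ages))
    level = {a: k for k, a in enumerate(ages)}
    p = len(ages)
    by_pattern: dict[tuple, list[np.ndarray]] = {}
    n_subjects = 0
    for _, g in d.groupby("subject"):
        g = g.sort_values("visit_age_months")
        key = tuple(level[a] for a in g["visit_age_months"])
        by_pattern.setdefault(key, []).append(g["z"].to_numpy())
        n_subjects += 1
    patterns = []
    for key, ys in by_pattern.items():
        ranks = np.array(key, dtype=float)
        X = np.zeros((len(key), p))
        X[:, 0] = 1.0
        for r, k in enumerate(key):
            if k > 0:
                X[r, k] = 1.0
        patterns.append((ranks, X, np.column_stack(ys)))
    groups = patterns

    n_obs = sum(Y.size for _, _, Y in patterns)
    # moment-based starting values
    resid_var = float(d.groupby("visit_age_months")["z"].transform(lambda s: s - s.mean()).var())
    resid_var = max(resid_var, 1e-4)
    x0 = np.array([np.log(resid_var / 3), np.log(2 * resid_var / 3), np.arctanh(0.2)])
    if fix_rho is None:
        res = optimize.minimize(_reml_loglik, x0, args=(groups, p), method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
        theta = res.x
    else:
        zr = np.arctanh(np.clip(fix_rho, -1 + 1e-9, 1 - 1e-9))
        obj = lambda t2: _reml_loglik(np.array([t2[0], t2[1], zr]), groups, p)
        res = optimize.minimize(obj, x0[:2], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        theta = np.array([res.x[0], res.x[1], zr])
    beta, cov = _gls(theta, groups, p)

    df_den = n_obs - p
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * sps.t.sf(np.abs(t), df_den)
    # joint Wald F on the age indicators
    q = p - 1
    Lb = beta[1:]
    Lcov = cov[1:, 1:]
    f_stat = float(Lb @ np.linalg.solve(Lcov, Lb) / q)
    p_age = float(sps.f.sf(f_stat, q, df_den))

    changes = {ages[k]: (float(beta[k]), float(se[k]), float(pvals[k])) for k in range(1, p)}
    return LmmResult(
        connection=connection, chromophore=chromophore,
        f_stat=f_stat, p_value=p_age,
        baseline=(float(beta[0]), float(se[0]), float(pvals[0])),
        changes=changes, n_subjects=n_subjects, n_obs=n_obs,
        sigma_b=float(np.exp(theta[0] / 2)), sigma_e=float(np.exp(theta[1] / 2)),
        rho=float(np.tanh(theta[2])), converged=bool(res.success),
        df_num=q, df_den=df_den)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold α/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _ols_predictor_test(y: np.ndarray, x: np.ndarray,
                        covars: np.ndarray | None) -> tuple[float, tuple[int, int], float, float, float, int]:
    X = x[:, None] if covars is None else np.column_stack([x, covars])
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design (collinear predictor/covariates)")
    fit = sm.OLS(y, Xc).fit()
    t = fit.tvalues[1]
    df_den = int(fit.df_resid)
    f_stat = float(t ** 2)                       # partial F of the predictor, df1 = 1
    p = float(fit.pvalues[1])
    return f_stat, (1, df_den), p, float(fit.rsquared), float(fit.params[1]), int(fit.nobs)


def growth_fc_regression(fc: pd.DataFrame, growth: pd.DataFrame, connection: str,
                         interval: tuple[str, str], covariate: str = "none",
                         chromophore: str = "HbO2", fc_age_months: float = 24.0,
                         min_n: int = 10) -> RegressionResult:
    """OLS of FC(24 mo Fisher z) on an interval's ΔWLZ, optionally adjusted.

    ``covariate`` ∈ {"none", "WLZ_birth", "HCZ_7_14d"} (birth WLZ or 7/14-day
    head-circumference z, guarding against confounding by size at birth).
    """
    z24 = fc[(fc["connection"] == connection) & (fc["chromophore"] == chromophore)
             & (fc["visit_age_months"] == fc_age_months)].set_index("subject")["z"]
    dw = delta_wlz(growth, *interval)
    data = pd.concat([z24.rename("z"), dw.rename("dwlz")], axis=1)
    covars = None
    covariates: tuple[str, ...] = ()
    if covariate != "none":
        piv = growth.pivot_table(index="subject", columns="visit_label",
                                 values="wlz" if covariate == "WLZ_birth" else "hcz")
        col = "birth" if covariate == "WLZ_birth" else "7/14d"
        data["cov"] = piv[col] if col in piv.columns else np.nan
        covariates = (covariate,)
    data = data.dropna()
    if len(data) < min_n:
        raise ValueError(f"only {len(data)} complete cases (< {min_n})")
    if covariate != "none":
        covars = data[["cov"]].to_numpy()
    f, df, p, r2, slope, n = _ols_predictor_test(
        data["z"].to_numpy(), data["dwlz"].to_numpy(), covars)
    return RegressionResult(
        outcome=f"{connection} FC z at {fc_age_months:g} mo ({chromophore})",
        predictor=f"dWLZ {interval[0]}->{interval[1]}",
        f_stat=f, df=df, p_value=p, r_squared=r2, slope=slope, n=n,
        covariates=covariates)


def fc_outcome_regression(fc: pd.DataFrame, outcomes: pd.DataFrame, connection: str,
                          fc_age_months: float, outcome_group: str,
                          chromophore: str = "HbO2", min_n: int = 10) -> RegressionResult:
    """OLS of the preschool cognitive-flexibility score on FC z at one age,
    fitted separately per preschool group ("younger" or "older")."""
    grp = outcomes[outcomes["group"] == outcome_group]
    if grp.empty:
        raise ValueError(f"no outcome scores for group {outcome_group!r}")
    zfc = fc[(fc["connection"] == connection) & (fc["chromophore"] == chromophore)
             & (fc["visit_age_months"] == fc_age_months)].set_index("subject")["z"]
    data = pd.concat([grp.set_index("subject")["score"], zfc.rename("z")], axis=1).dropna()
    if len(data) < min_n:
        raise ValueError(f"only {len(data)} complete cases (< {min_n})")
    f, df, p, r2, slope, n = _ols_predictor_test(
        data["score"].to_numpy(), data["z"].to_numpy(), None)
    return RegressionResult(
        outcome=f"cognitive flexibility ({outcome_group} preschoolers)",
        predictor=f"{connection} FC z at {fc_age_months:g} mo ({chromophore})",
        f_stat=f, df=df, p_value=p, r_squared=r2, slope=slope, n=n)
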