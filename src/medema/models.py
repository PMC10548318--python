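"""Model fitting: hierarchical linear mixed models, penalized-spline
dose-response smooths, adherence logistic regression, FDR adjustment,
and simulation-based parameter-recovery reporting.

Model families
--------------
* Linear mixed models (gaussian): fixed-effect dose/habit predictors and
  covariates, with users nested in their continent of use — a random
  continent intercept plus per-user random intercepts (variance
  components).  Wald 95% CIs throughout.
* Generalized additive models: penalized cubic B-spline smooths of the
  outcome against cumulative session count, optionally stratified by a
  habit-level factor (one fit per level, mirroring per-level plotted
  curves), with parametric covariate adjustment and GCV-selected penalty.
* Logistic regression for adherence, reporting odds ratios per factor
  level against documented reference levels.

Every coefficient table carries Benjamini-Hochberg q-values computed
within that table (one FDR family per model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from . import features as ft
from . import outcomes as oc
from . import synthetic as syn
from .synthetic import ConfigError

__all__ = [
    "ModelSpec",
    "ModelResult",
    "RecoveryReport",
    "fdr_adjust",
    "fit_linear_mixed",
    "fit_nonlinear_mixed",
    "fit_adherence_logit",
    "recovery_report",
    "linear_recovery_study",
    "adherence_recovery_study",
    "nonlinear_recovery_study",
    "DEFAULT_MOOD_TERMS",
    "DEFAULT_ADHERENCE_TERMS",
]

# reference levels are documented per factor: the least-intensive habit
# level is the baseline against which odds ratios are reported
REFERENCE_LEVELS = {
    "days_per_week_level": "1",
    "days_since_last_level": "1",
    "length_bin": "5-10",
    "practice_types_bin": "1-4",
    "ratio_level": "0:1",
    "time_of_day": "night",
}

DEFAULT_MOOD_TERMS = (
    "baseline_mood",
    "session_count",
    "length_min_5",
    "days_per_week",
    "days_since_last",
    "extero_intero_ratio",
    "n_practice_types",
    "rating_score",
    "age",
)

DEFAULT_ADHERENCE_TERMS = (
    "C(days_per_week_level, Treatment('1'))",
    "C(length_bin, Treatment('5-10'))",
    "C(practice_types_bin, Treatment('1-4'))",
    "baseline_mood",
)


@dataclass
class ModelSpec:
    """Declarative description of one model fit."""

    outcome: str
    fixed_terms: Sequence[str] = ()
    smooth_terms: Sequence[tuple[str, str | None]] = ()   # (variable, by-factor)
    family: str = "gaussian"
    group_user: str = "user_id"
    group_continent: str | None = "continent"
    basis_df: int = 10
    alpha: float | None = None            # None -> GCV-selected penalty
    support_cutoff: float = 0.01          # relative-frequency session-axis cutoff
    min_level_rows: int = 50

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ConfigError(f"family must be gaussian or binomial, got {self.family!r}")

    def validate_columns(self, df: pd.DataFrame) -> None:
        import re

        for term in list(self.fixed_terms) + [v for v, _ in self.smooth_terms]:
            cols = re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term)
            named = [c for c in cols if c in df.columns]
            if not named and not {"C", "Treatment", "np"}.issuperset(cols):
                raise ConfigError(f"term {term!r} references no column of the feature table")


@dataclass
class ModelResult:
    """Coefficient table with CIs, p- and q-values, plus smooth grids."""

    table: pd.DataFrame                   # term, estimate, ci_low, ci_high, p, q
    smooths: dict[str, pd.DataFrame] = field(default_factory=dict)
    random_effects: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0
    n_users: int = 0
    converged: bool = True
    diagnostic: str = ""


@dataclass
class RecoveryReport:
    """Truth vs estimate diagnostics over seeded replicate fits."""

    per_parameter: pd.DataFrame           # parameter, truth, mean_estimate, bias, rmse, coverage
    n_replicates: int


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish_table(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["q"] = fdr_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Missing-ratio policy
# ---------------------------------------------------------------------------

def _prepare_ratio(df: pd.DataFrame, terms: list[str], missing: str = "indicator"
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Missing exteroceptive:interoceptive ratios (interoceptive count
    still zero): default keeps the rows with a zero-filled value plus a
    missingness indicator; ``missing="complete"`` drops them instead."""
    if "extero_intero_ratio" not in terms or "extero_intero_ratio" not in df.columns:
        return df, terms
    df = df.copy()
    if missing == "complete":
        return df[df["extero_intero_ratio"].notna()].copy(), terms
    isna = df["extero_intero_ratio"].isna()
    df["extero_intero_ratio"] = df["extero_intero_ratio"].fillna(0.0)
    df["ratio_missing_ind"] = isna.astype(float)
    terms = list(terms)
    if isna.any() and "ratio_missing_ind" not in terms:
        terms.append("ratio_missing_ind")
    return df, terms


def _check_design(df: pd.DataFrame, terms: Sequence[str]) -> None:
    for term in terms:
        if term in df.columns and pd.api.types.is_numeric_dtype(df[term]):
            v = df[term].to_numpy(dtype=float)
            if np.nanstd(v) == 0:
                raise ConfigError(f"column {term!r} has zero variance in the design")


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------


class _NestedREML:
    """Profiled REML for the nested random-intercept gaussian model

        y = X beta + c_continent + u_user + e,
        c ~ N(0, s2_c), u ~ N(0, s2_u), e ~ N(0, s2_e),

    with users nested in continents.  The marginal covariance is
    V = s2_e (I + lam_u Zu Zu' + lam_c Zc Zc'); because both random
    designs are disjoint indicator blocks, V^{-1} M and log|V| follow
    from two Sherman-Morrison steps (first user blocks, then continent
    blocks) in O(N) per evaluation, so the two variance ratios can be
    optimized directly.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 user_idx: np.ndarray, cont_idx: np.ndarray):
        self.X, self.y = X, y
        self.user_idx, self.cont_idx = user_idx, cont_idx
        self.n_users = int(user_idx.max()) + 1
        self.n_cont = int(cont_idx.max()) + 1
        self.n, self.p = X.shape
        self.n_i = np.bincount(user_idx, minlength=self.n_users).astype(float)
        # continent of each user (nesting: constant within user)
        self.user_cont = np.zeros(self.n_users, dtype=int)
        self.user_cont[user_idx] = cont_idx

    def _solve(self, lam_u: float, lam_c: float, M: np.ndarray
               ) -> tuple[np.ndarray, float]:
        """Return (W^{-1} M, log|W|) for W = I + lam_u ZuZu' + lam_c ZcZc'."""
        k = M.shape[1]
        shrink_u = lam_u / (1.0 + lam_u * self.n_i)            # per user
        sums_u = np.zeros((self.n_users, k))
        np.add.at(sums_u, self.user_idx, M)
        AinvM = M - (shrink_u[self.user_idx, None] * sums_u[self.user_idx])
        logdet = float(np.log1p(lam_u * self.n_i).sum())
        if lam_c == 0.0 or self.n_cont < 2:
            return AinvM, logdet
        # A^{-1} 1_c is a_i = 1/(1 + lam_u n_i) on user i's rows
        a_user = 1.0 / (1.0 + lam_u * self.n_i)
        s_c = np.bincount(self.user_cont, weights=self.n_i * a_user,
                          minlength=self.n_cont)               # 1_c' A^{-1} 1_c
        onesAinvM = np.zeros((self.n_cont, k))                 # 1_c' A^{-1} M
        np.add.at(onesAinvM, self.cont_idx, AinvM)
        coef = lam_c / (1.0 + lam_c * s_c)
        a_rows = a_user[self.user_idx]
        WinvM = AinvM - (coef[self.cont_idx, None] * a_rows[:, None]
                         * onesAinvM[self.cont_idx])
        logdet += float(np.log1p(lam_c * s_c).sum())
        return WinvM, logdet

    def _criterion(self, lam_u: float, lam_c: float) -> tuple[float, dict]:
        M = np.column_stack([self.X, self.y])
        WinvM, logdet = self._solve(lam_u, lam_c, M)
        WinvX, Winvy = WinvM[:, :-1], WinvM[:, -1]
        XtWiX = self.X.T @ WinvX
        XtWiy = self.X.T @ Winvy
        try:
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError as err:
            raise ConfigError(f"rank-deficient design: {err}") from err
        resid = self.y - self.X @ beta
        quad = float(resid @ Winvy - resid @ (WinvX @ beta))
        # quad = r' W^{-1} r (using W^{-1} symmetry)
        quad = max(quad, 1e-12)
        dof = self.n - self.p
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        crit = dof * np.log(quad / dof) + logdet + logdet_XtWiX
        info = {"beta": beta, "XtWiX": XtWiX, "sigma2": quad / dof}
        return crit, info

    def fit(self) -> dict:
        from scipy.optimize import minimize

        def obj(theta):
            lam_u, lam_c = np.exp(theta)
            return self._criterion(lam_u, lam_c)[0]

        best = minimize(obj, x0=np.log([0.3, 0.05]), method="Nelder-Mead",
                        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        lam_u, lam_c = np.exp(best.x)
        # ratios driven to ~0 mean the component is absent
        lam_u = 0.0 if lam_u < 1e-8 else lam_u
        lam_c = 0.0 if lam_c < 1e-8 else lam_c
        _, info = self._criterion(lam_u, lam_c)
        cov_beta = info["sigma2"] * np.linalg.inv(info["XtWiX"])
        return {
            "beta": info["beta"], "cov_beta": cov_beta,
            "sigma2_e": info["sigma2"],
            "sigma2_u": lam_u * info["sigma2"],
            "sigma2_c": lam_c * info["sigma2"],
            "converged": bool(best.success),
            "message": "" if best.success else str(best.message),
        }


def _design_matrix(df: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    import patsy
    from scipy.linalg import qr

    y, X = patsy.dmatrices(formula, data=df, return_type="dataframe")
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the columns implicated via pivoted QR
        _, _, piv = qr(Xv, pivoting=True, mode="economic")
        bad = [X.columns[j] for j in piv[rank:]]
        raise ConfigError(f"rank-deficient design; dependent columns: {bad}")
    return Xv, list(X.columns), y.to_numpy(dtype=float).ravel()


def fit_linear_mixed(df: pd.DataFrame, spec: ModelSpec,
                     ratio_missing: str = "indicator",
                     engine: str = "nested") -> ModelResult:
    """Gaussian mixed model with continent/user nested random intercepts.

    With >= 2 continent levels the model carries a random continent
    intercept plus per-user random intercepts; with a single level it
    degenerates to a plain per-user random intercept.  The default
    ``engine="nested"`` uses the closed-form profiled-REML solver above;
    ``engine="mixedlm"`` fits the same structure through statsmodels
    MixedLM (variance components), practical only at small scale.
    Estimates carry Wald 95% CIs; non-convergence is flagged on the
    result, never raised.
    """
    if spec.family != "gaussian":
        raise ConfigError("fit_linear_mixed requires a gaussian family spec")
    if df[spec.group_user].nunique() < 2:
        raise ConfigError("need at least 2 users to fit a mixed model")
    spec.validate_columns(df)
    terms = list(spec.fixed_terms)
    df, terms = _prepare_ratio(df, terms, ratio_missing)
    _check_design(df, terms)
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{spec.outcome} ~ {rhs}"

    use_continent = (
        spec.group_continent is not None
        and spec.group_continent in df.columns
        and df[spec.group_continent].nunique() >= 2
    )
    if engine == "mixedlm":
        return _fit_mixedlm(df, spec, formula, use_continent)
    if engine != "nested":
        raise ConfigError(f"unknown engine {engine!r}")

    X, names, y = _design_matrix(df, formula)
    user_idx = pd.factorize(df[spec.group_user])[0]
    if use_continent:
        cont_idx = pd.factorize(df[spec.group_continent])[0]
    else:
        cont_idx = np.zeros(len(df), dtype=int)
    solver = _NestedREML(X, y, user_idx, cont_idx)
    fitres = solver.fit()

    z = sps.norm.ppf(0.975)
    est = fitres["beta"]
    se = np.sqrt(np.diag(fitres["cov_beta"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2.0 * sps.norm.sf(np.abs(est / se))
    table = _finish_table(pd.DataFrame({
        "term": names, "estimate": est,
        "ci_low": est - z * se, "ci_high": est + z * se, "p": pvals,
    }))
    re_var = {
        "user_intercept_var": fitres["sigma2_u"],
        "residual_var": fitres["sigma2_e"],
    }
    if use_continent:
        re_var["continent_intercept_var"] = fitres["sigma2_c"]
    return ModelResult(
        table=table, random_effects=re_var, n_rows=len(df),
        n_users=int(df[spec.group_user].nunique()),
        converged=fitres["converged"], diagnostic=fitres["message"],
    )


def _fit_mixedlm(df: pd.DataFrame, spec: ModelSpec, formula: str,
                 use_continent: bool) -> ModelResult:
    converged = True
    diagnostic = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if use_continent:
            model = smf.mixedlm(
                formula, data=df, groups=df[spec.group_continent],
                re_formula="1", vc_formula={"user": f"0 + C({spec.group_user})"},
            )
        else:
            model = smf.mixedlm(formula, data=df, groups=df[spec.group_user], re_formula="1")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError as err:
            raise ConfigError(f"rank-deficient design: {err}") from err
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            diagnostic = str(w.message)

    fe = res.fe_params
    se = res.bse_fe
    z = sps.norm.ppf(0.975)
    table = _finish_table(pd.DataFrame({
        "term": fe.index,
        "estimate": fe.to_numpy(),
        "ci_low": fe.to_numpy() - z * se.to_numpy(),
        "ci_high": fe.to_numpy() + z * se.to_numpy(),
        "p": res.pvalues.loc[fe.index].to_numpy(),
    }))

    re_var = {}
    if use_continent:
        re_var["continent_intercept_var"] = float(np.asarray(res.cov_re)[0, 0])
        if res.vcomp.size:
            re_var["user_intercept_var"] = float(res.vcomp[0])
    else:
        re_var["user_intercept_var"] = float(np.asarray(res.cov_re)[0, 0])
    re_var["residual_var"] = float(res.scale)

    return ModelResult(
        table=table, random_effects=re_var, n_rows=len(df),
        n_users=int(df[spec.group_user].nunique()),
        converged=converged, diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Penalized-spline dose-response smooths
# ---------------------------------------------------------------------------

def _session_axis_cutoff(x: np.ndarray, cutoff: float) -> float:
    """Largest session time point whose relative frequency (on the
    5-session-harmonized axis) is >= cutoff; ensures adequate support at
    high session counts before the smooth is fitted."""
    binned = ft.harmonize(x, 5.0)
    freq = pd.Series(binned).value_counts(normalize=True)
    kept = freq[freq >= cutoff].index
    if len(kept) == 0:
        return float(np.max(x))
    return float(max(kept) + 2.5)


def _fit_one_gam(df: pd.DataFrame, spec: ModelSpec, var: str, label: str,
                 warnings_out: list[str]) -> tuple[pd.DataFrame, dict] | None:
    x = df[var].to_numpy(dtype=float)
    if len(df) < spec.min_level_rows or len(np.unique(x)) < spec.basis_df:
        warnings_out.append(f"level {label!r} dropped: insufficient support ({len(df)} rows)")
        return None
    y = df[spec.outcome].to_numpy(dtype=float)
    if np.std(y) == 0.0:
        # degenerate input: constant outcome fits an exactly flat smooth
        grid = np.linspace(x.min(), x.max(), 100)
        flat = np.zeros_like(grid)
        return (pd.DataFrame({"level": label, var: grid, "fit": flat,
                              "ci_low": flat, "ci_high": flat}),
                {"p_smooth": 1.0, "n_rows": len(df), "alpha": float("nan")})
    bs = BSplines(x[:, None], df=[spec.basis_df], degree=[3], variable_names=[var])
    rhs = " + ".join(spec.fixed_terms) if spec.fixed_terms else "1"
    family = sm.families.Gaussian() if spec.family == "gaussian" else sm.families.Binomial()
    gam = GLMGam.from_formula(f"{spec.outcome} ~ {rhs}", data=df, smoother=bs,
                              family=family, alpha=spec.alpha or 0.0)
    if spec.alpha is None:
        try:
            alpha = gam.select_penweight(criterion="gcv")[0]
        except Exception:
            alpha = [1.0]
        gam = GLMGam.from_formula(f"{spec.outcome} ~ {rhs}", data=df, smoother=bs,
                                  family=family, alpha=alpha)
    res = gam.fit()

    grid = np.linspace(x.min(), x.max(), 100)
    basis = bs.smoothers[0].transform(grid[:, None])
    k_par = res.model.exog.shape[1] - basis.shape[1]
    coefs = res.params[k_par:]
    cov = np.asarray(res.cov_params())[k_par:, k_par:]
    fit_vals = basis @ coefs
    se = np.sqrt(np.einsum("ij,jk,ik->i", basis, cov, basis))
    zq = sps.norm.ppf(0.975)

    # smooth-term significance: Wald test on the spline coefficient block
    R = np.zeros((len(coefs), len(res.params)))
    R[:, k_par:] = np.eye(len(coefs))
    try:
        p_smooth = float(res.wald_test(R, scalar=True).pvalue)
    except Exception:
        p_smooth = np.nan

    grid_df = pd.DataFrame({
        "level": label, var: grid,
        "fit": fit_vals, "ci_low": fit_vals - zq * se, "ci_high": fit_vals + zq * se,
    })
    meta = {"p_smooth": p_smooth, "n_rows": len(df), "alpha": float(np.atleast_1d(res.model.alpha)[0])}
    return grid_df, meta


def fit_nonlinear_mixed(df: pd.DataFrame, spec: ModelSpec,
                        ratio_missing: str = "indicator") -> ModelResult:
    """Penalized cubic B-spline smooths of the outcome against each smooth
    variable, one fit per level of the by-factor (pooled fit when the
    by-factor is None), with parametric covariate adjustment and a
    GCV-selected penalty.  The session axis is truncated per level at the
    relative-frequency support cutoff before fitting; under-supported
    levels are dropped with a logged warning.
    """
    if not spec.smooth_terms:
        raise ConfigError("spec.smooth_terms is empty")
    spec.validate_columns(df)
    terms = list(spec.fixed_terms)
    df, terms = _prepare_ratio(df, terms, ratio_missing)
    spec = ModelSpec(**{**spec.__dict__, "fixed_terms": terms})
    _check_design(df, terms)

    smooths: dict[str, pd.DataFrame] = {}
    rows = []
    dropped: list[str] = []
    for var, by in spec.smooth_terms:
        if by is None:
            sub = df[df[var].notna() & df[spec.outcome].notna()]
            cut = _session_axis_cutoff(sub[var].to_numpy(float), spec.support_cutoff)
            sub = sub[sub[var] <= cut]
            out = _fit_one_gam(sub, spec, var, "all", dropped)
            if out is not None:
                grid_df, meta = out
                smooths[f"s({var})"] = grid_df
                rows.append({"term": f"s({var})", "estimate": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": meta["p_smooth"]})
        else:
            for level in df[by].dropna().unique():
                sub = df[(df[by] == level) & df[var].notna() & df[spec.outcome].notna()]
                if len(sub) == 0:
                    continue
                cut = _session_axis_cutoff(sub[var].to_numpy(float), spec.support_cutoff)
                sub = sub[sub[var] <= cut]
                out = _fit_one_gam(sub, spec, var, str(level), dropped)
                if out is None:
                    continue
                grid_df, meta = out
                smooths[f"s({var})|{by}={level}"] = grid_df
                rows.append({"term": f"s({var})|{by}={level}", "estimate": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": meta["p_smooth"]})
    if not rows:
        raise ConfigError("all smooth levels dropped for insufficient support")
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = fdr_adjust(table.loc[ok, "p"].to_numpy())
    return ModelResult(
        table=table, smooths=smooths, n_rows=len(df),
        n_users=int(df[spec.group_user].nunique()) if spec.group_user in df else 0,
        converged=True, diagnostic="; ".join(dropped),
    )


# ---------------------------------------------------------------------------
# Adherence logistic regression
# ---------------------------------------------------------------------------

def fit_adherence_logit(df: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Logistic adherence model reporting odds ratios per term.

    Factors are treatment-coded against documented reference levels
    (least-intensive habit level).  Complete separation yields a flagged
    result with a diagnostic, not a crash; a zero-variance feature raises
    a configuration error naming the column.
    """
    if spec.family != "binomial":
        raise ConfigError("fit_adherence_logit requires a binomial family spec")
    y = df[spec.outcome].astype(int)
    if y.nunique() < 2:
        raise ConfigError("both adherence classes must be present")
    spec.validate_columns(df)
    _check_design(df, list(spec.fixed_terms))
    for term in spec.fixed_terms:
        if term in df.columns and isinstance(df[term].dtype, pd.CategoricalDtype):
            if df[term].nunique() < 2:
                raise ConfigError(f"column {term!r} has zero variance in the design")
    rhs = " + ".join(_treatment_code(t) for t in spec.fixed_terms) if spec.fixed_terms else "1"
    converged, diagnostic = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.glm(f"{spec.outcome} ~ {rhs}",
                        data=df.assign(**{spec.outcome: y}),
                        family=sm.families.Binomial())
        try:
            res = model.fit()
        except PerfectSeparationError as err:
            return ModelResult(table=pd.DataFrame(), n_rows=len(df),
                               converged=False, diagnostic=f"complete separation: {err}")
    for w in caught:
        msg = str(w.message).lower()
        if "separation" in msg or issubclass(w.category, ConvergenceWarning):
            converged = False
            diagnostic = str(w.message)
    if np.abs(res.params).max() > 15:
        converged = False
        diagnostic = diagnostic or "quasi-separated fit: extreme coefficient magnitude"

    z = sps.norm.ppf(0.975)
    est, se = res.params, res.bse
    table = pd.DataFrame({
        "term": est.index,
        "estimate": est.to_numpy(),
        "ci_low": est.to_numpy() - z * se.to_numpy(),
        "ci_high": est.to_numpy() + z * se.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    with np.errstate(over="ignore"):   # separated fits have huge estimates
        table["odds_ratio"] = np.exp(table["estimate"])
        table["or_ci_low"] = np.exp(table["ci_low"])
        table["or_ci_high"] = np.exp(table["ci_high"])
    table = _finish_table(table)
    return ModelResult(table=table, n_rows=len(df),
                       n_users=len(df), converged=converged, diagnostic=diagnostic)


def _treatment_code(term: str) -> str:
    if "(" in term or term not in REFERENCE_LEVELS:
        return term
    return f"C({term}, Treatment('{REFERENCE_LEVELS[term]}'))"


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def recovery_report(truths: dict[str, float],
                    replicates: Sequence[dict[str, tuple[float, float, float]]]
                    ) -> RecoveryReport:
    """Coverage, bias and RMSE of replicate estimates against injected truth.

    ``replicates`` maps parameter name -> (estimate, ci_low, ci_high) per
    seeded replicate fit; at least 20 replicates are required for the
    coverage rate to be meaningful.
    """
    if len(replicates) < 20:
        raise ConfigError(f"need >= 20 replicates, got {len(replicates)}")
    rows = []
    for name, truth in truths.items():
        ests = np.array([r[name][0] for r in replicates if name in r])
        los = np.array([r[name][1] for r in replicates if name in r])
        his = np.array([r[name][2] for r in replicates if name in r])
        covered = (los <= truth) & (truth <= his)
        rows.append({
            "parameter": name,
            "truth": truth,
            "mean_estimate": float(ests.mean()),
            "bias": float(ests.mean() - truth),
            "rmse": float(np.sqrt(((ests - truth) ** 2).mean())),
            "coverage": float(covered.mean()),
            "n": len(ests),
        })
    return RecoveryReport(per_parameter=pd.DataFrame(rows), n_replicates=len(replicates))


def _recovery_config(session_effect: float, n_users: int, seed: int) -> syn.SimConfig:
    return syn.SimConfig(
        n_users=n_users,
        mean_sessions_per_user=15,
        session_effect=session_effect,
        consistency_effect=0.0,
        noise_sd=0.6,
        max_sessions=40,
        seed=seed,
    )


def linear_recovery_study(n_replicates: int = 100, n_users: int = 500,
                          session_effect: float = 0.01, seed: int = 0) -> RecoveryReport:
    """Replicate fits of the linear mixed model on synthetic streams with a
    known session effect; truth is the model-scale implied slope from the
    ordinal-threshold expectation (identical across replicates up to the
    baseline draw, so it is computed once at large n)."""
    base = _recovery_config(session_effect, n_users, 0)
    truth = syn.implied_session_slope(base, n_sessions=base.max_sessions)
    spec = ModelSpec(outcome="outcome_mood",
                     fixed_terms=("session_count", "days_per_week"))
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    reps = []
    for s in seeds:
        cfg = _recovery_config(session_effect, n_users, int(s))
        users, sessions, _ = syn.simulate_streams(cfg)
        table = ft.build_feature_table(sessions, users, trim=False)
        res = fit_linear_mixed(table, spec)
        row = res.table.set_index("term").loc["session_count"]
        reps.append({"session_effect": (row["estimate"], row["ci_low"], row["ci_high"])})
    return recovery_report({"session_effect": truth}, reps)


def adherence_recovery_study(n_replicates: int = 100, n_users: int = 2000,
                             odds_ratio: float = 2.0, seed: int = 0) -> RecoveryReport:
    """Replicate logistic fits on cohorts whose adherence log-odds rise by
    log(odds_ratio) for the 4-7 days/week level; recovery is checked on
    the odds-ratio scale."""
    spec = ModelSpec(outcome="adherent", family="binomial",
                     fixed_terms=("days_per_week_level", "length_bin",
                                  "practice_types_bin", "baseline_mood"))
    seeds = np.random.SeedSequence((seed, 1)).generate_state(n_replicates) % (2**31)
    term = "C(days_per_week_level, Treatment('1'))[T.4-7]"
    reps = []
    for s in seeds:
        cohort = syn.simulate_adherence_cohort(
            n_users, days_per_week_effects={"2": 0.2, "3": 0.4, "4-7": float(np.log(odds_ratio))},
            seed=int(s))
        res = fit_adherence_logit(cohort, spec)
        row = res.table.set_index("term").loc[term]
        reps.append({"or_days_4_7": (row["odds_ratio"], row["or_ci_low"], row["or_ci_high"])})
    return recovery_report({"or_days_4_7": odds_ratio}, reps)


def nonlinear_recovery_study(n_users: int = 1000, seed: int = 0,
                             amplitude: float = 0.4, tau: float = 8.0
                             ) -> tuple[float, float, pd.DataFrame]:
    """Fit the penalized-spline dose-response smooth on data generated from
    a saturating latent profile and compare the fitted curve with the
    generator's tabulated truth on the expected-mood scale.

    Returns ``(rmse, early_gain_fraction, curve_table)`` where
    ``early_gain_fraction`` is the share of the fitted total gain attained
    in the first third of the session axis (the truth concentrates its
    rise there).
    """
    def profile(idx: np.ndarray) -> np.ndarray:
        return amplitude * (1.0 - np.exp(-(np.asarray(idx, float) - 1.0) / tau))

    cfg = syn.SimConfig(
        n_users=n_users, mean_sessions_per_user=60, churn_hazard=0.01,
        nonlinear_profile=profile, noise_sd=0.6, max_sessions=60,
        seed=seed,
    )
    users, sessions, truth = syn.simulate_streams(cfg)
    table = ft.build_feature_table(sessions, users, trim=False)
    spec = ModelSpec(outcome="outcome_mood", fixed_terms=(), basis_df=8,
                     smooth_terms=(("session_count", None),), support_cutoff=0.001)
    res = fit_nonlinear_mixed(table, spec)
    grid = res.smooths["s(session_count)"]

    # tabulated truth: mean expected mood at session index c+1 (the shifted
    # outcome paired with predictor count c), centred like the fitted smooth
    tr = truth.groupby("session_index")["expected_mood"].mean()
    counts = grid["session_count"].to_numpy()
    truth_curve = np.interp(counts + 1, tr.index.to_numpy(float), tr.to_numpy())
    fit = grid["fit"].to_numpy()
    fit_c = fit - fit.mean()
    truth_c = truth_curve - truth_curve.mean()
    rmse = float(np.sqrt(np.mean((fit_c - truth_c) ** 2)))

    lo = fit[counts <= counts.min() + (counts.max() - counts.min()) / 3.0]
    total_gain = fit[-1] - fit[0]
    early_gain = lo[-1] - lo[0]
    early_fraction = float(early_gain / total_gain) if total_gain != 0 else float("nan")
    curve = grid.assign(truth=truth_curve, fit_centered=fit_c, truth_centered=truth_c)
    return rmse, early_fraction, curve
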