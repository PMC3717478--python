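"""Two-level mixed-effects models of daily affect on daily physical
activity.

The day-level model regresses an affect score on a linear time trend,
the child's study-average activity (between-person effect) and the daily
deviation from that average (within-person effect):

    Affect_ti = (g00 + s0i) + (g10 + s1i) * Trend_ti
                + g20 * PAmean_i + (g30 + s3i) * PAdev_ti + e_ti

with random intercept s0i, random trend s1i (their covariance included),
an independent random daily-activity slope s3i, and residual e_ti.
Estimation is restricted maximum likelihood (REML); maximum likelihood
is available for nested deviance comparisons, since REML likelihoods are
not comparable across fixed-effect structures.  Fixed effects are tested
with Wald z-tests (no small-sample df correction).  Variance estimates
at the boundary are reported as 0 with a missing standard error.

The model-building sequence fits, in order: the empty model, trend only,
trend + both PA effects as fixed effects, and finally the model with the
random daily-activity slope added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "HLMDesign", "HLMFit", "MODEL_TAGS", "build_design", "fit_hlm",
    "model_sequence", "results_table", "format_results_text",
]

MODEL_TAGS = ("empty", "trend_only", "fixed_only", "fixed_and_random")

#: variance estimates below this are treated as boundary zeros
BOUNDARY_TOL = 1e-6


@dataclass
class HLMDesign:
    """Person-mean-centered day-level design for one outcome/PA pair.

    ``data`` has canonical columns ``group`` (child), ``y`` (outcome),
    ``trend`` (day index from each child's first study day),
    ``pa_between`` (child mean of the PA variable, constant within
    child) and ``pa_within`` (daily deviation from the child's own mean,
    which sums to zero within every child).
    """

    data: pd.DataFrame
    outcome: str
    pa_variable: str
    degenerate_pa: bool = False

    @property
    def n_children(self) -> int:
        return self.data["group"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)


@dataclass
class HLMFit:
    """Estimates from one fitted two-level model."""

    model_tag: str
    outcome: str
    pa_variable: str
    fixed: pd.DataFrame  # index: term; columns: estimate, se, z, p
    var_sigma0: float
    var_sigma1: float
    var_sigma3: float
    cov_sigma0_sigma1: float
    var_epsilon: float
    var_se: dict = field(default_factory=dict)  # SEs of variance estimates
    neg2loglik: float = float("nan")
    reml: bool = True
    converged: bool = True
    n_children: int = 0
    n_obs: int = 0

    def fixed_effect(self, term: str) -> tuple[float, float]:
        row = self.fixed.loc[term]
        return float(row["estimate"]), float(row["se"])


def build_design(
    day_table: pd.DataFrame,
    outcome: str,
    pa_variable: str = "pa_fraction",
    group: str = "child_id",
    trend: str = "day_index",
    min_days: int = 2,
    allow_constant_pa: bool = False,
) -> HLMDesign:
    """Person-mean-center a PA variable and assemble the model design.

    Rows with a missing outcome or PA value are dropped listwise; at
    least two children with at least two retained days each are
    required.  A design whose within-person PA deviations are all zero
    is flagged as degenerate (the daily-activity effect is inestimable).
    """
    cols = [group, trend, outcome, pa_variable]
    df = day_table[cols].dropna().copy()
    df.columns = ["group", "trend", "y", "pa"]
    counts = df.groupby("group").size()
    df = df[df["group"].isin(counts[counts >= min_days].index)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 children with at least 2 valid days each")
    df["pa_between"] = df.groupby("group")["pa"].transform("mean")
    df["pa_within"] = df["pa"] - df["pa_between"]
    degenerate = bool(np.allclose(df["pa_within"], 0.0))
    if degenerate and not allow_constant_pa:
        warnings.warn(
            f"PA variable {pa_variable!r} is constant within every child; "
            "the daily-activity effect is inestimable",
            stacklevel=2,
        )
    return HLMDesign(
        data=df.reset_index(drop=True),
        outcome=outcome,
        pa_variable=pa_variable,
        degenerate_pa=degenerate,
    )


_FIXED_TERMS = {
    "empty": "y ~ 1",
    "trend_only": "y ~ trend",
    "fixed_only": "y ~ trend + pa_between + pa_within",
    "fixed_and_random": "y ~ trend + pa_between + pa_within",
}
_RE_FORMULA = {
    "empty": "~1",
    "trend_only": "~trend",
    "fixed_only": "~trend",
    "fixed_and_random": "~trend",
}
#: display names of the fixed-effect terms
TERM_NAMES = {
    "Intercept": "intercept",
    "trend": "trend",
    "pa_between": "average_activity",
    "pa_within": "daily_activity",
}


def _ols_fit(design: HLMDesign, model_tag: str) -> HLMFit:
    """The no-random-effects limit: ordinary least squares on the same
    fixed design (a mixed model with an empty random structure)."""
    import statsmodels.formula.api as smf

    res = smf.ols(_FIXED_TERMS[model_tag], data=design.data).fit()
    fixed = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "z": res.params / res.bse,
            "p": 2 * stats.norm.sf(np.abs(res.params / res.bse)),
        }
    )
    fixed.index = [TERM_NAMES.get(t, t) for t in fixed.index]
    return HLMFit(
        model_tag=model_tag,
        outcome=design.outcome,
        pa_variable=design.pa_variable,
        fixed=fixed,
        var_sigma0=0.0,
        var_sigma1=0.0,
        var_sigma3=0.0,
        cov_sigma0_sigma1=0.0,
        var_epsilon=float(res.ssr / res.nobs),
        neg2loglik=float(-2 * res.llf),
        reml=False,
        converged=True,
        n_children=design.n_children,
        n_obs=design.n_obs,
    )


_FIXED_COLS = {
    "empty": [],
    "trend_only": ["trend"],
    "fixed_only": ["trend", "pa_between", "pa_within"],
    "fixed_and_random": ["trend", "pa_between", "pa_within"],
}


def _gls_fixed_se(design: HLMDesign, model_tag: str, res) -> np.ndarray:
    """Model-based SEs of the fixed effects: sqrt diag of
    (sum_i X_i' V_i^-1 X_i)^-1 with V_i built from the estimated
    variance components of group i."""
    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    var3 = float(res.vcomp[0]) if res.vcomp.size else 0.0
    scale = float(res.scale)
    with_trend_re = _RE_FORMULA[model_tag] == "~trend"
    xtvx = 0.0
    for _, sub in design.data.groupby("group", sort=False):
        n = len(sub)
        X = np.column_stack(
            [np.ones(n)] + [sub[c].to_numpy(float) for c in _FIXED_COLS[model_tag]]
        )
        Z = np.column_stack([np.ones(n), sub["trend"].to_numpy(float)]) \
            if with_trend_re else np.ones((n, 1))
        V = Z @ cov_re @ Z.T + scale * np.eye(n)
        if var3 > 0:
            u = sub["pa_within"].to_numpy(float)
            V += var3 * np.outer(u, u)
        xtvx = xtvx + X.T @ np.linalg.solve(V, X)
    return np.sqrt(np.diag(np.linalg.inv(xtvx)))


def fit_hlm(
    design: HLMDesign,
    model_tag: str,
    reml: bool = True,
    include_random: bool = True,
) -> HLMFit:
    """Fit one model of the sequence by REML (or ML).

    ``include_random=False`` drops the entire random structure, reducing
    the fit to OLS on the same fixed design.  Non-convergence is
    reported through :attr:`HLMFit.converged` plus a warning, never
    silently.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")
    if model_tag in ("fixed_only", "fixed_and_random") and design.degenerate_pa:
        raise ValueError(
            "within-person PA deviations are all zero; the daily-activity "
            "effect cannot be estimated"
        )
    if not include_random:
        return _ols_fit(design, model_tag)

    vc = {"daily": "0 + pa_within"} if model_tag == "fixed_and_random" else None
    model = sm.MixedLM.from_formula(
        _FIXED_TERMS[model_tag],
        groups="group",
        re_formula=_RE_FORMULA[model_tag],
        vc_formula=vc,
        data=design.data,
    )
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs"], ["powell"], ["cg"]):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=200)
            except Exception:
                continue
            res = cand
            if cand.converged:
                break
        if res is not None:
            # a boundary solution can be an optimizer artifact: verify it
            # against a second optimizer and keep the better likelihood
            onboundary = float(np.diag(res.cov_re).min()) < BOUNDARY_TOL or (
                res.vcomp.size and float(res.vcomp.min()) < BOUNDARY_TOL
            )
            if onboundary or not res.converged or not np.isfinite(res.llf):
                try:
                    alt = model.fit(reml=reml, method=["bfgs"], maxiter=200)
                    if np.isfinite(alt.llf) and (
                        not np.isfinite(res.llf) or alt.llf > res.llf + 1e-8
                    ):
                        res = alt
                except Exception:
                    pass
    if res is None:
        raise RuntimeError(f"mixed-model fit failed for tag {model_tag!r}")
    if not res.converged:
        warnings.warn(
            f"mixed-model fit did not fully converge for tag {model_tag!r} "
            f"(outcome {design.outcome!r}); estimates may be unreliable",
            stacklevel=2,
        )

    fe_se = np.asarray(res.bse_fe, dtype=float)
    if not np.isfinite(fe_se).all():
        # near a variance boundary the joint Hessian can be singular and
        # the Wald SEs come out NaN; fall back to the model-based GLS
        # covariance (X' V^-1 X)^-1 at the estimated variance components
        fe_se = _gls_fixed_se(design, model_tag, res)
    z = np.asarray(res.fe_params) / fe_se
    fixed = pd.DataFrame(
        {
            "estimate": np.asarray(res.fe_params),
            "se": fe_se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=list(res.fe_params.index),
    )
    fixed.index = [TERM_NAMES.get(t, t) for t in fixed.index]

    cov_re = res.cov_re
    var0 = float(cov_re.iloc[0, 0])
    var1 = float(cov_re.loc["trend", "trend"]) if "trend" in cov_re.index else 0.0
    cov01 = float(cov_re.loc[cov_re.index[0], "trend"]) if "trend" in cov_re.index else 0.0
    var3 = float(res.vcomp[0]) if model_tag == "fixed_and_random" else 0.0

    # delta-method SEs of the variance estimates, converted from the
    # profiled parametrization the same way the fitting library's own
    # summary does (ignores uncertainty in the residual scale)
    var_se: dict[str, float] = {}
    try:
        bse_all = np.asarray(res.bse) * np.sqrt(res.scale)
        k_fe = len(res.fe_params)
        re_names = list(cov_re.index)
        pos = k_fe
        for a in range(len(re_names)):
            for b in range(a + 1):
                name = (
                    "var_sigma0" if (a, b) == (0, 0)
                    else "var_sigma1" if a == b == 1
                    else "cov_sigma0_sigma1"
                )
                var_se[name] = float(bse_all[pos])
                pos += 1
        if model_tag == "fixed_and_random":
            var_se["var_sigma3"] = float(bse_all[pos])
    except Exception:
        pass

    # boundary reporting: a variance estimated at (numerical) zero has no
    # meaningful Wald SE
    def _boundary(v: float, key: str) -> float:
        if v < BOUNDARY_TOL:
            var_se[key] = float("nan")
            return 0.0
        return v

    var0 = _boundary(var0, "var_sigma0")
    if "trend" in cov_re.index:
        var1 = _boundary(var1, "var_sigma1")
    if model_tag == "fixed_and_random":
        var3 = _boundary(var3, "var_sigma3")

    return HLMFit(
        model_tag=model_tag,
        outcome=design.outcome,
        pa_variable=design.pa_variable,
        fixed=fixed,
        var_sigma0=var0,
        var_sigma1=var1,
        var_sigma3=var3,
        cov_sigma0_sigma1=cov01,
        var_epsilon=float(res.scale),
        var_se=var_se,
        neg2loglik=float(-2 * res.llf),
        reml=reml,
        converged=bool(res.converged),
        n_children=design.n_children,
        n_obs=design.n_obs,
    )


def model_sequence(design: HLMDesign, reml: bool = True) -> list[HLMFit]:
    """Fit the four models of the building sequence in order: empty,
    trend only, fixed effects, fixed and random effects."""
    return [fit_hlm(design, tag, reml=reml) for tag in MODEL_TAGS]


_ROW_ORDER = [
    ("fixed", "intercept", "fixed_intercept"),
    ("fixed", "trend", "trend"),
    ("fixed", "average_activity", "average_activity"),
    ("fixed", "daily_activity", "daily_activity"),
    ("var", "var_sigma0", "random_intercept_var"),
    ("var", "var_sigma3", "daily_activity_var"),
    ("var", "var_sigma1", "trend_var"),
    ("var", "var_epsilon", "residual_var"),
    ("ll", "", "neg2loglik"),
]


def _fmt(est: float, se: float, sig: bool = False) -> str:
    star = "*" if sig else ""
    if np.isnan(se):
        return f"{est:.3g}{star} (NA)"
    return f"{est:.3g}{star} ({se:.2g})"


def results_table(fits: list[HLMFit]) -> pd.DataFrame:
    """Human-readable results table: one column per fitted model, rows
    for the fixed effects ("estimate (SE)", starred at p < 0.05), the
    variance components and the deviance."""
    cols = {}
    for fit in fits:
        col = {}
        for kind, key, row in _ROW_ORDER:
            if kind == "fixed":
                if key in fit.fixed.index:
                    r = fit.fixed.loc[key]
                    col[row] = _fmt(r["estimate"], r["se"], r["p"] < 0.05)
                else:
                    col[row] = ""
            elif kind == "var":
                if key == "var_epsilon":
                    col[row] = f"{fit.var_epsilon:.3g}"
                elif key == "var_sigma1" and fit.model_tag == "empty":
                    col[row] = ""
                elif key == "var_sigma3" and fit.model_tag != "fixed_and_random":
                    col[row] = ""
                else:
                    v = getattr(fit, key)
                    se = fit.var_se.get(key, float("nan"))
                    col[row] = _fmt(v, se)
            else:
                col[row] = f"{fit.neg2loglik:.1f}"
        cols[fit.model_tag] = col
    return pd.DataFrame(cols).reindex([r for _, _, r in _ROW_ORDER])


def format_results_text(fits: list[HLMFit]) -> str:
    head = fits[0]
    table = results_table(fits)
    return (
        f"Outcome: {head.outcome}   PA variable: {head.pa_variable}   "
        f"(REML, {head.n_children} children, {head.n_obs} child-days)\n"
        + table.to_string()
        + "\n* p < 0.05 (Wald z)\n"
    )
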