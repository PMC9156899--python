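"""Mixed-effects state-dependence analysis of day-level task parameters.

Three nested random-intercept models are fit per parameter:

* repetition:  value ~ 1 + repetition
* group:       value ~ 1 + repetition + diagnosis
* mood:        value ~ 1 + repetition + diagnosis + mood_within + mood_between
                         + diagnosis:mood_within + diagnosis:mood_between

``repetition`` is the running count of completed administrations of the task
up to and including the current day.  Mood enters as a 0-100 composite
(mean of positive mood and the reflection 100 - negative mood, prompts
averaged to the day first), split into a person-mean-centered within-person
deviation and a grand-mean-centered person mean (within-cluster centering).
Diagnosis is coded control = 0, patient = 1 and recorded in the result
metadata, since the sign of group effects is pure coding convention.

Fixed-effect inference uses the Satterthwaite approximation: the degrees of
freedom for a contrast c are df = 2 f^2 / (g' A^{-1} g) where f = c'Var(b)c,
g its gradient in the variance components and A the observed REML
information, all computed for the random-intercept covariance structure.  If
the between-person variance collapses to zero the residual df n - p is used
instead and labeled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PARAMETER_MAP",
    "LmeResult",
    "build_mood_days",
    "add_repetition",
    "parameter_series",
    "fit_repetition_model",
    "fit_group_model",
    "fit_mood_model",
    "lme_results_to_frame",
]

# display name -> (task label, fits-table column)
PARAMETER_MAP = {
    "risk_tol_gain": ("risk-gain", "risk_tol"),
    "amb_tol_gain": ("risk-gain", "amb_tol"),
    "risk_tol_loss": ("risk-loss", "risk_tol"),
    "amb_tol_loss": ("risk-loss", "amb_tol"),
    "log_kappa": ("itc", "log_kappa"),
}

DIAGNOSIS_CODING = {"control": 0.0, "OUD": 1.0}


@dataclass
class LmeResult:
    """Fixed effects (with Satterthwaite df) and variance components of one
    random-intercept model."""

    outcome: str
    model: str
    terms: pd.DataFrame  # term, estimate, se, t, df, p, ci_low, ci_high, df_method
    random_intercept_var: float
    residual_var: float
    n_observations: int
    n_subjects: int
    metadata: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def build_mood_days(ratings: pd.DataFrame) -> pd.DataFrame:
    """Collapse prompt-level mood ratings to one composite per subject-day.

    Positive and negative ratings are first averaged across the day's
    prompts, then composited as (positive + (100 - negative)) / 2, keeping
    the result on the 0-100 scale.  For this linear composite the averaging
    order is immaterial, but it mirrors the per-item day averaging used for
    all survey measures.
    """
    bad = ratings[
        (ratings["positive"] < 0) | (ratings["positive"] > 100)
        | (ratings["negative"] < 0) | (ratings["negative"] > 100)
    ]
    if len(bad):
        raise ValueError(f"{len(bad)} mood ratings outside [0, 100]")
    day = (
        ratings.groupby(["subject_id", "day"], sort=True)[["positive", "negative"]]
        .mean()
        .reset_index()
    )
    day["composite"] = (day["positive"] + (100.0 - day["negative"])) / 2.0
    return day


def add_repetition(fits: pd.DataFrame) -> pd.DataFrame:
    """Attach the repetition covariate: per subject and task, the number of
    completed administrations up to and including the current day."""
    out = fits.sort_values(["subject_id", "task", "day"]).copy()
    out["repetition"] = out.groupby(["subject_id", "task"]).cumcount() + 1
    return out


def parameter_series(
    fits: pd.DataFrame,
    parameter: str,
    exclude_nonconverged: bool = True,
) -> pd.DataFrame:
    """Long series (subject, group, day, value, repetition) for one reported
    parameter.  Boundary / degenerate day fits are excluded by default since
    they distort variance decompositions."""
    task, col = PARAMETER_MAP[parameter]
    d = add_repetition(fits)
    d = d[d["task"] == task]
    if exclude_nonconverged and "converged" in d.columns:
        d = d[d["converged"].astype(bool)]
    out = d[["subject_id", "group", "day", "repetition", col]].rename(columns={col: "value"})
    return out.dropna(subset=["value"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model (Satterthwaite df)
# ---------------------------------------------------------------------------


def _clusters(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    out = []
    for g in pd.unique(groups):
        idx = groups == g
        out.append((y[idx], X[idx]))
    return out


def _gls_pieces(tau2: float, sigma2: float, clusters):
    """Accumulate X'V^-1 X, X'V^-1 y and the REML log-determinant terms."""
    p = clusters[0][1].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    for yi, Xi in clusters:
        n_i = len(yi)
        w = tau2 / (sigma2 + n_i * tau2)
        Xs, ys = Xi.sum(axis=0), yi.sum()
        xtvx += (Xi.T @ Xi - w * np.outer(Xs, Xs)) / sigma2
        xtvy += (Xi.T @ yi - w * Xs * ys) / sigma2
        logdet_v += (n_i - 1) * np.log(sigma2) + np.log(sigma2 + n_i * tau2)
    return xtvx, xtvy, logdet_v


def _reml_loglik(tau2: float, sigma2: float, clusters) -> float:
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    xtvx, xtvy, logdet_v = _gls_pieces(tau2, sigma2, clusters)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = 0.0
    for yi, Xi in clusters:
        ri = yi - Xi @ beta
        n_i = len(ri)
        w = tau2 / (sigma2 + n_i * tau2)
        quad += (ri @ ri - w * ri.sum() ** 2) / sigma2
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet_v + logdet_xtvx + quad)


def _beta_cov(tau2: float, sigma2: float, clusters) -> np.ndarray:
    xtvx, _, _ = _gls_pieces(tau2, sigma2, clusters)
    return np.linalg.inv(xtvx)


def satterthwaite_df(tau2: float, sigma2: float, clusters, c: np.ndarray) -> tuple[float, str]:
    """Satterthwaite degrees of freedom for the contrast ``c`` of the fixed
    effects, with the residual df as labeled fallback near the tau2 = 0
    boundary or when the REML information is not invertible."""
    n = sum(len(yi) for yi, _ in clusters)
    p = clusters[0][1].shape[1]
    resid_df = float(n - p)
    if tau2 <= 1e-10 * max(sigma2, 1e-12):
        return resid_df, "residual"

    def f(theta):
        return float(c @ _beta_cov(theta[0], theta[1], clusters) @ c)

    theta = np.array([tau2, sigma2])
    h = 1e-4 * theta
    grad = np.array(
        [
            (f(theta + np.eye(2)[j] * h[j]) - f(theta - np.eye(2)[j] * h[j])) / (2 * h[j])
            for j in range(2)
        ]
    )

    def ll(theta):
        return _reml_loglik(theta[0], theta[1], clusters)

    hess = np.empty((2, 2))
    for j in range(2):
        for k in range(j, 2):
            ej, ek = np.eye(2)[j] * h[j], np.eye(2)[k] * h[k]
            if j == k:
                hess[j, j] = (ll(theta + ej) - 2 * ll(theta) + ll(theta - ej)) / h[j] ** 2
            else:
                hess[j, k] = hess[k, j] = (
                    ll(theta + ej + ek) - ll(theta + ej - ek) - ll(theta - ej + ek) + ll(theta - ej - ek)
                ) / (4 * h[j] * h[k])
    info = -hess
    try:
        var_f = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        return resid_df, "residual"
    if var_f <= 0 or not np.isfinite(var_f):
        return resid_df, "residual"
    df = 2.0 * f(theta) ** 2 / var_f
    return float(min(max(df, 1.0), resid_df)), "satterthwaite"


def _fit_random_intercept(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    model_name: str,
    parameter: str,
    metadata: dict | None = None,
) -> LmeResult:
    """Fit outcome ~ fixed effects + (1 | subject) by REML and package the
    fixed-effect table with Satterthwaite inference."""
    d = data.dropna(subset=[outcome] + fixed)
    y = d[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in fixed])
    names = ["Intercept"] + fixed
    groups = d["subject_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    clusters = _clusters(y, X, groups)
    cov = _beta_cov(tau2, sigma2, clusters)
    rows = []
    for j, name in enumerate(names):
        c = np.zeros(len(names))
        c[j] = 1.0
        est = float(res.fe_params[j])
        se = float(np.sqrt(cov[j, j]))
        df, df_method = satterthwaite_df(tau2, sigma2, clusters, c)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        crit = stats.t.ppf(0.975, df)
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "t": t,
                "df": df,
                "p": p,
                "ci_low": est - crit * se,
                "ci_high": est + crit * se,
                "df_method": df_method,
            }
        )
    return LmeResult(
        outcome=parameter,
        model=model_name,
        terms=pd.DataFrame(rows),
        random_intercept_var=tau2,
        residual_var=sigma2,
        n_observations=int(len(d)),
        n_subjects=int(d["subject_id"].nunique()),
        metadata={"diagnosis_coding": dict(DIAGNOSIS_CODING), **(metadata or {})},
    )


def _with_diagnosis(series: pd.DataFrame, coding: dict[str, float]) -> pd.DataFrame:
    d = series.copy()
    unknown = set(d["group"].unique()) - set(coding)
    if unknown:
        raise ValueError(f"groups without diagnosis coding: {sorted(unknown)}")
    d["diagnosis"] = d["group"].map(coding)
    return d


def fit_repetition_model(fits: pd.DataFrame, parameter: str, **kw) -> LmeResult:
    """Practice/drift model: value ~ 1 + repetition + (1 | subject)."""
    series = parameter_series(fits, parameter, **kw)
    return _fit_random_intercept(series, "value", ["repetition"], "repetition", parameter)


def fit_group_model(
    fits: pd.DataFrame,
    parameter: str,
    coding: dict[str, float] = DIAGNOSIS_CODING,
    **kw,
) -> LmeResult:
    """Aggregate group-difference model: value ~ 1 + repetition + diagnosis
    + (1 | subject), controlling practice effects."""
    series = _with_diagnosis(parameter_series(fits, parameter, **kw), coding)
    res = _fit_random_intercept(series, "value", ["repetition", "diagnosis"], "group", parameter)
    res.metadata["diagnosis_coding"] = dict(coding)
    return res


def fit_mood_model(
    fits: pd.DataFrame,
    mood_days: pd.DataFrame,
    parameter: str,
    coding: dict[str, float] = DIAGNOSIS_CODING,
    **kw,
) -> LmeResult:
    """State-dependence model with within-cluster-centered mood.

    ``mood_within`` is the day's composite minus the subject's mean composite
    (within-person deviation); ``mood_between`` is the subject mean,
    grand-mean-centered.  Only days with both a mood composite and a fitted
    parameter enter (complete case).
    """
    series = _with_diagnosis(parameter_series(fits, parameter, **kw), coding)
    merged = series.merge(
        mood_days[["subject_id", "day", "composite"]], on=["subject_id", "day"], how="inner"
    )
    subj_mean = merged.groupby("subject_id")["composite"].transform("mean")
    merged["mood_within"] = merged["composite"] - subj_mean
    merged["mood_between"] = subj_mean - subj_mean.mean()
    merged["diagnosis:mood_within"] = merged["diagnosis"] * merged["mood_within"]
    merged["diagnosis:mood_between"] = merged["diagnosis"] * merged["mood_between"]
    fixed = [
        "repetition",
        "diagnosis",
        "mood_within",
        "mood_between",
        "diagnosis:mood_within",
        "diagnosis:mood_between",
    ]
    res = _fit_random_intercept(merged, "value", fixed, "mood", parameter)
    res.metadata["diagnosis_coding"] = dict(coding)
    return res


def lme_results_to_frame(results: list[LmeResult]) -> pd.DataFrame:
    """Long table with one row per term per model per outcome parameter."""
    frames = []
    for r in results:
        t = r.terms.copy()
        t.insert(0, "model", r.model)
        t.insert(0, "outcome", r.outcome)
        t["n_observations"] = r.n_observations
        t["n_subjects"] = r.n_subjects
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
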