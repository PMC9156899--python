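"""Between- vs within-person variance decomposition of day-level parameters.

The central quantity is the intraclass correlation coefficient from an
unconditional (intercept-only) linear mixed model with a subject random
intercept,

    ICC = sigma2_between / (sigma2_between + sigma2_within),

estimated by REML.  1 - ICC indexes day-to-day (within-person) variability.
A one-way ANOVA moment estimator is kept alongside as a closed-form
cross-check.  Week-level down-sampling (mean of each 7-day week, or one
randomly chosen day per week spaced >= 4 days apart) reproduces the coarser
sampling designs a lab study would use, and day-wise correlation matrices
summarize how distinct the parameters are from each other versus from
themselves over time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .seeds import substream

__all__ = [
    "VarianceDecomposition",
    "CorrelationMatrix",
    "compute_icc",
    "anova_icc",
    "downsample_week_mean",
    "downsample_random_days",
    "correlation_matrices",
]

logger = logging.getLogger(__name__)

PARAMETER_COLUMNS = ("risk_tol", "amb_tol", "log_kappa")


@dataclass
class VarianceDecomposition:
    """REML variance components and ICC for one parameter series."""

    parameter: str
    sigma2_between: float
    sigma2_within: float
    icc: float
    n_subjects: int
    n_observations: int
    grouping: str = "all"
    singular: bool = False


def compute_icc(
    data: pd.DataFrame,
    value_col: str,
    subject_col: str = "subject_id",
    grouping: str = "all",
) -> VarianceDecomposition:
    """ICC of a day-level parameter series from an intercept-only REML fit.

    ``data`` is long format with one row per subject-day; missing days are
    simply absent (censored).  A singular fit (between-person variance
    estimated at zero) returns ICC 0 with the ``singular`` flag set.
    """
    d = data[[subject_col, value_col]].dropna()
    counts = d.groupby(subject_col).size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 days each")
    endog = d[value_col].to_numpy(dtype=float)
    groups = d[subject_col].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, np.ones((len(endog), 1)), groups=groups)
        res = model.fit(reml=True)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    singular = tau2 <= 1e-10 * max(sigma2, 1e-12)
    icc = 0.0 if singular else tau2 / (tau2 + sigma2)
    return VarianceDecomposition(
        parameter=value_col,
        sigma2_between=0.0 if singular else tau2,
        sigma2_within=sigma2,
        icc=float(icc),
        n_subjects=int(len(counts)),
        n_observations=int(len(d)),
        grouping=grouping,
        singular=singular,
    )


def anova_icc(values, subjects) -> float:
    """One-way random-effects ANOVA (moment) estimator of the ICC.

    Closed form, used as an independent cross-check of the REML fit; negative
    between-variance moment estimates are truncated at zero.  Handles
    unbalanced groups via the standard average-group-size correction.
    """
    d = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(subjects)}).dropna()
    grp = d.groupby("g")["y"]
    n_i = grp.size().to_numpy(dtype=float)
    means = grp.mean().to_numpy()
    a, N = len(n_i), n_i.sum()
    grand = d["y"].mean()
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(((d["y"] - grp.transform("mean")) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    k0 = (N - np.sum(n_i**2) / N) / (a - 1)
    tau2 = max((ms_between - ms_within) / k0, 0.0)
    total = tau2 + ms_within
    return float(tau2 / total) if total > 0 else 0.0


def downsample_week_mean(
    fits: pd.DataFrame,
    value_cols: tuple[str, ...] = PARAMETER_COLUMNS,
    subject_col: str = "subject_id",
    day_col: str = "day",
) -> pd.DataFrame:
    """Collapse up to 28 daily values to 4 weekly means per subject.

    Weeks are days 1-7, 8-14, 15-21, 22-28; each week's value is the mean of
    the days the subject actually provided, and a week with no data is
    absent.  Averaging shrinks independent day noise by roughly the number of
    averaged days, so week-level ICCs run higher than day-level ones.
    """
    d = fits.copy()
    d["week"] = (d[day_col].astype(int) - 1) // 7 + 1
    keep = [c for c in value_cols if c in d.columns]
    out = d.groupby([subject_col, "week"], sort=True)[keep].mean().reset_index()
    return out.dropna(how="all", subset=keep)


def _eligible_combos(week_days: list[np.ndarray], min_gap: int) -> bool:
    """Whether any selection of one day per listed week satisfies the gap."""
    reachable = set(week_days[0].tolist())
    for days in week_days[1:]:
        reachable = {d for d in days.tolist() if any(d - r >= min_gap for r in reachable)}
        if not reachable:
            return False
    return True


def downsample_random_days(
    fits: pd.DataFrame,
    seed: int,
    value_cols: tuple[str, ...] = PARAMETER_COLUMNS,
    subject_col: str = "subject_id",
    day_col: str = "day",
    min_gap: int = 4,
    rule: str = "consecutive",
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Select one available day per week per subject, spaced >= ``min_gap``
    days apart, emulating sparse lab-style testing.

    ``rule='consecutive'`` constrains consecutively selected days (the
    default reading); ``rule='allpairs'`` constrains every pair.  Selection is
    by rejection resampling from the per-week uniform draw, seeded; a week
    with no data, or no day satisfying the constraint, is skipped for that
    subject.
    """
    if rule not in ("consecutive", "allpairs"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = substream(seed, "downsample")
    keep = [c for c in value_cols if c in fits.columns]
    d = fits.copy()
    d["week"] = (d[day_col].astype(int) - 1) // 7 + 1
    rows = []
    for subject, sub in d.groupby(subject_col, sort=True):
        weeks = {int(w): np.sort(g[day_col].unique()) for w, g in sub.groupby("week")}
        week_ids = sorted(weeks)
        selection = None
        for _ in range(max_tries):
            pick = [int(rng.choice(weeks[w])) for w in week_ids]
            gaps_ok = (
                all(b - a >= min_gap for a, b in zip(pick, pick[1:]))
                if rule == "consecutive"
                else all(pick[j] - pick[i] >= min_gap for i in range(len(pick)) for j in range(i + 1, len(pick)))
            )
            if gaps_ok:
                selection = dict(zip(week_ids, pick))
                break
        if selection is None:
            # No joint solution: drop weeks greedily until one exists.
            selection = {}
            last = -np.inf
            for w in week_ids:
                ok = weeks[w][weeks[w] - last >= min_gap]
                if len(ok) == 0:
                    logger.warning("subject %s week %d skipped: no eligible day", subject, w)
                    continue
                choice = int(rng.choice(ok))
                selection[w] = choice
                last = choice
        for w, day in selection.items():
            row = sub[sub[day_col] == day].iloc[0]
            rows.append({subject_col: subject, "week": w, day_col: int(day), **{c: row[c] for c in keep}})
    return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    """Across-subject correlations on the (parameter x day) grid.

    ``matrix`` is indexed by (parameter, day) on both axes; ``summary`` has
    one row per parameter pair: the mean/SD of same-day correlations for
    distinct parameters, and of across-day (test-retest) correlations within
    a parameter.
    """

    matrix: pd.DataFrame
    summary: pd.DataFrame


def correlation_matrices(
    fits: pd.DataFrame,
    parameters: dict[str, tuple[str, str]],
    subject_col: str = "subject_id",
    day_col: str = "day",
    min_subjects: int = 3,
) -> CorrelationMatrix:
    """Day-wise Pearson correlations between and within task parameters.

    ``parameters`` maps a display name to (task, value column), e.g.
    ``{"risk_tol_gain": ("risk-gain", "risk_tol")}``.  Correlations are
    computed across subjects with pairwise-complete observations; cells with
    fewer than ``min_subjects`` common subjects are NaN.
    """
    cols = {}
    for name, (task, col) in parameters.items():
        sub = fits[fits["task"] == task]
        wide = sub.pivot_table(index=subject_col, columns=day_col, values=col)
        for day in wide.columns:
            cols[(name, int(day))] = wide[day]
    grid = pd.DataFrame(cols)
    grid.columns = pd.MultiIndex.from_tuples(grid.columns, names=["parameter", "day"])
    corr = grid.corr(min_periods=min_subjects)

    rows = []
    names = list(parameters)
    for i, p1 in enumerate(names):
        for p2 in names[i:]:
            vals = []
            for (q1, d1) in corr.index:
                if q1 != p1:
                    continue
                for (q2, d2) in corr.columns:
                    if q2 != p2:
                        continue
                    if p1 == p2 and d1 >= d2:  # within-parameter: distinct day pairs
                        continue
                    if p1 != p2 and d1 != d2:  # between-parameter: same day only
                        continue
                    r = corr.loc[(q1, d1), (q2, d2)]
                    if np.isfinite(r):
                        vals.append(float(r))
            rows.append(
                {
                    "parameter_1": p1,
                    "parameter_2": p2,
                    "kind": "test_retest" if p1 == p2 else "between_parameter",
                    "mean_r": float(np.mean(vals)) if vals else np.nan,
                    "sd_r": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n_pairs": len(vals),
                }
            )
    return CorrelationMatrix(matrix=corr, summary=pd.DataFrame(rows))
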