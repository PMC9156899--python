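"""Per-subject-per-day maximum-likelihood estimation of task parameters.

Each subject-day-task administration is fit independently: (alpha, beta,
gamma) for a risk-task condition, (kappa, gamma) for the intertemporal task.
Optimization runs in a transformed space (logit-scaled within the parameter
box for alpha, beta, kappa; log-scaled for gamma) with a quasi-random
multi-start, which handles the bound constraints and the multimodality of
the likelihood in gamma.  An exhaustive grid evaluator over the same box is
provided as a testing oracle.

Model fit is summarized by BIC = k * ln(n_trials) + 2 * NLL, used to
arbitrate between the two datings of the "this week" option (delay 0 versus
delay 7 days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .models import (
    ALPHA_BOUNDS,
    BETA_BOUNDS,
    GAMMA_BOUNDS,
    KAPPA_BOUNDS,
    kappa_to_log,
    risk_to_reported,
)
from .seeds import substream_seed

__all__ = [
    "DayFit",
    "fit_risk_day",
    "fit_itc_day",
    "grid_oracle",
    "compare_delay_conventions",
    "fit_all",
    "fits_to_frame",
    "remap_convention",
]

logger = logging.getLogger(__name__)

DEFAULT_N_STARTS = 10
DEFAULT_MIN_TRIALS = 20
_BOUNDARY_TOL = 1e-3  # fraction of the box width counted as "at a bound"


@dataclass
class DayFit:
    """Fitted parameters and diagnostics for one subject-day-task."""

    subject_id: str
    day: int
    task: str  # "risk-gain" | "risk-loss" | "itc"
    params: dict[str, float]
    reported: dict[str, float]
    neg_log_likelihood: float
    bic: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    group: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bounded <-> unconstrained reparameterization
# ---------------------------------------------------------------------------


def _to_unconstrained(x, lo, hi):
    z = np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return logit(z)


def _from_unconstrained(u, lo, hi):
    return lo + (hi - lo) * expit(np.asarray(u, dtype=float))


class _Space:
    """Box-constrained parameter space with a logit reparameterization.

    gamma is handled on the log scale (then logit-scaled within the log-box),
    which conditions the likelihood far better than the raw scale.
    """

    def __init__(self, bounds: list[tuple[float, float]], log_scale: list[bool]):
        self.lo = np.array([np.log(b[0]) if s else b[0] for b, s in zip(bounds, log_scale)])
        self.hi = np.array([np.log(b[1]) if s else b[1] for b, s in zip(bounds, log_scale)])
        self.log_scale = np.array(log_scale)
        self.bounds = bounds

    def _internal(self, theta) -> np.ndarray:
        x = np.array(theta, dtype=float)
        x[self.log_scale] = np.log(x[self.log_scale])
        return x

    def constrain(self, u):
        x = _from_unconstrained(u, self.lo, self.hi)
        out = np.asarray(x)
        return np.where(self.log_scale, np.exp(out), out)

    def unconstrain(self, theta):
        return _to_unconstrained(self._internal(theta), self.lo, self.hi)

    def sobol_starts(self, n: int, seed: int) -> np.ndarray:
        m = int(np.ceil(np.log2(max(n, 2))))
        frac = qmc.Sobol(d=len(self.lo), scramble=True, seed=seed).random_base2(m)[:n]
        internal = self.lo + (0.02 + 0.96 * frac) * (self.hi - self.lo)
        return _to_unconstrained(internal, self.lo, self.hi)

    def at_boundary(self, theta) -> bool:
        x = self._internal(theta)
        width = self.hi - self.lo
        return bool(np.any((x - self.lo < _BOUNDARY_TOL * width) | (self.hi - x < _BOUNDARY_TOL * width)))


_RISK_SPACE = _Space([ALPHA_BOUNDS, BETA_BOUNDS, GAMMA_BOUNDS], [False, False, True])
_ITC_SPACE = _Space([KAPPA_BOUNDS, GAMMA_BOUNDS], [True, True])


# ---------------------------------------------------------------------------
# negative log-likelihoods (vectorized over trials)
# ---------------------------------------------------------------------------


def _bernoulli_nll(z: np.ndarray, y: np.ndarray) -> float:
    """-sum log P(y) for logistic P(choose) = expit(z); numerically stable."""
    return float(np.sum(np.logaddexp(0.0, np.where(y == 1, -z, z))))


def _risk_arrays(records: pd.DataFrame):
    return (
        records["v"].to_numpy(dtype=float),
        records["guaranteed"].to_numpy(dtype=float),
        records["p"].to_numpy(dtype=float),
        records["A"].to_numpy(dtype=float),
        records["choice"].to_numpy(dtype=int),
    )


def _risk_nll(theta, v, g, p, A, y) -> float:
    alpha, beta, gamma = theta
    eu_l = np.clip(p - beta * A / 2.0, 0.0, 1.0) * np.sign(v) * np.abs(v) ** alpha
    eu_s = np.sign(g) * np.abs(g) ** alpha
    return _bernoulli_nll(gamma * (eu_l - eu_s), y)


def _itc_arrays(records: pd.DataFrame):
    return (
        records["v_immediate"].to_numpy(dtype=float),
        records["v_delayed"].to_numpy(dtype=float),
        records["d_immediate"].to_numpy(dtype=float),
        records["d_delayed"].to_numpy(dtype=float),
        records["choice"].to_numpy(dtype=int),
    )


def _itc_nll(theta, vi, vd, di, dd, y) -> float:
    kappa, gamma = theta
    u_d = vd / (1.0 + kappa * dd)
    u_i = vi / (1.0 + kappa * di)
    return _bernoulli_nll(gamma * (u_d - u_i), y)


def _bic(nll: float, k: int, n: int) -> float:
    return k * np.log(n) + 2.0 * nll


# ---------------------------------------------------------------------------
# multi-start bounded MLE
# ---------------------------------------------------------------------------


def _multistart_mle(nll_constrained, space: _Space, seed: int, n_starts: int, extra_starts=()):
    """Multi-start bounded MLE in the unconstrained space.

    Quasi-random starts are refined with L-BFGS-B; grid-candidate starts
    (which already sit in promising basins) additionally get a Nelder-Mead
    refinement, since the probability clamp makes the surface piecewise
    smooth and gradient steps can stall on its kinks.  The overall best run
    receives a final Nelder-Mead polish.
    """

    def f(u):
        return nll_constrained(space.constrain(u))

    def _nm(u0):
        return minimize(f, u0, method="Nelder-Mead", options={"xatol": 1e-7, "fatol": 1e-10})

    best_u, best_nll, used = None, np.inf, 0

    def _consider(res):
        nonlocal best_u, best_nll
        if np.isfinite(res.fun) and res.fun < best_nll - 1e-12:
            best_nll, best_u = float(res.fun), res.x

    for u0 in space.sobol_starts(n_starts, seed):
        _consider(minimize(f, u0, method="L-BFGS-B"))
        used += 1
    for theta0 in extra_starts:
        u0 = space.unconstrain(np.asarray(theta0, dtype=float))
        res = minimize(f, u0, method="L-BFGS-B")
        _consider(res)
        _consider(_nm(res.x))
        used += 1
    _consider(_nm(best_u))
    theta = space.constrain(best_u)
    return theta, best_nll, used


def fit_risk_day(
    records: pd.DataFrame,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> DayFit:
    """Fit (alpha, beta, gamma) by bounded MLE for one subject-day-condition.

    ``records`` needs columns v, guaranteed, p, A, choice, all from one
    condition.  Days on which every choice is identical carry no interior
    information; they are fit anyway but flagged ``converged=False`` so that
    downstream variance decompositions can exclude them.
    """
    if len(records) == 0:
        raise ValueError("no records to fit")
    conditions = set(np.where(records["v"].to_numpy(dtype=float) > 0, "gain", "loss"))
    if len(conditions) > 1:
        raise ValueError("records mix gain and loss trials")
    condition = conditions.pop()
    arrays = _risk_arrays(records)
    y = arrays[-1]
    candidates = _grid_candidates(records, "risk", (20, 20, 10), k=5)
    theta, nll, used = _multistart_mle(
        lambda t: _risk_nll(t, *arrays),
        _RISK_SPACE,
        seed,
        n_starts,
        extra_starts=candidates,
    )
    alpha, beta, gamma = (float(t) for t in theta)
    degenerate = len(np.unique(y)) < 2
    converged = not degenerate and not _RISK_SPACE.at_boundary(theta)
    risk_tol, amb_tol = risk_to_reported(alpha, beta, condition)
    return DayFit(
        subject_id=str(records["subject_id"].iloc[0]) if "subject_id" in records else "",
        day=int(records["day"].iloc[0]) if "day" in records else 0,
        task=f"risk-{condition}",
        params={"alpha": alpha, "beta": beta, "gamma": gamma},
        reported={"risk_tol": risk_tol, "amb_tol": amb_tol},
        neg_log_likelihood=nll,
        bic=_bic(nll, 3, len(records)),
        n_trials=len(records),
        converged=converged,
        n_restarts_used=used,
        group=str(records["group"].iloc[0]) if "group" in records else None,
    )


def remap_convention(records: pd.DataFrame, convention: str) -> pd.DataFrame:
    """Re-date intertemporal delays under a convention.

    The physical trial is the same either way; the week gap between the two
    options is preserved and the "this week" option is dated at 0 or 7 days.
    """
    try:
        base = {"immediate0": 0, "immediate7": 7}[convention]
    except KeyError:
        raise ValueError(f"unknown convention {convention!r}") from None
    weeks = np.rint(
        (records["d_delayed"].to_numpy(dtype=float) - records["d_immediate"].to_numpy(dtype=float)) / 7.0
    )
    out = records.copy()
    out["d_immediate"] = base
    out["d_delayed"] = base + 7 * weeks.astype(int)
    return out


def fit_itc_day(
    records: pd.DataFrame,
    convention: str = "immediate0",
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> DayFit:
    """Fit (kappa, gamma) by bounded MLE for one subject-day under a delay
    convention.  An always-delayed chooser drives kappa to its lower bound
    (0.0001) and the fit is flagged non-converged."""
    if len(records) == 0:
        raise ValueError("no records to fit")
    records = remap_convention(records, convention)
    arrays = _itc_arrays(records)
    y = arrays[-1]
    candidates = _grid_candidates(records, "itc", (25, 10), k=3, convention=convention)
    theta, nll, used = _multistart_mle(
        lambda t: _itc_nll(t, *arrays),
        _ITC_SPACE,
        seed,
        n_starts,
        extra_starts=candidates,
    )
    kappa, gamma = (float(t) for t in theta)
    degenerate = len(np.unique(y)) < 2
    converged = not degenerate and not _ITC_SPACE.at_boundary(theta)
    return DayFit(
        subject_id=str(records["subject_id"].iloc[0]) if "subject_id" in records else "",
        day=int(records["day"].iloc[0]) if "day" in records else 0,
        task="itc",
        params={"kappa": kappa, "gamma": gamma},
        reported={"log_kappa": kappa_to_log(kappa)},
        neg_log_likelihood=nll,
        bic=_bic(nll, 2, len(records)),
        n_trials=len(records),
        converged=converged,
        n_restarts_used=used,
        group=str(records["group"].iloc[0]) if "group" in records else None,
        extra={"convention": convention},
    )


# ---------------------------------------------------------------------------
# exhaustive grid oracle (testing only)
# ---------------------------------------------------------------------------


def _risk_grid(records: pd.DataFrame, resolution: tuple[int, int, int]):
    """NLL over an (alpha, gamma, beta) lattice on the bounded box."""
    na, nb, ng = resolution
    alphas = np.linspace(*ALPHA_BOUNDS, na)
    alphas[0] = 1e-6  # alpha exactly 0 makes every utility +-1; keep interior
    betas = np.linspace(*BETA_BOUNDS, nb)
    gammas = np.geomspace(*GAMMA_BOUNDS, ng)
    v, g, p, A, y = _risk_arrays(records)
    sign_v, abs_v = np.sign(v), np.abs(v)
    sign_g, abs_g = np.sign(g), np.abs(g)
    peff = np.clip(p[None, :] - betas[:, None] * A[None, :] / 2.0, 0.0, 1.0)
    nll = np.empty((na, ng, nb))
    for ia, alpha in enumerate(alphas):
        diff = peff * (sign_v * abs_v**alpha)[None, :] - (sign_g * abs_g**alpha)[None, :]
        z = gammas[:, None, None] * diff[None, :, :]
        nll[ia] = np.logaddexp(0.0, np.where(y == 1, -z, z)).sum(axis=2)
    return alphas, gammas, betas, nll


def _itc_grid(records: pd.DataFrame, resolution: tuple[int, int], convention: str):
    nk, ng = resolution
    kappas = np.geomspace(*KAPPA_BOUNDS, nk)
    gammas = np.geomspace(*GAMMA_BOUNDS, ng)
    rec = remap_convention(records, convention)
    vi, vd, di, dd, y = _itc_arrays(rec)
    diff = vd[None, :] / (1.0 + kappas[:, None] * dd[None, :]) - vi[None, :] / (
        1.0 + kappas[:, None] * di[None, :]
    )
    z = gammas[:, None, None] * diff[None, :, :]
    nll = np.logaddexp(0.0, np.where(y == 1, -z, z)).sum(axis=2)
    return kappas, gammas, nll


def _grid_candidates(records, model, resolution, k, convention="immediate0"):
    """Top-k lattice points by NLL, as parameter tuples in fit order."""
    if model == "risk":
        alphas, gammas, betas, nll = _risk_grid(records, resolution)
        idx = np.argsort(nll.ravel())[:k]
        return [
            (alphas[ia], betas[ib], gammas[ig])
            for ia, ig, ib in (np.unravel_index(i, nll.shape) for i in idx)
        ]
    kappas, gammas, nll = _itc_grid(records, resolution, convention)
    idx = np.argsort(nll.ravel())[:k]
    return [(kappas[ik], gammas[ig]) for ig, ik in (np.unravel_index(i, nll.shape) for i in idx)]


def grid_oracle(
    records: pd.DataFrame,
    model: str,
    resolution: tuple[int, ...] | None = None,
    convention: str = "immediate0",
):
    """Best parameters over an exhaustive grid on the bounded box.

    At high resolution this is the testing oracle that bounds the MLE's NLL
    from above; at low resolution the same lattice seeds the multi-start.
    Returns (params dict, nll).
    """
    if model == "risk":
        alphas, gammas, betas, nll = _risk_grid(records, resolution or (50, 50, 20))
        ia, ig, ib = np.unravel_index(np.argmin(nll), nll.shape)
        return (
            {"alpha": float(alphas[ia]), "beta": float(betas[ib]), "gamma": float(gammas[ig])},
            float(nll[ia, ig, ib]),
        )
    if model == "itc":
        kappas, gammas, nll = _itc_grid(records, resolution or (50, 20), convention)
        ig, ik = np.unravel_index(np.argmin(nll), nll.shape)
        return {"kappa": float(kappas[ik]), "gamma": float(gammas[ig])}, float(nll[ig, ik])
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# delay-convention comparison and batch fitting
# ---------------------------------------------------------------------------


def compare_delay_conventions(
    itc_records: pd.DataFrame,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> tuple[pd.DataFrame, str]:
    """BIC per subject-day under both delay conventions and the overall winner.

    The winner is the convention with the smaller summed BIC across all
    subject-days; exact ties go to ``immediate0``.
    """
    rows = []
    for (subject, day), grp in itc_records.groupby(["subject_id", "day"], sort=True):
        fits = {
            conv: fit_itc_day(
                grp, convention=conv, seed=substream_seed(seed, "fit", subject, day, conv), n_starts=n_starts
            )
            for conv in ("immediate0", "immediate7")
        }
        rows.append(
            {
                "subject_id": subject,
                "day": day,
                "bic_immediate0": fits["immediate0"].bic,
                "bic_immediate7": fits["immediate7"].bic,
            }
        )
    table = pd.DataFrame(rows)
    total0 = table["bic_immediate0"].sum()
    total7 = table["bic_immediate7"].sum()
    winner = "immediate0" if total0 <= total7 else "immediate7"
    return table, winner


def fits_to_frame(fits: list[DayFit]) -> pd.DataFrame:
    """Flatten DayFit objects to the long fits table (one row per
    subject-day-task)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "subject_id": f.subject_id,
                "group": f.group,
                "day": f.day,
                "task": f.task,
                "alpha": f.params.get("alpha", np.nan),
                "beta": f.params.get("beta", np.nan),
                "gamma": f.params.get("gamma", np.nan),
                "kappa": f.params.get("kappa", np.nan),
                "risk_tol": f.reported.get("risk_tol", np.nan),
                "amb_tol": f.reported.get("amb_tol", np.nan),
                "log_kappa": f.reported.get("log_kappa", np.nan),
                "nll": f.neg_log_likelihood,
                "bic": f.bic,
                "n_trials": f.n_trials,
                "converged": f.converged,
                "n_restarts_used": f.n_restarts_used,
            }
        )
    return pd.DataFrame(rows)


def fit_all(
    choices: pd.DataFrame,
    seed: int = 0,
    convention: str = "immediate0",
    min_trials: int = DEFAULT_MIN_TRIALS,
    n_starts: int = DEFAULT_N_STARTS,
) -> pd.DataFrame:
    """Fit every subject-day-task in a long choice table.

    Days with fewer than ``min_trials`` presented trials are excluded with a
    log warning (partial administrations are not fit).  Missing days are
    simply absent — never imputed.  Returns the long fits table.
    """
    fits: list[DayFit] = []
    n_excluded = 0
    for (subject, day, task), grp in choices.groupby(["subject_id", "day", "task"], sort=True):
        if len(grp) < min_trials:
            n_excluded += 1
            logger.warning(
                "excluding %s day %s task %s: %d < %d trials", subject, day, task, len(grp), min_trials
            )
            continue
        fit_seed = substream_seed(seed, "fit", subject, day, task)
        if task == "itc":
            fits.append(fit_itc_day(grp, convention=convention, seed=fit_seed, n_starts=n_starts))
        elif task in ("risk-gain", "risk-loss"):
            fits.append(fit_risk_day(grp, seed=fit_seed, n_starts=n_starts))
        else:
            raise ValueError(f"unknown task {task!r}")
    if n_excluded:
        logger.info("excluded %d short subject-day-tasks", n_excluded)
    return fits_to_frame(fits)
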