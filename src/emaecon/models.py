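"""Utility and choice-probability models for the risk/ambiguity and intertemporal tasks.

Two model families are implemented:

* A power-utility model with a linear ambiguity penalty for choices between
  a guaranteed amount and a lottery whose winning probability may be partly
  occluded.  The expected utility of an option is

      EU = [p - beta * (A / 2)] * sign(v) * |v| ** alpha

  where ``p`` is the known probability, ``A`` the occluded fraction of the
  probability scale, ``alpha`` the risk-tolerance curvature and ``beta`` the
  ambiguity attitude.  ``alpha = 1`` is risk-neutral in gains, ``beta = 0``
  ambiguity-neutral.

* A linear-utility hyperbolic discounting model for smaller-sooner versus
  larger-later money choices,

      U = v / (1 + kappa * d)

  with ``kappa`` the discount rate per day.

Both map utility differences to choice probabilities through a logistic
with inverse temperature ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
    "KAPPA_BOUNDS",
    "GAMMA_BOUNDS",
    "RiskParams",
    "TimeParams",
    "effective_probability",
    "utility_value",
    "expected_utility",
    "safe_utility",
    "prob_choose_lottery",
    "discounted_utility",
    "prob_choose_delayed",
    "risk_to_reported",
    "reported_to_risk",
    "kappa_to_log",
    "log_to_kappa",
    "to_reported",
]

# Parameter boxes used both for estimation and for validity checks.
ALPHA_BOUNDS = (0.0, 10.0)
BETA_BOUNDS = (-5.0, 5.0)
KAPPA_BOUNDS = (1e-4, 1.0)
# No published bounds for the stochasticity parameter; this default keeps the
# likelihood away from flat (gamma -> 0) and step-function (gamma -> inf)
# degeneracies.
GAMMA_BOUNDS = (1e-3, 50.0)


@dataclass(frozen=True)
class RiskParams:
    """Risk-task parameters: curvature ``alpha``, ambiguity attitude ``beta``,
    choice stochasticity ``gamma``."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]):
            raise ValueError(f"alpha {self.alpha} outside {ALPHA_BOUNDS}")
        if not (BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]):
            raise ValueError(f"beta {self.beta} outside {BETA_BOUNDS}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class TimeParams:
    """Intertemporal-task parameters: hyperbolic rate ``kappa`` (per day) and
    choice stochasticity ``gamma``."""

    kappa: float
    gamma: float

    def __post_init__(self) -> None:
        if not (KAPPA_BOUNDS[0] <= self.kappa <= KAPPA_BOUNDS[1]):
            raise ValueError(f"kappa {self.kappa} outside {KAPPA_BOUNDS}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def effective_probability(p, A, beta):
    """Winning probability after the ambiguity penalty, clamped to [0, 1].

    The clamp is required because ``beta`` in [-5, 5] can push
    ``p - beta * A / 2`` outside the probability scale.
    """
    return np.clip(p - beta * (np.asarray(A) / 2.0), 0.0, 1.0)


def utility_value(v, alpha):
    """Power utility of a signed amount: ``sign(v) * |v| ** alpha``.

    The sign-preserving form extends ``v ** alpha`` to the loss domain, where
    ``v < 0`` with non-integer ``alpha`` would otherwise be undefined; it keeps
    ``alpha = 1`` the expected-value maximizer in both domains.
    """
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.abs(v) ** alpha


def expected_utility(trial, params: RiskParams):
    """Expected utility of a lottery trial under ``params``.

    ``trial`` is anything with ``v``, ``p`` and ``A`` attributes (a
    :class:`~emaecon.tasks.RiskTrial` or a DataFrame row namespace).
    """
    return effective_probability(trial.p, trial.A, params.beta) * utility_value(
        trial.v, params.alpha
    )


def safe_utility(guaranteed, alpha):
    """Utility of the guaranteed option, a degenerate lottery with p=1, A=0."""
    return utility_value(guaranteed, alpha)


def prob_choose_lottery(eu_lottery, eu_safe, gamma):
    """Logistic choice probability of taking the lottery over the sure amount."""
    return expit(gamma * (np.asarray(eu_lottery) - np.asarray(eu_safe)))


def discounted_utility(v, d, kappa):
    """Hyperbolically discounted value ``v / (1 + kappa * d)``."""
    return np.asarray(v, dtype=float) / (1.0 + kappa * np.asarray(d, dtype=float))


def prob_choose_delayed(u_delayed, u_immediate, gamma):
    """Logistic choice probability of taking the delayed over the sooner reward."""
    return expit(gamma * (np.asarray(u_delayed) - np.asarray(u_immediate)))


# ---------------------------------------------------------------------------
# Reporting transforms.  Raw (alpha, beta) have opposite behavioral readings
# in gains and losses; the reported scales are oriented so that larger always
# means more tolerant: risk tolerance is alpha - 1 in gains and 1 - alpha in
# losses, ambiguity tolerance is -beta in gains and beta in losses, and the
# discount rate is reported as log(kappa).
# ---------------------------------------------------------------------------


def risk_to_reported(alpha: float, beta: float, condition: str) -> tuple[float, float]:
    """Map raw (alpha, beta) to (risk tolerance, ambiguity tolerance)."""
    if condition == "gain":
        return alpha - 1.0, -beta
    if condition == "loss":
        return 1.0 - alpha, beta
    raise ValueError(f"unknown condition {condition!r}")


def reported_to_risk(risk_tol: float, amb_tol: float, condition: str) -> tuple[float, float]:
    """Inverse of :func:`risk_to_reported`; exact round-trip."""
    if condition == "gain":
        return risk_tol + 1.0, -amb_tol
    if condition == "loss":
        return 1.0 - risk_tol, amb_tol
    raise ValueError(f"unknown condition {condition!r}")


def kappa_to_log(kappa: float) -> float:
    return float(np.log(kappa))


def log_to_kappa(log_kappa: float) -> float:
    return float(np.exp(log_kappa))


def to_reported(params, condition: str | None = None) -> dict[str, float]:
    """Reported-scale summary of a parameter set.

    Risk parameters require the task condition; intertemporal parameters do
    not take one.
    """
    if isinstance(params, RiskParams):
        if condition not in ("gain", "loss"):
            raise ValueError("risk parameters need condition 'gain' or 'loss'")
        risk_tol, amb_tol = risk_to_reported(params.alpha, params.beta, condition)
        return {"risk_tol": risk_tol, "amb_tol": amb_tol}
    if isinstance(params, TimeParams):
        return {"log_kappa": kappa_to_log(params.kappa)}
    raise TypeError(f"unsupported parameter type {type(params)!r}")
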