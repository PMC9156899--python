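"""Trial-set generators for the two smartphone tasks and the daily bonus rule.

The risk task offers a guaranteed +-$0.50 against a two-outcome lottery
($0 or v) whose winning probability is either fully known (risk trials) or
partly occluded (ambiguity trials).  The intertemporal task offers a smaller
reward available "this week" against a larger reward delayed one to three
weeks.  One trial from one completed task per day is drawn at random and
played out for a real bonus, capped at $6.60.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RISK_VALUES",
    "RISK_PROBABILITIES",
    "AMBIGUITY_LEVELS",
    "GUARANTEED_AMOUNT",
    "AMBIGUOUS_BASE_P",
    "ITC_GRID",
    "ITC_DELAY_WEEKS",
    "MAX_BONUS",
    "RiskTrial",
    "IntertemporalTrial",
    "BonusOutcome",
    "generate_risk_trials",
    "generate_itc_trials",
    "realize_bonus",
]

# Lottery magnitudes in dollars (gain condition; the loss condition mirrors
# them with negated signs).  Built from integer cents so multiset comparisons
# between generated sets are exact.
_RISK_VALUE_CENTS = (60, 80, 120, 180, 260, 390, 440, 660)
RISK_VALUES = tuple(c / 100 for c in _RISK_VALUE_CENTS)
RISK_PROBABILITIES = (0.25, 0.50, 0.75)
AMBIGUITY_LEVELS = (0.24, 0.50, 0.74)
GUARANTEED_AMOUNT = 0.50
# On ambiguity trials the occluder is centered on the probability scale, so
# the nominal (displayed midpoint) winning probability is 0.50.
AMBIGUOUS_BASE_P = 0.50

# Immediate amount -> the five delayed amounts offered against it (dollars).
ITC_GRID = {
    0.20: (0.70, 1.20, 2.20, 4.20, 6.60),
    0.50: (1.00, 1.50, 2.50, 4.50, 6.50),
    1.50: (2.00, 2.50, 3.50, 5.50, 6.50),
}
ITC_DELAY_WEEKS = (1, 2, 3)

MAX_BONUS = 6.60


@dataclass(frozen=True)
class RiskTrial:
    """One guaranteed-vs-lottery offer.

    ``A == 0`` marks a known-risk trial (p in {.25, .50, .75}); ``A > 0``
    marks an ambiguity trial where ``p`` is the nominal midpoint 0.50 and
    ``A`` is the occluded fraction of the probability scale.
    """

    condition: str  # "gain" | "loss"
    guaranteed: float
    v: float
    p: float
    A: float

    def __post_init__(self) -> None:
        if self.condition not in ("gain", "loss"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("A must lie in [0, 1]")
        sign = 1.0 if self.condition == "gain" else -1.0
        if sign * self.v <= 0 or sign * self.guaranteed <= 0:
            raise ValueError("amount signs must match the condition")


@dataclass(frozen=True)
class IntertemporalTrial:
    """One smaller-sooner vs larger-later money offer; delays in days."""

    v_immediate: float
    v_delayed: float
    d_immediate: int
    d_delayed: int

    def __post_init__(self) -> None:
        if self.v_immediate <= 0 or self.v_delayed <= 0:
            raise ValueError("amounts must be positive")
        if self.v_delayed < self.v_immediate + 0.50 - 1e-9:
            raise ValueError("delayed reward must exceed immediate by >= $0.50")
        if self.d_delayed <= self.d_immediate:
            raise ValueError("delayed option must be later than the sooner one")


@dataclass(frozen=True)
class BonusOutcome:
    """Realized daily bonus: which task it came from and the amount paid."""

    day: int
    source_task: str  # "risk-gain" | "risk-loss" | "itc"
    realized_amount: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.realized_amount <= MAX_BONUS + 1e-9:
            raise ValueError("bonus outside [0, 6.60]")


def _risk_offer_grid(repeated_value: float) -> list[tuple[float, float, float]]:
    """(v, p, A) offers for the gain condition: the 8 x 3 known-risk grid and
    the 8 x 3 ambiguity grid, plus one repeat of ``repeated_value`` per
    probability and per ambiguity level (48 distinct offers padded to 54)."""
    if repeated_value not in RISK_VALUES:
        raise ValueError(f"repeated value {repeated_value} not a task value level")
    offers: list[tuple[float, float, float]] = []
    for p in RISK_PROBABILITIES:
        for v in RISK_VALUES:
            offers.append((v, p, 0.0))
        offers.append((repeated_value, p, 0.0))
    for A in AMBIGUITY_LEVELS:
        for v in RISK_VALUES:
            offers.append((v, AMBIGUOUS_BASE_P, A))
        offers.append((repeated_value, AMBIGUOUS_BASE_P, A))
    return offers


def generate_risk_trials(
    condition: str,
    seed: int,
    repeated_value: float = RISK_VALUES[0],
) -> list[RiskTrial]:
    """Generate the 54-trial risk-task set for one condition.

    27 known-risk and 27 ambiguity trials; the loss set is the gain set with
    every amount negated.  ``seed`` only shuffles presentation order — the
    multiset of offers is fixed.  The composition pads the 48 distinct offers
    with one extra presentation of ``repeated_value`` per probability and per
    ambiguity level.
    """
    if condition not in ("gain", "loss"):
        raise ValueError(f"unknown condition {condition!r}")
    sign = 1.0 if condition == "gain" else -1.0
    trials = [
        RiskTrial(
            condition=condition,
            guaranteed=sign * GUARANTEED_AMOUNT,
            v=sign * v,
            p=p,
            A=A,
        )
        for v, p, A in _risk_offer_grid(repeated_value)
    ]
    order = np.random.default_rng(seed).permutation(len(trials))
    return [trials[i] for i in order]


def generate_itc_trials(convention: str, seed: int) -> list[IntertemporalTrial]:
    """Generate the 45-trial intertemporal set: 3 immediate amounts x 5
    delayed amounts x 3 delays.

    ``convention`` fixes how the "this week" option is dated: ``immediate0``
    treats it as today (delays 7/14/21 days); ``immediate7`` as the end of the
    week (7 days, with delays 14/21/28).  ``seed`` shuffles order only.
    """
    try:
        base = {"immediate0": 0, "immediate7": 7}[convention]
    except KeyError:
        raise ValueError(f"unknown convention {convention!r}") from None
    trials = [
        IntertemporalTrial(
            v_immediate=v_now,
            v_delayed=v_later,
            d_immediate=base,
            d_delayed=base + 7 * weeks,
        )
        for v_now, laters in ITC_GRID.items()
        for v_later in laters
        for weeks in ITC_DELAY_WEEKS
    ]
    order = np.random.default_rng(seed).permutation(len(trials))
    return [trials[i] for i in order]


def _risk_payout(trial: RiskTrial, choice: int, rng: np.random.Generator) -> float:
    """Play out one risk-task choice; returns the bonus in dollars.

    Gains pay the realized amount directly; losses are subtracted from the
    $6.60 endowment and the remainder paid.  Ambiguous lotteries resolve at
    the nominal midpoint probability.
    """
    if choice:
        win = rng.random() < trial.p  # nominal p == effective p when A == 0
        outcome = trial.v if win else 0.0
    else:
        outcome = trial.guaranteed
    if trial.condition == "gain":
        return outcome
    return MAX_BONUS - abs(outcome)


def realize_bonus(
    day_choices: dict[str, Sequence[tuple[RiskTrial | IntertemporalTrial, int]]],
    rng_seed: int,
    day: int = 0,
) -> BonusOutcome | None:
    """Draw the day's bonus: one completed task uniformly, then one of its
    trials uniformly, played out according to the subject's choice.

    ``day_choices`` maps task label ("risk-gain", "risk-loss", "itc") to the
    (trial, choice) pairs completed that day; ``choice`` is 1 for the lottery
    or delayed option.  A day with no completed task earns no bonus (None).
    """
    completed = {k: v for k, v in day_choices.items() if len(v) > 0}
    if not completed:
        return None
    rng = np.random.default_rng(rng_seed)
    task = sorted(completed)[rng.integers(len(completed))]
    trial, choice = completed[task][rng.integers(len(completed[task]))]
    if isinstance(trial, IntertemporalTrial):
        amount = trial.v_delayed if choice else trial.v_immediate
    else:
        amount = _risk_payout(trial, choice, rng)
    return BonusOutcome(day=day, source_task=task, realized_amount=float(amount))
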