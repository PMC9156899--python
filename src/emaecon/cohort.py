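"""Synthetic EMA cohort generator.

Emulates the statistical structure of a 28-day smartphone study of economic
preferences in opioid-use-disorder (OUD) patients and matched controls:

* 23 patients and 21 controls, up to three task prompts per day (risk in
  gains, risk in losses, intertemporal choice), with group-dependent task
  compliance (patients ~54%, controls ~81%).
* Day-varying latent preferences on the reported scale (risk tolerance
  alpha-1 / 1-alpha, ambiguity tolerance -beta / beta, log kappa), built as
  person mean + repetition drift + mood coupling + truncated-Gaussian day
  noise, with between/within SDs chosen to hit target intraclass
  correlations.
* A stable patient-minus-control offset of +2.17 on log kappa (patients
  discount more steeply).
* An AR(1) mood process on a 0-100 composite scale whose within-person
  deviations shift gain-domain risk tolerance by 0.02 per mood point.
* Choices simulated on the exact task trial sets through the logistic choice
  models, then thinned at the prompt level by group compliance.

Everything is deterministic given (config, master seed).  The ground-truth
table of latent parameters is emitted alongside the observable tables so
recovery can be checked at any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import tasks
from .models import prob_choose_delayed, prob_choose_lottery
from .seeds import substream
from .variance import anova_icc

__all__ = ["PARAMETERS", "REPORTED_BOUNDS", "CohortConfig", "simulate_cohort", "truth_icc"]

PARAMETERS = ("risk_tol_gain", "risk_tol_loss", "amb_tol_gain", "amb_tol_loss", "log_kappa")

# Reported-scale supports implied by the estimation bounds
# (alpha in [0,10], beta in [-5,5], kappa in [1e-4, 1]).
REPORTED_BOUNDS = {
    "risk_tol_gain": (-1.0, 9.0),
    "risk_tol_loss": (-9.0, 1.0),
    "amb_tol_gain": (-5.0, 5.0),
    "amb_tol_loss": (-5.0, 5.0),
    "log_kappa": (float(np.log(1e-4)), 0.0),
}

_PARAM_TASK = {
    "risk_tol_gain": "risk-gain",
    "amb_tol_gain": "risk-gain",
    "risk_tol_loss": "risk-loss",
    "amb_tol_loss": "risk-loss",
    "log_kappa": "itc",
}


def _default_between_sd() -> dict[str, float]:
    # within SD * sqrt(ICC / (1 - ICC)) for target day-level ICCs of
    # 0.43 / 0.40 / 0.53 / 0.53 / 0.67 (noise components; repetition drift
    # and mood coupling add further within-person variation on top).
    return {
        "risk_tol_gain": 0.30 * float(np.sqrt(0.43 / 0.57)),
        "risk_tol_loss": 0.30 * float(np.sqrt(0.40 / 0.60)),
        "amb_tol_gain": 0.45 * float(np.sqrt(0.53 / 0.47)),
        "amb_tol_loss": 0.45 * float(np.sqrt(0.53 / 0.47)),
        "log_kappa": 1.0 * float(np.sqrt(0.67 / 0.33)),
    }


def _default_within_sd() -> dict[str, float]:
    # Day-to-day SDs kept small against the alpha/kappa support so the
    # truncation needed to stay inside the fit bounds rarely binds.
    return {
        "risk_tol_gain": 0.30,
        "risk_tol_loss": 0.30,
        "amb_tol_gain": 0.45,
        "amb_tol_loss": 0.45,
        "log_kappa": 1.0,
    }


@dataclass
class CohortConfig:
    """Generative settings for one synthetic study.

    Defaults reproduce the stated study world: sample sizes, group
    compliance means, the +2.17 patient offset in log kappa, 0.02/point mood
    coupling on gain risk tolerance, and repetition drifts of -0.08
    (risk tolerance in losses), -0.06 (ambiguity tolerance in losses) and
    -0.06 (log kappa) per completed administration.
    """

    n_patients: int = 23
    n_controls: int = 21
    n_days: int = 28

    compliance_patient: float = 0.5414
    compliance_control: float = 0.8084

    # population means on the reported scale (mildly risk- and
    # ambiguity-averse sample; controls at kappa ~ e^-5 per day)
    population_mean: dict[str, float] = field(
        default_factory=lambda: {
            "risk_tol_gain": 0.0,
            "risk_tol_loss": -0.10,
            "amb_tol_gain": -0.40,
            "amb_tol_loss": -0.20,
            "log_kappa": -5.5,
        }
    )
    between_sd: dict[str, float] = field(default_factory=_default_between_sd)
    within_sd: dict[str, float] = field(default_factory=_default_within_sd)

    # patient minus control shift in mean log kappa (patients steeper)
    group_logkappa_offset: float = 2.17

    # mood process (0-100 composite scale)
    mood_mean: float = 60.0
    mood_between_sd: float = 12.0
    mood_ar: float = 0.5
    mood_noise_sd: float = 10.0
    prompt_noise_sd: float = 2.0
    prompts_per_day: int = 3

    # within-person mood coupling on gain risk tolerance, per composite point
    mood_effect: float = 0.02
    mood_effect_patient_extra: float = 0.0

    # drift per additional completed administration of the relevant task
    repetition_drift: dict[str, float] = field(
        default_factory=lambda: {"risk_tol_loss": -0.08, "amb_tol_loss": -0.06, "log_kappa": -0.06}
    )

    # generative choice stochasticity
    gamma_risk: float = 3.0
    gamma_itc: float = 1.5

    itc_convention: str = "immediate0"

    def validate(self) -> None:
        for name, rate in (
            ("compliance_patient", self.compliance_patient),
            ("compliance_control", self.compliance_control),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for d in (self.between_sd, self.within_sd):
            for p, sd in d.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {p}")
        if min(self.mood_between_sd, self.mood_noise_sd, self.prompt_noise_sd) < 0:
            raise ValueError("negative mood SD")
        if not -1.0 < self.mood_ar < 1.0:
            raise ValueError("mood AR(1) coefficient must lie in (-1, 1)")
        if self.n_patients < 0 or self.n_controls < 0 or self.n_days < 1:
            raise ValueError("invalid cohort dimensions")

    def with_icc_target(self, parameter: str, icc: float) -> "CohortConfig":
        """Copy of the config whose between-SD for ``parameter`` is set so the
        latent series has the requested ICC at the current within-SD."""
        if not 0.0 < icc < 1.0:
            raise ValueError("target ICC must lie in (0, 1)")
        b = dict(self.between_sd)
        b[parameter] = self.within_sd[parameter] * float(np.sqrt(icc / (1.0 - icc)))
        return replace(self, between_sd=b)


def _truncated_normal(rng, mean, sd, lo, hi):
    """Gaussian draw(s) truncated to [lo, hi]; degenerate sd returns the
    clipped mean."""
    mean = np.asarray(mean, dtype=float)
    if np.isscalar(sd) and sd == 0:
        return np.clip(mean, lo, hi)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    size = np.shape(mean) if np.shape(mean) else None
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _simulate_task_choices(trials, params, gamma, task, rng):
    """Bernoulli choices on a trial list under the logistic choice model."""
    rows = []
    for idx, tr in enumerate(trials):
        if task == "itc":
            kappa = params
            u_d = tr.v_delayed / (1.0 + kappa * tr.d_delayed)
            u_i = tr.v_immediate / (1.0 + kappa * tr.d_immediate)
            pr = prob_choose_delayed(u_d, u_i, gamma)
            rows.append(
                {
                    "trial_index": idx,
                    "guaranteed": np.nan,
                    "v": np.nan,
                    "p": np.nan,
                    "A": np.nan,
                    "v_immediate": tr.v_immediate,
                    "v_delayed": tr.v_delayed,
                    "d_immediate": tr.d_immediate,
                    "d_delayed": tr.d_delayed,
                    "choice": int(rng.random() < pr),
                }
            )
        else:
            alpha, beta = params
            eff = np.clip(tr.p - beta * tr.A / 2.0, 0.0, 1.0)
            eu_l = eff * np.sign(tr.v) * abs(tr.v) ** alpha
            eu_s = np.sign(tr.guaranteed) * abs(tr.guaranteed) ** alpha
            pr = prob_choose_lottery(eu_l, eu_s, gamma)
            rows.append(
                {
                    "trial_index": idx,
                    "guaranteed": tr.guaranteed,
                    "v": tr.v,
                    "p": tr.p,
                    "A": tr.A,
                    "v_immediate": np.nan,
                    "v_delayed": np.nan,
                    "d_immediate": np.nan,
                    "d_delayed": np.nan,
                    "choice": int(rng.random() < pr),
                }
            )
    return rows


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    include_choices: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one study: (choices, ratings, truth) long tables.

    ``include_choices=False`` skips the trial-level choice simulation (the
    expensive part) and returns an empty choices table; the latent truth and
    mood tables are unchanged, which is what generator-level calibration
    checks need.
    """
    config.validate()
    n_subjects = config.n_patients + config.n_controls
    groups = ["OUD"] * config.n_patients + ["control"] * config.n_controls
    subject_ids = [f"{'P' if g == 'OUD' else 'C'}{i:03d}" for i, g in enumerate(groups, 1)]
    days = np.arange(1, config.n_days + 1)

    truth_rows = []
    rating_rows = []
    choice_frames = []

    for s_idx, (sid, group) in enumerate(zip(subject_ids, groups)):
        is_patient = group == "OUD"
        rng = substream(seed, "subject", sid)

        # --- person means on the reported scale ------------------------------
        person_mean = {}
        for p in PARAMETERS:
            mu = config.population_mean[p]
            if p == "log_kappa" and is_patient:
                mu = mu + config.group_logkappa_offset
            lo, hi = REPORTED_BOUNDS[p]
            person_mean[p] = float(_truncated_normal(rng, mu, config.between_sd[p], lo, hi))

        # --- compliance and repetition counts --------------------------------
        rate = config.compliance_patient if is_patient else config.compliance_control
        completed = rng.random((config.n_days, 3)) < rate  # columns: risk-gain, risk-loss, itc
        task_names = ("risk-gain", "risk-loss", "itc")
        # running count of completed administrations, counting the current day
        # as if completed (the count a completed day would carry)
        rep = np.cumsum(completed, axis=0)
        rep_asif = np.where(completed, rep, rep + 1)

        # --- mood process -----------------------------------------------------
        person_mood = float(
            _truncated_normal(rng, config.mood_mean, config.mood_between_sd, 15.0, 95.0)
        )
        stat_sd = config.mood_noise_sd / np.sqrt(1.0 - config.mood_ar**2)
        dev = np.empty(config.n_days)
        dev[0] = rng.normal(0.0, stat_sd)
        for d in range(1, config.n_days):
            dev[d] = config.mood_ar * dev[d - 1] + rng.normal(0.0, config.mood_noise_sd)
        composite = np.clip(person_mood + dev, 0.0, 100.0)
        mood_centered = composite - person_mood

        # --- day-level latent parameters -------------------------------------
        mood_slope = config.mood_effect + (config.mood_effect_patient_extra if is_patient else 0.0)
        # Day values are Gaussian around the structural mean, clipped to the
        # reported-scale support so inverted (alpha, beta, kappa) always lie
        # inside the fit bounds.  Clipping (rather than resampling the whole
        # tail) leaves the linear mood/drift structure intact except for the
        # rare draws that actually hit a bound.
        day_params = {}
        for p in PARAMETERS:
            lo, hi = REPORTED_BOUNDS[p]
            task_col = task_names.index(_PARAM_TASK[p])
            mu_day = np.full(config.n_days, person_mean[p])
            mu_day = mu_day + config.repetition_drift.get(p, 0.0) * (rep_asif[:, task_col] - 1)
            if p == "risk_tol_gain":
                mu_day = mu_day + mood_slope * mood_centered
            noise = rng.normal(0.0, config.within_sd[p], config.n_days) if config.within_sd[p] > 0 else 0.0
            day_params[p] = np.clip(mu_day + noise, lo, hi)

        for d_idx, day in enumerate(days):
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "day": int(day),
                    **{p: float(day_params[p][d_idx]) for p in PARAMETERS},
                    **{f"person_mean_{p}": person_mean[p] for p in PARAMETERS},
                    "mood_composite": float(composite[d_idx]),
                    "person_mean_mood": person_mood,
                    **{
                        f"completed_{t}": bool(completed[d_idx, t_idx])
                        for t_idx, t in enumerate(task_names)
                    },
                    **{
                        f"repetition_{t}": int(rep[d_idx, t_idx])
                        for t_idx, t in enumerate(task_names)
                    },
                }
            )
            for prompt in range(config.prompts_per_day):
                pos = float(np.clip(composite[d_idx] + rng.normal(0, config.prompt_noise_sd), 0, 100))
                neg = float(
                    np.clip(100.0 - composite[d_idx] + rng.normal(0, config.prompt_noise_sd), 0, 100)
                )
                rating_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "day": int(day),
                        "prompt_index": prompt + 1,
                        "positive": pos,
                        "negative": neg,
                    }
                )

        # --- trial-level choices ---------------------------------------------
        if include_choices:
            for d_idx, day in enumerate(days):
                for t_idx, task in enumerate(task_names):
                    if not completed[d_idx, t_idx]:
                        continue
                    trial_rng = substream(seed, "choices", sid, int(day), task)
                    design_seed = int(trial_rng.integers(2**31))
                    if task == "itc":
                        trials = tasks.generate_itc_trials(config.itc_convention, design_seed)
                        params = float(np.exp(day_params["log_kappa"][d_idx]))
                        gamma = config.gamma_itc
                    else:
                        condition = "gain" if task == "risk-gain" else "loss"
                        trials = tasks.generate_risk_trials(condition, design_seed)
                        if condition == "gain":
                            alpha = 1.0 + day_params["risk_tol_gain"][d_idx]
                            beta = -day_params["amb_tol_gain"][d_idx]
                        else:
                            alpha = 1.0 - day_params["risk_tol_loss"][d_idx]
                            beta = day_params["amb_tol_loss"][d_idx]
                        params = (alpha, beta)
                        gamma = config.gamma_risk
                    rows = _simulate_task_choices(trials, params, gamma, task, trial_rng)
                    frame = pd.DataFrame(rows)
                    frame.insert(0, "task", task)
                    frame.insert(0, "day", int(day))
                    frame.insert(0, "group", group)
                    frame.insert(0, "subject_id", sid)
                    choice_frames.append(frame)

    choice_cols = [
        "subject_id", "group", "day", "task", "trial_index", "guaranteed", "v", "p", "A",
        "v_immediate", "v_delayed", "d_immediate", "d_delayed", "choice",
    ]
    choices = (
        pd.concat(choice_frames, ignore_index=True)[choice_cols]
        if choice_frames
        else pd.DataFrame(columns=choice_cols)
    )
    ratings = pd.DataFrame(rating_rows)
    truth = pd.DataFrame(truth_rows)
    return choices, ratings, truth


def truth_icc(truth: pd.DataFrame, parameter: str) -> float:
    """ICC of a noiseless latent parameter series (ANOVA moment estimator).

    Generator self-check: verifies the configured between/within variance
    ratio is realized on the simulated grid before any estimation noise.
    """
    if parameter not in truth.columns:
        raise KeyError(parameter)
    return anova_icc(truth[parameter], truth["subject_id"])
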