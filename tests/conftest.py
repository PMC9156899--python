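import numpy as np
import pandas as pd
import pytest

from emaecon import cohort, tasks
from emaecon.models import prob_choose_delayed, prob_choose_lottery


def simulate_risk_choices(alpha, beta, gamma, seed, n_sets=1, condition="gain"):
    """Trial-level risk choices from known parameters (independent of the
    estimation code path: probabilities computed directly from the model)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        for tr in tasks.generate_risk_trials(condition, seed=seed + 1000 * s):
            eff = np.clip(tr.p - beta * tr.A / 2.0, 0.0, 1.0)
            eu_l = eff * np.sign(tr.v) * abs(tr.v) ** alpha
            eu_s = np.sign(tr.guaranteed) * abs(tr.guaranteed) ** alpha
            pr = prob_choose_lottery(eu_l, eu_s, gamma)
            rows.append(
                {
                    "subject_id": "s1",
                    "day": 1,
                    "v": tr.v,
                    "guaranteed": tr.guaranteed,
                    "p": tr.p,
                    "A": tr.A,
                    "choice": int(rng.random() < pr),
                }
            )
    return pd.DataFrame(rows)


def simulate_itc_choices(kappa, gamma, seed, n_sets=1, convention="immediate0"):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        for tr in tasks.generate_itc_trials(convention, seed=seed + 1000 * s):
            u_d = tr.v_delayed / (1.0 + kappa * tr.d_delayed)
            u_i = tr.v_immediate / (1.0 + kappa * tr.d_immediate)
            pr = prob_choose_delayed(u_d, u_i, gamma)
            rows.append(
                {
                    "subject_id": "s1",
                    "day": 1,
                    "v_immediate": tr.v_immediate,
                    "v_delayed": tr.v_delayed,
                    "d_immediate": tr.d_immediate,
                    "d_delayed": tr.d_delayed,
                    "choice": int(rng.random() < pr),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated study shared across tests (8 subjects, 12 days)."""
    cfg = cohort.CohortConfig(n_patients=4, n_controls=4, n_days=12)
    return cohort.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def truth_as_fits():
    """Latent truth table of a mid-sized cohort reshaped to the fits-table
    schema, so LME machinery can be exercised without running the MLE."""
    cfg = cohort.CohortConfig(n_patients=12, n_controls=12, n_days=20)
    _, ratings, truth = cohort.simulate_cohort(cfg, seed=5, include_choices=False)
    return truth_to_fits(truth), ratings, truth


def truth_to_fits(truth: pd.DataFrame) -> pd.DataFrame:
    """Reshape a truth table into the long fits schema (one row per completed
    subject-day-task, latent parameters standing in for estimates)."""
    frames = []
    for task, cols in (
        ("risk-gain", {"risk_tol": "risk_tol_gain", "amb_tol": "amb_tol_gain"}),
        ("risk-loss", {"risk_tol": "risk_tol_loss", "amb_tol": "amb_tol_loss"}),
        ("itc", {"log_kappa": "log_kappa"}),
    ):
        d = truth[truth[f"completed_{task}"]].copy()
        frame = d[["subject_id", "group", "day"]].copy()
        frame["task"] = task
        for out_col in ("risk_tol", "amb_tol", "log_kappa"):
            frame[out_col] = d[cols[out_col]].to_numpy() if out_col in cols else np.nan
        frame["converged"] = True
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
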