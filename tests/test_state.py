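"""Mood composites, repetition counting, and random-intercept LME inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from emaecon import state

from conftest import truth_to_fits
from emaecon import cohort


class TestMoodDays:
    @pytest.mark.parametrize(
        "prompts,expected",
        [
            ([(70, 20)], (70.0, 20.0, 75.0)),           # (70 + 80) / 2
            ([(50, 50)], (50.0, 50.0, 50.0)),           # neutral point
            ([(60, 40), (80, 20)], (70.0, 30.0, 70.0)), # prompts averaged first
        ],
    )
    def test_composite(self, prompts, expected):
        ratings = pd.DataFrame(
            [
                {"subject_id": "s1", "day": 1, "prompt_index": i + 1, "positive": p, "negative": n}
                for i, (p, n) in enumerate(prompts)
            ]
        )
        out = state.build_mood_days(ratings)
        assert (out.iloc[0]["positive"], out.iloc[0]["negative"], out.iloc[0]["composite"]) == expected

    def test_out_of_range_rejected(self):
        ratings = pd.DataFrame(
            [{"subject_id": "s1", "day": 1, "prompt_index": 1, "positive": 130, "negative": 0}]
        )
        with pytest.raises(ValueError, match="outside"):
            state.build_mood_days(ratings)


class TestRepetition:
    def test_running_count_skips_missing_days(self):
        fits = pd.DataFrame(
            {
                "subject_id": ["s1"] * 4,
                "task": ["itc"] * 4,
                "day": [1, 2, 5, 6],  # days 3-4 missed
                "log_kappa": [0.0] * 4,
                "risk_tol": np.nan,
                "amb_tol": np.nan,
                "converged": True,
                "group": "control",
            }
        )
        out = state.add_repetition(fits)
        assert list(out.sort_values("day")["repetition"]) == [1, 2, 3, 4]


def _simple_series(n_subjects=20, n_days=12, re_sd=0.8, noise_sd=0.5, slope=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        intercept = rng.normal(0, re_sd)
        group = "OUD" if i < n_subjects // 2 else "control"
        for d in range(1, n_days + 1):
            rows.append(
                {
                    "subject_id": f"s{i:02d}",
                    "group": group,
                    "day": d,
                    "task": "itc",
                    "log_kappa": intercept + slope * d + rng.normal(0, noise_sd),
                    "risk_tol": np.nan,
                    "amb_tol": np.nan,
                    "converged": True,
                }
            )
    return pd.DataFrame(rows)


class TestLmeMachinery:
    def test_ols_limit_without_subject_structure(self):
        """With zero random-intercept variance the GLS fixed effects collapse
        to ordinary least squares."""
        fits = _simple_series(re_sd=0.0, slope=-0.05, seed=1)
        res = state.fit_repetition_model(fits, "log_kappa")
        series = state.parameter_series(fits, "log_kappa")
        X = sm.add_constant(series["repetition"].to_numpy())
        ols = sm.OLS(series["value"].to_numpy(), X).fit()
        est = res.terms.set_index("term")["estimate"]
        assert est["Intercept"] == pytest.approx(ols.params[0], abs=5e-3)
        assert est["repetition"] == pytest.approx(ols.params[1], abs=5e-3)

    def test_satterthwaite_df_bounds_and_balanced_value(self):
        """df never exceeds n - p, and for a purely between-subject contrast
        on a balanced complete panel matches the classical n_subjects - 2."""
        fits = _simple_series(n_subjects=16, n_days=10, re_sd=1.0, noise_sd=0.5, seed=2)
        res = state.fit_group_model(fits, "log_kappa")
        n, p = res.n_observations, len(res.terms)
        assert (res.terms["df"] <= n - p + 1e-9).all()
        diag = res.term("diagnosis")
        assert diag["df_method"] == "satterthwaite"
        assert diag["df"] == pytest.approx(16 - 2, rel=0.01)

    def test_ci_consistent_with_estimate_and_df(self):
        from scipy import stats as sps

        fits = _simple_series(seed=3)
        res = state.fit_repetition_model(fits, "log_kappa")
        for _, row in res.terms.iterrows():
            crit = sps.t.ppf(0.975, row["df"])
            assert row["ci_low"] == pytest.approx(row["estimate"] - crit * row["se"], rel=1e-9)
            assert row["ci_high"] == pytest.approx(row["estimate"] + crit * row["se"], rel=1e-9)

    def test_diagnosis_coding_flip_negates_effect(self):
        fits = _simple_series(seed=4)
        fits.loc[fits["group"] == "OUD", "log_kappa"] += 1.5
        a = state.fit_group_model(fits, "log_kappa")
        b = state.fit_group_model(fits, "log_kappa", coding={"control": 1.0, "OUD": 0.0})
        assert a.term("diagnosis")["estimate"] == pytest.approx(
            -b.term("diagnosis")["estimate"], abs=1e-8
        )
        assert a.metadata["diagnosis_coding"] == {"control": 0.0, "OUD": 1.0}


class TestMoodModel:
    @staticmethod
    def _cohort_frames(seed=21, mood_effect=0.02):
        cfg = cohort.CohortConfig(n_patients=12, n_controls=12, n_days=20, mood_effect=mood_effect)
        _, ratings, truth = cohort.simulate_cohort(cfg, seed=seed, include_choices=False)
        return truth_to_fits(truth), state.build_mood_days(ratings)

    def test_centering_identity_and_shift_invariance(self):
        """mood_within + subject mean reconstructs the composite, and adding a
        constant to every rating leaves the within/between terms unchanged."""
        fits, mood = self._cohort_frames()
        res = state.fit_mood_model(fits, mood, "risk_tol_gain")
        shifted = mood.copy()
        shifted["composite"] = shifted["composite"] + 7.0
        res2 = state.fit_mood_model(fits, shifted, "risk_tol_gain")
        for term in ("mood_within", "mood_between", "diagnosis:mood_within"):
            assert res.term(term)["estimate"] == pytest.approx(res2.term(term)["estimate"], abs=1e-8)

    def test_within_person_mood_effect_recovered(self):
        fits, mood = self._cohort_frames(seed=22)
        res = state.fit_mood_model(fits, mood, "risk_tol_gain")
        row = res.term("mood_within")
        assert row["estimate"] > 0
        assert row["ci_low"] <= 0.02 <= row["ci_high"]

    def test_uncoupled_parameter_shows_no_mood_effect(self):
        fits, mood = self._cohort_frames(seed=23)
        res = state.fit_mood_model(fits, mood, "log_kappa")
        assert res.term("mood_within")["p"] > 0.01

    def test_repetition_drift_recovered(self):
        fits, _ = self._cohort_frames(seed=24)
        res = state.fit_repetition_model(fits, "log_kappa")
        row = res.term("repetition")
        assert row["ci_low"] <= -0.06 <= row["ci_high"]

    def test_unknown_group_rejected(self):
        fits, mood = self._cohort_frames()
        fits.loc[fits.index[:5], "group"] = "other"
        with pytest.raises(ValueError, match="coding"):
            state.fit_group_model(fits, "risk_tol_gain")


def test_results_long_table():
    fits = _simple_series(seed=5)
    res = [state.fit_repetition_model(fits, "log_kappa"), state.fit_group_model(fits, "log_kappa")]
    table = state.lme_results_to_frame(res)
    assert {"outcome", "model", "term", "estimate", "df", "p"} <= set(table.columns)
    assert set(table["model"]) == {"repetition", "group"}
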