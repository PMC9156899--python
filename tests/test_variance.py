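"""ICC estimation, week-level down-sampling, and day-wise correlations."""

import numpy as np
import pandas as pd
import pytest

from emaecon import variance


def _panel(n_subjects, n_days, between_sd, within_sd, seed, mean=0.0):
    rng = np.random.default_rng(seed)
    person = mean + rng.normal(0, between_sd, n_subjects)
    rows = [
        {"subject_id": f"s{i:03d}", "day": d + 1, "value": person[i] + rng.normal(0, within_sd)}
        for i in range(n_subjects)
        for d in range(n_days)
    ]
    return pd.DataFrame(rows)


class TestComputeIcc:
    def test_constant_per_subject_gives_one(self):
        df = _panel(6, 8, between_sd=1.0, within_sd=0.0, seed=0)
        vd = variance.compute_icc(df, "value")
        assert vd.icc == pytest.approx(1.0, abs=1e-6)

    def test_iid_series_gives_zero(self):
        df = _panel(20, 20, between_sd=0.0, within_sd=1.0, seed=1)
        vd = variance.compute_icc(df, "value")
        assert vd.icc == pytest.approx(0.0, abs=0.05)

    def test_equal_components_give_half(self):
        df = _panel(44, 28, between_sd=1.0, within_sd=1.0, seed=2)
        vd = variance.compute_icc(df, "value")
        assert vd.icc == pytest.approx(0.5, abs=0.03)
        assert vd.n_subjects == 44 and vd.n_observations == 44 * 28

    def test_agrees_with_anova_oracle_on_balanced_panel(self):
        """On a balanced complete panel the REML variance components coincide
        with the closed-form one-way ANOVA moment estimator."""
        df = _panel(15, 10, between_sd=0.8, within_sd=1.2, seed=3)
        vd = variance.compute_icc(df, "value")
        oracle = variance.anova_icc(df["value"], df["subject_id"])
        assert vd.icc == pytest.approx(oracle, abs=1e-6)

    def test_affine_invariance(self):
        df = _panel(12, 8, between_sd=1.0, within_sd=0.7, seed=4)
        a = variance.compute_icc(df, "value").icc
        df["value"] = 3.5 * df["value"] - 11.0
        b = variance.compute_icc(df, "value").icc
        assert a == pytest.approx(b, abs=1e-6)

    def test_too_few_subjects_rejected(self):
        df = _panel(1, 10, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            variance.compute_icc(df, "value")


class TestWeekMean:
    def test_full_subject_gets_four_weekly_means(self):
        df = _panel(1, 28, 0.0, 1.0, seed=5)
        out = variance.downsample_week_mean(df, value_cols=("value",))
        assert list(out["week"]) == [1, 2, 3, 4]
        manual = df.groupby((df["day"] - 1) // 7)["value"].mean().to_numpy()
        assert np.allclose(out["value"].to_numpy(), manual)

    def test_missing_weeks_are_censored(self):
        df = _panel(1, 28, 0.0, 1.0, seed=6)
        df = df[df["day"].between(8, 14)]  # only week 2
        out = variance.downsample_week_mean(df, value_cols=("value",))
        assert len(out) == 1 and out["week"].iloc[0] == 2

    def test_week_averaging_raises_icc_by_predicted_factor(self):
        """Averaging 7 independent days shrinks within-person variance ~7x,
        so ICC rises to b2 / (b2 + w2/7) for i.i.d. day noise.  The 4-point
        weekly ICC estimate is noisy, so the check averages replicates."""
        b, w = 1.0, 1.5
        week_iccs = []
        for seed in range(10):
            df = _panel(44, 28, b, w, seed=100 + seed)
            weekly = variance.downsample_week_mean(df, value_cols=("value",)).rename(
                columns={"week": "day"}
            )
            week_iccs.append(variance.compute_icc(weekly, "value").icc)
        day_icc = variance.compute_icc(_panel(44, 28, b, w, seed=100), "value").icc
        predicted = b**2 / (b**2 + w**2 / 7)
        assert np.mean(week_iccs) > day_icc
        assert np.mean(week_iccs) == pytest.approx(predicted, abs=0.05)


class TestRandomDays:
    def test_full_compliance_selection(self):
        df = _panel(3, 28, 1.0, 1.0, seed=8)
        out = variance.downsample_random_days(df, seed=1, value_cols=("value",))
        for _, sub in out.groupby("subject_id"):
            days = sub.sort_values("week")["day"].to_numpy()
            assert len(days) == 4
            assert (np.diff(days) >= 4).all()

    def test_seed_reproducibility(self):
        df = _panel(5, 28, 1.0, 1.0, seed=9)
        a = variance.downsample_random_days(df, seed=2, value_cols=("value",))
        b = variance.downsample_random_days(df, seed=2, value_cols=("value",))
        pd.testing.assert_frame_equal(a, b)

    def test_selection_covers_eligible_combinations(self):
        """With two candidate days per week, repeated seeded draws reach every
        combination that satisfies the >= 4-day spacing."""
        avail = [1, 7, 8, 14, 15, 21, 22, 28]
        df = _panel(1, 28, 0.0, 1.0, seed=10)
        df = df[df["day"].isin(avail)]
        week_days = [(1, 7), (8, 14), (15, 21), (22, 28)]
        import itertools

        eligible = {
            combo
            for combo in itertools.product(*week_days)
            if all(y - x >= 4 for x, y in zip(combo, combo[1:]))
        }
        seen = set()
        for seed in range(400):
            out = variance.downsample_random_days(df, seed=seed, value_cols=("value",))
            seen.add(tuple(out.sort_values("week")["day"]))
        assert seen == eligible

    def test_infeasible_week_skipped(self):
        df = _panel(1, 28, 0.0, 1.0, seed=11)
        df = df[df["day"].isin([7, 8, 21])]  # weeks 1, 2 only 1 day apart
        out = variance.downsample_random_days(df, seed=0, value_cols=("value",))
        days = out.sort_values("day")["day"].to_numpy()
        assert (np.diff(days) >= 4).all()
        assert len(days) < 3  # at least one week dropped

    def test_allpairs_rule(self):
        df = _panel(2, 28, 1.0, 1.0, seed=12)
        out = variance.downsample_random_days(df, seed=3, value_cols=("value",), rule="allpairs")
        for _, sub in out.groupby("subject_id"):
            days = np.sort(sub["day"].to_numpy())
            assert all(b - a >= 4 for i, a in enumerate(days) for b in days[i + 1:])


class TestCorrelations:
    @staticmethod
    def _fits(coupling, seed, n_subjects=30, n_days=10, stability=1.0):
        rng = np.random.default_rng(seed)
        person_a = rng.normal(0, stability, n_subjects)
        person_b = coupling * person_a + rng.normal(0, stability, n_subjects)
        rows = []
        for i in range(n_subjects):
            for d in range(1, n_days + 1):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "day": d,
                        "task": "risk-gain",
                        "risk_tol": person_a[i] + rng.normal(0, 0.5),
                        "amb_tol": person_b[i] + rng.normal(0, 0.5),
                        "log_kappa": np.nan,
                    }
                )
        return pd.DataFrame(rows)

    PARAMS = {
        "risk_tol_gain": ("risk-gain", "risk_tol"),
        "amb_tol_gain": ("risk-gain", "amb_tol"),
    }

    def test_self_same_day_is_one(self):
        fits = self._fits(0.0, seed=13)
        cm = variance.correlation_matrices(fits, self.PARAMS)
        diag = np.diag(cm.matrix.to_numpy())
        assert np.allclose(diag[np.isfinite(diag)], 1.0)

    def test_uncoupled_parameters_have_small_between_correlation(self):
        fits = self._fits(0.0, seed=14, n_subjects=60)
        cm = variance.correlation_matrices(fits, self.PARAMS)
        row = cm.summary.query("kind == 'between_parameter'").iloc[0]
        assert abs(row["mean_r"]) < 0.1

    def test_stable_parameters_have_higher_test_retest_than_cross(self):
        fits = self._fits(0.3, seed=15, stability=1.5)
        cm = variance.correlation_matrices(fits, self.PARAMS)
        retest = cm.summary.query("kind == 'test_retest'")["mean_r"].mean()
        cross = cm.summary.query("kind == 'between_parameter'")["mean_r"].mean()
        assert retest > cross
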