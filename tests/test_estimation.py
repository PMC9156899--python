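"""Bounded MLE behavior: oracle equivalence, recovery, boundary flags, BIC."""

import numpy as np
import pandas as pd
import pytest

from emaecon import estimation
from emaecon.models import KAPPA_BOUNDS

from conftest import simulate_itc_choices, simulate_risk_choices


class TestRiskFit:
    def test_never_worse_than_grid_oracle(self):
        for seed, (a, b, g) in enumerate([(0.8, 0.5, 5.0), (1.5, -1.0, 2.0), (0.5, 2.0, 10.0)]):
            df = simulate_risk_choices(a, b, g, seed=seed)
            fit = estimation.fit_risk_day(df, seed=seed)
            _, grid_nll = estimation.grid_oracle(df, "risk", resolution=(40, 40, 15))
            assert fit.neg_log_likelihood <= grid_nll + 1e-6

    def test_ev_maximizer_recovery(self):
        """A chooser taking the lottery iff its EV beats $0.50 looks
        risk/ambiguity-neutral (up to the deterministic-choice gamma limit)."""
        df = simulate_risk_choices(1.0, 0.0, 50.0, seed=3, n_sets=4)
        ev = np.clip(df["p"] - 0.0 * df["A"] / 2, 0, 1) * df["v"]
        df["choice"] = (ev > 0.50).astype(int)
        fit = estimation.fit_risk_day(df, seed=0)
        assert fit.params["alpha"] == pytest.approx(1.0, abs=0.25)
        assert abs(fit.params["beta"]) < 0.35

    def test_seed_reproducibility(self):
        df = simulate_risk_choices(0.9, 0.4, 4.0, seed=2)
        f1 = estimation.fit_risk_day(df, seed=7)
        f2 = estimation.fit_risk_day(df, seed=7)
        assert f1.params == f2.params and f1.neg_log_likelihood == f2.neg_log_likelihood

    def test_all_same_choice_flagged(self):
        df = simulate_risk_choices(0.9, 0.0, 4.0, seed=1)
        df["choice"] = 1
        fit = estimation.fit_risk_day(df, seed=0)
        assert not fit.converged

    def test_mixed_conditions_rejected(self):
        gain = simulate_risk_choices(1.0, 0.0, 3.0, seed=0)
        loss = simulate_risk_choices(1.0, 0.0, 3.0, seed=0, condition="loss")
        with pytest.raises(ValueError, match="mix"):
            estimation.fit_risk_day(pd.concat([gain, loss]), seed=0)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            estimation.fit_risk_day(pd.DataFrame(columns=["v", "guaranteed", "p", "A", "choice"]))

    def test_bic_definition(self):
        df = simulate_risk_choices(1.0, 0.0, 3.0, seed=4)
        fit = estimation.fit_risk_day(df, seed=0)
        assert fit.bic == pytest.approx(3 * np.log(fit.n_trials) + 2 * fit.neg_log_likelihood)


class TestItcFit:
    def test_never_worse_than_grid_oracle(self):
        for seed, (k, g) in enumerate([(0.05, 2.0), (0.005, 1.0), (0.5, 3.0)]):
            df = simulate_itc_choices(k, g, seed=seed)
            fit = estimation.fit_itc_day(df, seed=seed)
            _, grid_nll = estimation.grid_oracle(df, "itc", resolution=(40, 15))
            assert fit.neg_log_likelihood <= grid_nll + 1e-6

    def test_kappa_recovery_order_of_magnitude(self):
        df = simulate_itc_choices(0.05, 2.0, seed=9, n_sets=2)
        fit = estimation.fit_itc_day(df, seed=1)
        assert 0.025 <= fit.params["kappa"] <= 0.1

    def test_always_delayed_hits_lower_bound(self):
        df = simulate_itc_choices(0.05, 2.0, seed=1)
        df["choice"] = 1
        fit = estimation.fit_itc_day(df, seed=0)
        assert fit.params["kappa"] == pytest.approx(KAPPA_BOUNDS[0], rel=0.05)
        assert not fit.converged

    def test_bic_definition(self):
        df = simulate_itc_choices(0.05, 2.0, seed=2)
        fit = estimation.fit_itc_day(df, seed=0)
        assert fit.bic == pytest.approx(2 * np.log(fit.n_trials) + 2 * fit.neg_log_likelihood)


class TestConventionRemap:
    def test_remap_preserves_week_gap(self):
        df = simulate_itc_choices(0.05, 2.0, seed=0)
        r7 = estimation.remap_convention(df, "immediate7")
        assert set(r7["d_immediate"]) == {7}
        assert set(r7["d_delayed"]) == {14, 21, 28}
        assert ((r7["d_delayed"] - r7["d_immediate"]) == (df["d_delayed"] - df["d_immediate"])).all()

    def test_steep_discounter_identifies_immediate0(self):
        """For effective rates above 1/8 per day the immediate7 family has no
        equivalent parameterization, so immediate0 wins strictly."""
        frames = []
        for day in range(1, 5):
            d = simulate_itc_choices(0.4, 3.0, seed=20 + day, convention="immediate0")
            d["day"] = day
            frames.append(d)
        table, winner = estimation.compare_delay_conventions(pd.concat(frames), seed=0)
        assert winner == "immediate0"
        assert table["bic_immediate0"].sum() < table["bic_immediate7"].sum()
        assert {"bic_immediate0", "bic_immediate7"} <= set(table.columns)

    def test_conventions_equivalent_for_shallow_discounters(self):
        """With kappa' = kappa/(1+7 kappa) and gamma' = gamma (1+7 kappa) the
        two datings induce identical choice likelihoods, so for data from a
        shallow discounter the summed BICs agree to optimizer precision."""
        frames = []
        for day in range(1, 4):
            d = simulate_itc_choices(0.08, 2.0, seed=40 + day, convention="immediate7")
            d["day"] = day
            frames.append(d)
        table, _ = estimation.compare_delay_conventions(pd.concat(frames), seed=0)
        gap = abs(table["bic_immediate0"].sum() - table["bic_immediate7"].sum())
        assert gap < 0.2

    def test_tie_breaks_toward_immediate0(self, monkeypatch):
        def fake_fit(records, convention="immediate0", seed=0, n_starts=10):
            return estimation.DayFit(
                subject_id="s1", day=1, task="itc", params={}, reported={},
                neg_log_likelihood=10.0, bic=25.0, n_trials=45, converged=True, n_restarts_used=1,
            )

        monkeypatch.setattr(estimation, "fit_itc_day", fake_fit)
        df = simulate_itc_choices(0.05, 2.0, seed=0)
        _, winner = estimation.compare_delay_conventions(df, seed=0)
        assert winner == "immediate0"


class TestFitAll:
    def test_short_days_excluded_and_schema(self):
        a = simulate_risk_choices(1.0, 0.0, 3.0, seed=0)
        a["task"] = "risk-gain"
        b = simulate_itc_choices(0.05, 2.0, seed=0)
        b["task"] = "itc"
        short = a.head(5).copy()
        short["day"] = 2
        choices = pd.concat([a, b, short], ignore_index=True)
        fits = estimation.fit_all(choices, seed=0, min_trials=20)
        assert set(fits["task"]) == {"risk-gain", "itc"}
        assert len(fits) == 2  # the 5-trial day is dropped
        assert {"risk_tol", "amb_tol", "log_kappa", "bic", "converged"} <= set(fits.columns)
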