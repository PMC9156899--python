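"""Decompose day-level parameter variation into between- vs within-person
components, and see how week-level sampling inflates apparent stability.

ICC = between-person variance / total variance from an intercept-only
random-intercept model; 1 - ICC is day-to-day (within-person) variability.
"""

from emaecon import cohort, variance

cfg = cohort.CohortConfig(repetition_drift={}, mood_effect=0.0, group_logkappa_offset=0.0)
_, _, truth = cohort.simulate_cohort(cfg.with_icc_target("log_kappa", 0.67), seed=9,
                                     include_choices=False)

day = variance.compute_icc(truth, "log_kappa")
print(f"day-level ICC[log kappa] = {day.icc:.2f} "
      f"(between {day.sigma2_between:.2f}, within {day.sigma2_within:.2f}; target 0.67)")

weekly = variance.downsample_week_mean(truth, value_cols=("log_kappa",)).rename(columns={"week": "day"})
wk = variance.compute_icc(weekly, "log_kappa")
print(f"week-mean ICC = {wk.icc:.2f} (averaging 7 days shrinks within-person noise ~7x)")

random_days = variance.downsample_random_days(truth, seed=1, value_cols=("log_kappa",))
rd = variance.compute_icc(random_days, "log_kappa")
print(f"random-day ICC = {rd.icc:.2f} (one day per week, >= 4 days apart, like sparse lab visits)")
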