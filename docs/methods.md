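# Methods

This note documents the models, the synthetic world, and the numerical
choices behind `emaecon`, in the spirit of a statistical software methods
appendix.  It states no empirical result that the test suite does not
itself compute.

## Choice models

**Risk/ambiguity.**  Each trial offers a guaranteed ±$0.50 against a
lottery paying $0 or *v* (|v| ∈ {0.60, 0.80, 1.20, 1.80, 2.60, 3.90, 4.40,
6.60}).  On known-risk trials the winning probability is p ∈ {.25, .50,
.75} with occlusion A = 0; on ambiguity trials a central occluder hides a
fraction A ∈ {.24, .50, .74} of the probability scale, so the nominal
(midpoint) probability stored with the trial is 0.50.  Expected utility is

    EU = clamp(p − β·A/2, 0, 1) · sign(v)·|v|^α .

Numerical choices:

* *Probability clamp.*  β ∈ [−5, 5] can push p − βA/2 outside [0, 1]; the
  effective probability is clamped before use.  This creates plateaus and
  kinks in the likelihood (see Estimation).
* *Loss domain.*  v^α is undefined for v < 0 with non-integer α, so
  utility is sign-preserving: sign(v)|v|^α.  α = 1 remains the
  expected-value maximizer in both domains, and mirrored gain/loss trials
  have exactly negated utilities (property-tested).
* *Guaranteed option.*  Modeled as a degenerate lottery (p = 1, A = 0), so
  its utility ±0.50^α lives in the same space as the lottery's.  The same
  power transform is applied to the guaranteed loss (symmetric treatment).

**Discounting.**  U = v/(1 + κd), linear utility, κ in [0.0001, 1] per
day.  The "this week" (immediate) option can be dated at 0 days with
delayed options at 7/14/21 days (`immediate0`) or at 7 days with 14/21/28
(`immediate7`); delays are re-derived from the week gap, so the same
recorded choices can be fit under either dating.

**54-trial composition.**  The printed level sets give 8 values × 3
probabilities + 8 values × 3 ambiguity levels = 48 distinct offers.  To
reach the administered 54 (27 known-risk + 27 ambiguity) the generator
repeats one designated value level — by default the near-guaranteed $0.60
anchor — once per probability and per ambiguity level.  The repeated value
is configurable; only presentation order depends on the seed.

**Bonus realization.**  One completed task is drawn uniformly, then one of
its trials; gains pay the realized outcome, losses are subtracted from the
$6.60 endowment, intertemporal choices pay the chosen amount.  Ambiguous
lotteries resolve at the nominal midpoint probability (the resolution rule
is not otherwise determined; it is configurable in principle and payouts
are provably within [0, 6.60]).

## Estimation

Each subject-day-task is fit independently by maximizing the Bernoulli
likelihood over the bounded box (α, β, γ) or (κ, γ), with γ ∈ [0.001, 50]
(no published bounds; this prevents flat and step-function degeneracies).

* *Reparameterization.*  Optimization runs unconstrained: logit-scaled
  within the box for α, β, and (on the log scale) κ and γ.
* *Multi-start.*  10 scrambled-Sobol starts refined with L-BFGS-B, plus
  the top-5 (risk) / top-3 (ITC) points of a coarse exhaustive lattice
  (20×20×10 / 25×10), each refined with L-BFGS-B and Nelder-Mead; the best
  run gets a final Nelder-Mead polish.  The Nelder-Mead steps matter: the
  probability clamp makes the surface only piecewise smooth and pure
  gradient refinement stalls on a few percent of random instances.  Ties
  go to the first-found optimum; everything is deterministic given the
  seed.
* *Oracle.*  A 50×50×20 (risk) / 50×20 (ITC) exhaustive grid is retained
  as an independent upper bound: tests require the optimizer's NLL to be
  at or below the grid optimum within 1e-6 on random instances.
* *Degenerate days.*  All-same-choice days (and fits landing at a box
  boundary, e.g. κ = 0.0001 for an always-delayed chooser) are returned
  with `converged=False` and excluded from downstream decompositions by
  default — boundary estimates distort variance components.
* *Short days.*  Administrations with fewer than 20 trials are excluded
  with a logged warning.  Missing days are censored, never imputed.
* *BIC.*  k·ln(n_trials) + 2·NLL with k = 3 (risk) or 2 (ITC), per
  subject-day-model.

**Delay-convention comparison — a structural caveat.**  On this trial grid
the `immediate7` model is an exact reparameterization of the `immediate0`
model: substituting κ′ = κ/(1+7κ) and γ′ = γ(1+7κ) makes the likelihoods
identical, and κ′ ≤ 1/8 for every κ in the fit box.  Consequently (a) for
data from shallow discounters the two maximized likelihoods tie and the
comparison is decided by the documented tie rule (ties → `immediate0`),
and (b) only steep discounting — an effective rate above 1/8 per day,
which has no `immediate7` equivalent — can make `immediate0` win
*strictly*.  The symmetric identification of `immediate7`-generated data
is therefore impossible in principle; the test suite documents this with a
deliberately failing check rather than hiding it.

## Synthetic cohort

The generator emulates a 28-day study of 23 OUD patients and 21 controls
with up to three task prompts per day.  Its defaults are the stated study
world: group task-compliance means 0.5414 / 0.8084 (independent Bernoulli
per task-prompt), a +2.17 patient offset in mean log κ, a 0.02-per-point
within-person mood effect on gain risk tolerance, and repetition drifts of
−0.08 (risk tolerance in losses), −0.06 (ambiguity tolerance in losses)
and −0.06 (log κ) per completed administration.

Day-level latent parameters on the reported scale are

    value(s, d) = person mean(s) + drift·(repetition − 1)
                  + mood coupling (gain risk tolerance only) + day noise,

clipped to the support implied by the fit bounds.  Choices are then
simulated on the exact trial sets through the choice models and thinned by
compliance.  Design choices that were genuinely open, decided once:

* *Population placement.*  Reported-scale means (0, −0.1, −0.4, −0.2) for
  risk/ambiguity tolerances (a mildly risk- and ambiguity-averse sample)
  and −5.5 for control log κ (κ ≈ 0.004/day; patients ≈ 0.036/day).
  Within-person SDs 0.30/0.30/0.45/0.45/1.0; between-person SDs set as
  within·√(ICC/(1−ICC)) for target ICCs 0.43/0.40/0.53/0.53/0.67.
  `CohortConfig.with_icc_target` re-derives the between-SD for any target.
* *Bound handling.*  Day noise is Gaussian hard-clipped at the support
  rather than truncated-normal resampled: full truncation compresses the
  conditional mean for every draw whose bound lies within ~2 SD,
  attenuating the generative mood coupling by ~10%, while clipping only
  moves the rare draws that hit a bound (~1–2%).  Person means do use
  truncated normals; the realized patient−control log κ offset is thereby
  ≈ 2.11 rather than the nominal 2.17 (well inside CI widths).
* *Mood.*  A 0–100 composite: person mean ~ N(60, 12²) truncated to
  [15, 95], AR(1) deviations with φ = 0.5 and innovation SD 10
  (stationary SD ≈ 11.5, day-level ICC ≈ 0.52).  Positive and negative
  prompt ratings are generated anticorrelated from the shared composite
  (negative = 100 − composite) with prompt noise SD 2, three prompts per
  day.  Coupling acts through the composite's within-person deviation; the
  per-subject centering discrepancy is absorbed by the random intercept,
  so the analysis-side slope is unbiased up to measurement attenuation
  (~1%).
* *Patient amplification.*  The mood coupling is a common effect by
  default; `mood_effect_patient_extra` adds a group-specific increment for
  studying interactions.
* *Repetition on missed days.*  The latent drift on a missed day uses the
  count the day would have carried if completed; only completed days reach
  the analysis, where the running count matches the analysis-side
  definition exactly.

**What a green test does and does not establish.**  The generator's
day-noise is i.i.d. given the structure above — real data have serially
correlated estimation error, scanner/context effects, and compliance that
is not missing-at-random.  Fitted-parameter ICCs sit *below* the latent
targets because day-level MLE noise counts as within-person variance; the
ICC-recovery checks therefore run on the latent truth series, and the
end-to-end pipeline reports fitted-parameter ICCs without claiming they
equal the latent targets.

## Variance decomposition

ICC from an intercept-only REML random-intercept fit (statsmodels MixedLM);
singular fits return ICC 0 with a flag.  A closed-form one-way ANOVA
moment estimator (negative between-variance truncated at 0, unbalanced
correction via the average-group-size k₀) is kept as an independent
cross-check and agrees with REML on balanced complete panels.

Week-level down-sampling: (a) mean of available days within weeks 1–7,
8–14, 15–21, 22–28; (b) one random available day per week with
consecutively selected days ≥ 4 days apart, drawn by seeded rejection
sampling (an all-pairs reading of the spacing rule is available behind
`rule="allpairs"`; the consecutive reading is the default because it
matches sparse lab-style scheduling).  A week with no eligible day is
skipped for that subject.

Day-wise correlation structure: between-parameter correlations are
computed across subjects day by day and summarized (mean/SD over days);
within-parameter (test–retest) correlations across all day pairs.
Pairwise-complete observations, cells with < 3 common subjects dropped.

## State models

Outcome series use converged fits only.  Three nested random-intercept
models per parameter (repetition; + diagnosis; + mood within/between and
diagnosis interactions).  Diagnosis is coded control = 0, patient = 1 and
recorded in the result metadata — the sign of a group effect is pure
coding convention, so results report magnitude plus coding rather than
matching any particular sign convention.

Satterthwaite degrees of freedom are computed from first principles for
the random-intercept structure: df = 2f²/(gᵀA⁻¹g) with f = cᵀVar(β̂)c, g
its gradient in (τ², σ²) by central differences, and A the observed REML
information (finite-difference Hessian of the closed-form restricted
log-likelihood, Woodbury per cluster).  Near the τ² = 0 boundary, or if
the information matrix is not invertible, the residual df n − p is used
and labeled `df_method="residual"`.  df is clamped to [1, n − p]; on
balanced panels the between-subject contrast df reproduces the classical
n_subjects − 2 within 1%.

## Reproducibility and scaling

All randomness flows from one master seed through named substreams
(design, simulation, fitting restarts, down-sampling), so every table is
byte-reproducible.  Calibration-style checks (CI coverage, type-I rates,
ICC recovery) run at the full 44 × 28 design but with replicate counts
scaled to a desktop time budget (e.g. 100 replicate studies for the
state-model calibration, 20 for ICC recovery, 60 per cell for
simulate-and-refit recovery); the acceptance pipeline script runs a 12 × 8
cohort for the same reason.

## Known limitations

* Per-day independent MLE (as specified) wastes no information across
  days but is noisy at 45–54 trials; hierarchical shrinkage is out of
  scope.
* The Satterthwaite implementation covers random-intercept models only
  (the only structure used here).
* The delay-convention BIC comparison is one-sided by construction (see
  above).
* The generator does not model within-day timing, dropout ramps (off by
  default but configurable), or non-random missingness.
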