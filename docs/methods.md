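# Methods

This note documents the models implemented in `circstrain`, the choices
made where the methodology was genuinely open, and what the synthetic
cohort does and does not emulate.

## Actimetry preprocessing

Recordings are rebinned to 10-min epochs (activity summed, light averaged;
a target bin is missing when more than half its source epochs are).
Non-wear is any maximal run of at least 10 consecutive zero-activity
epochs *at the analysis epoch length* (i.e. ≥ 100 min at 10-min epochs);
the run is masked in **both** channels, since lux from a pocketed device is
as invalid as its counts. Whether the zero-run rule should be applied
before or after rebinning is ambiguous in the actigraphy literature; here
it is applied after, and the threshold is a config knob
(`nonwear_min_run`).

The analysis window is the *earliest* run of 7 complete calendar days
(boundaries at local midnight, no daylight-saving handling — wall-clock
time throughout) in which every day has at most 4 h of missing data; the
4-h bound is inclusive. "Earliest" is a determinism choice: re-running a
cohort always selects the same days.

Two device dialects are supported (ActTrust: `DATE/TIME`/`PIM`/`LIGHT`;
Actiwatch-2: `timestamp`/`activity`/`white_light`). Cross-brand
comparability is restored by linear rescaling of each non-reference
channel so its pooled wear-epoch mean and SD match the Actiwatch-2
reference pool. Mean/SD matching is the simplest invertible correction for
a gain-like distortion; since IS, IV and RA are invariant under positive
affine transforms, the normalization affects only level-dependent outputs
(M10, L5, mesor, amplitude, profiles). Negative rescaled values are
clipped to zero and counted.

## Rhythm metrics

All NPCRA metrics are computed at the 10-min analysis resolution by
default (`p` = 144 bins/day); an hourly option exists for comparability
with the classical hourly definitions, which yield systematically
different absolute values (IV especially is resolution-dependent).

- `IS = [N·Σ_h (x̄_h − x̄)²] / [p·Σ_i (x_i − x̄)²]`, with `x̄_h` the
  across-day mean of within-day bin `h` and `N` the number of non-missing
  epochs. A signal repeating identically every 24 h attains IS = 1 by
  algebra; iid noise over `d` days gives IS ≈ 1/d. With missing data the
  estimate can exceed 1 by imbalance; the tests flag that case.
- `IV = [N·Σ (x_i − x_{i−1})²] / [(N−1)·Σ (x_i − x̄)²]`; successive
  differences are taken only across consecutive non-missing pairs, and `N`
  counts those pairs plus one. Anchors: ≈ 2 for Gaussian white noise (the
  expected value is 2·N/(N−1) up to O(1/N)), and
  `2(1 − cos(ωΔ)) ≈ (ωΔ)²` for a sampled sinusoid (≈ 0.0019 at 10-min
  sampling, i.e. 0.0 to one decimal).
- Both IS and IV refuse to run below 80% epoch coverage (configurable);
  a 7-day window passing the 4 h/day QC rule always satisfies this.
- M10/L5 are exhaustive scans over all circular 10-h / 5-h windows of the
  **mean** daily profile (never the median profile), wrapping across
  midnight; ties resolve to the earliest onset clock time. Undefined
  profile bins are imputed with the profile mean before scanning.
- The cosinor is the linear cos/sin least-squares fit over wear epochs;
  the acrophase is reported as the clock hour of the fitted maximum rather
  than a negative phase angle, matching how peak times are discussed
  clinically.

## Sleep variables and BMI

Sleep midpoints, durations and social jetlag are circular on the 24-h
clock, so shifting every reported time by a constant changes nothing. SJL
is stored as the absolute shorter-arc difference |MSF − MSW|: the sign
convention differs between sources, and the regression models only use the
dichotomized form (> 1 h), which a Wald linearity check also motivates
(see below). MSF is the plain free-day midpoint; the sleep-debt-corrected
MSFsc is available behind a flag but is not the default. BMI uses the WHO
half-open intervals ([18.5, 25) normal, [25, 30) overweight, ≥ 30 obese);
underweight subjects, night-shift workers (past 6 months) and alarm users
on free days are excluded, with reason codes kept so the subject
accounting always balances.

## Statistics

Kruskal–Wallis H is tie-corrected; the p-value uses the χ²(k−1)
approximation except at very small total n (≤ 8), where the exact
permutation null is enumerated — the χ² approximation misstates mid-range
p by up to ~0.1 there, which matters for the oracle tests. Dunn's pairwise
z-tests use pooled mid-ranks with the same tie correction; the Sidak
adjustment `1 − (1 − p)^m` is applied within each variable's family of
`m = k(k−1)/2` comparisons, not across variables.

Effect sizes are ε² = H(n+1)/(n²−1) and η² = (H−k+1)/(n−k), the latter
floored at 0 (it is negative for small H). CIs are seeded percentile
bootstraps resampling subjects within groups (default B = 2000).

The prevalence-ratio model is the "modified Poisson": a Poisson GLM with
log link fitted by IRLS on the binary overweight/obese outcome, with the
HC0 sandwich covariance (bread = inverse Fisher information, meat = outer
product of per-subject score residuals). It is implemented natively —
rather than delegated — because it is the analysis' headline estimator and
must be testable against closed forms: on a saturated two-group design the
PR equals the ratio of stratum proportions exactly and the robust SE has
the binomial closed form `√((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀))`; statsmodels'
GLM with HC0 serves as an independent cross-check in the tests. Diverging
coefficients (|β| > 25) are reported as suspected separation; the pipeline
drops indicator terms whose stratum has all or no events (logged) and, for
degenerate small cohorts, falls back to the model without categorical
dummies rather than emitting meaningless infinite PRs.

VIF uses the usual `1/(1 − R²_j)` auxiliary regressions with a > 5
severity flag. The log-linearity check for a continuous term adds
quartile-bin indicators on top of the linear term and Wald-tests their
joint significance under the HC0 covariance: a significant deviation
recommends categorization (the route by which SJL ends up modeled as
> 1 h).

Two named models mirror the analysis design: a questionnaire model
(age, sex, urbanization with "no electricity" as default reference —
configurable, since reference-level conventions vary — and SJL > 1 h) and
an actimetry model (age, sex, light IV, activity IV). Activity and light
IV enter the actimetry model on their raw scale; because measured IV spans
a narrow range, per-unit PRs can be numerically large with wide CIs — this
is a scale property, not instability.

## Synthetic cohort

The generator emulates: 10-min-epoch multi-day activity/light recordings
built from a two-state (rest/active) daily schedule; within-day
fragmentation as a Markov bout process (entry probability
`frag_switch_prob` per epoch, fixed exit rate 0.3/epoch, so misplaced
bouts average ~30 min) — IV is monotonically increasing in the entry
probability; day-level phase jitter (SD `phase_jitter_sd_h`) — IS is
monotonically decreasing in it; multiplicative lognormal activity noise
(counts are non-negative and right-skewed); state-coupled lognormal light
with occasional brief light-at-night events; inserted exact-zero non-wear
runs; and a pure multiplicative device gain (ActTrust vs Actiwatch-2).
Special modes provide the calibration anchors: a pure 24-h cosine and an
iid-Gaussian white-noise mode (offset to non-negative; the variance ratio
behind IV is offset-invariant).

The outcome model is log-linear:
`P(overweight/obese) = baseline_prev · PR_IV^z · PR_urban^urban · PR_female^female`,
clipped to [0, 1] (clipping above 5% of subjects is logged). Defaults,
chosen once as study conditions: urbanization mix 11.8/5.8/33.6/40.2/8.6%
(no electricity / <5 y / >20 y / ≥30 y electricity / urban), 60% female,
designed PRs 1.5 per SD of the IV target, 2.0 for urban, 1.5 for female,
baseline prevalence 0.10 (keeping the clipping rate far below 1% given the
PR products). BMI pairs are reverse-engineered from the drawn category
(height ~ N(1.65 m, 0.08 m), BMI uniform within the category interval)
because only the category enters the analysis. Each subject's randomness
derives from `cohort_seed + subject_index`, so subjects are independently
reproducible.

Parameter-recovery simulations regress on the *designed* standardized IV
covariate from `truth.csv`. Regressing on the measured IV instead is
attenuated by measurement error — a property of the data-generating
process, not of the estimator — and the recovery checks are about the
estimator. The recovery suite (200 replicates of n = 2000,
covariates-only cohorts) requires the aggregated PR estimates within 10%
of truth and per-parameter 95%-CI coverage between 93 and 97%.

What the generator does **not** emulate: physiological sleep architecture,
seasonal photoperiod, weekday/weekend activity structure, age-dependent
rhythm change, or any correlation between urbanization and rhythm
parameters beyond the outcome model. Passing tests therefore demonstrate
correctness of the estimators and pipeline plumbing under known truth, not
that real cohorts satisfy the model's assumptions.

## Problem sizes and numerical conventions

The shipped analysis simulates 200 subjects (8 recorded days each,
analyzed 7); calibration uses 500 white-noise replicates of 1008 epochs;
recovery uses 200 × n = 2000 covariates-only cohorts; null calibration of
the KW test uses 2000 replicates of 3 × 30. IRLS converges at max |Δβ| <
1e-10 (quadratic near the optimum, so the closed-form checks hold to
1e-8 relative); bootstrap and simulation seeds are fixed in configs and
recorded in outputs; all window/tie ambiguities resolve to the earliest
clock time.

## Known limitations

- Brand normalization defaults to global mean/SD matching; the
  quantile-mapping mode corrects distribution shape too but discards each
  subject's absolute level relative to peers on the same device.
  Level-dependent metrics retain residual brand effects if device pools
  differ in shape under the default mode.
- The exact-p Kruskal–Wallis path enumerates multiset assignments and is
  only intended for n ≤ ~10.
- The Wald linearity check bins at quartiles; terms with fewer than three
  distinct values are skipped with a warning.
- Light-at-night events are brief and rare by default; cohorts designed to
  study LAN effects should raise `lan_prob` explicitly.
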