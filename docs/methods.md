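# Methods

## Scope

`telecopd` benchmarks next-day prediction of two COPD outcomes —
hospital admission and oral-corticosteroid initiation — from daily
telemonitoring data, comparing five symptom-counting exacerbation
definitions against feature-based classifiers under patient-grouped
nested cross-validation. Because telemonitoring trial datasets of this
kind are held in clinical safe havens, all analyses run on simulated
cohorts whose generative mechanism (and therefore the Bayes-optimal
risk score) is known exactly.

## The synthetic cohort

**Latent process.** Each patient carries a first-order, three-state
Markov chain — *stable → prodrome → exacerbation → stable* — advanced
daily. Defaults: P(stable→prodrome) = 0.02, P(prodrome→exacerbation)
= 0.25, P(exacerbation→stable) = 0.30, giving mean dwell times of
~50 / 4 / 3.3 days and an exacerbation every couple of months, in the
range reported for frequent exacerbators. The prodrome exists so that a
learnable early-warning signal precedes the florid phase: its symptom
probabilities are intermediate and its physiological shifts small
(+4 bpm pulse, −1% SpO₂, vs +12 bpm / −3.5% in exacerbation). An
admission resets the chain to stable.

**Observables.** Eight symptoms are Bernoulli draws per day from
state-specific probabilities (stable ≈ 0.03–0.14 per symptom, prodrome
≈ 0.10–0.40, exacerbation ≈ 0.40–0.80). Pulse and SpO₂ are
patient-specific baselines (N(78, 8²) bpm; N(93, 2²) %) plus the state
shift plus daily noise, clipped to physiological ranges. Antibiotic and
corticosteroid use are course processes: a course starts with logistic
probability driven by the previous day's total symptom count and
continues each day with probability 0.85 (steroids) / 0.80
(antibiotics).

**Events.** The admission hazard on day *t* is logistic in the
*previous* day's state and physiology
(`logit p = −9.6 + 2.45·state + 0.15·(SpO₂ drop) + 0.03·(pulse rise)`),
on the view that an emergency admission follows the deterioration the
patient last reported. This choice also makes the recorded event
probability a function of day-*t* information only, so the oracle score
for an episode ending at *t* uses nothing from the future. Default rates
come out at ~1.3 admissions per 1000 patient-days (≈ 60 per cohort-year)
and ~1–2 corticosteroid starts per 100 eligible patient-days (several
hundred per cohort) — the two orders of magnitude the benchmark needs to
be about.

**Missingness.** Whole days go unreported with a patient-specific
probability drawn from Beta(mean 0.25, concentration 12); individual
fields additionally drop out at 0.02. Both probabilities are multiplied
by 3 on the 3 days before each admission (capped at 1): patients who are
becoming very unwell stop reporting. This informative missingness is the
mechanism behind the benchmark's central contrast — in the complete-data
scenario most admission episodes are excluded (no usable symptoms), while
in the imputed scenario they are retained with carried-forward values
that, because exacerbations are short (~3 days) and admissions follow
quickly, mostly predate the deterioration. Counting rules therefore
collapse towards chance under imputation while models that can read
trends, physiology and the imputation indicators themselves do not.
The admission flag and weather are never masked.

**Weather.** A single shared daily series: sinusoidal seasonal mean
temperature (annual mean 9 °C, amplitude 7 °C, coldest mid-January,
study start in autumn) plus an AR(1) anomaly (φ = 0.7, marginal SD
2.5 °C) so cold snaps persist for days; the three conventional cold
indicators (mean < 2 °C, max < 4 °C, max < 7 °C over 48 h) and a 0–3
alert level derived from the 7-day smoothed temperature. By default
weather is independent of any individual's risk — so weather-only models
sit at chance — and `weather_coupled_config()` (coupling 0.25) adds
`coupling · max(0, (5 − T)/5)` to every symptom probability for the
population-level analysis.

**Seeding.** One root seed feeds `numpy.random.SeedSequence`; each
consumer (baseline, weather, latent, symptoms, physiology, events,
missingness, folds, models, bootstrap) spawns from a fixed index, so any
module can be regenerated in isolation and identical configurations are
byte-identical.

**What the simulator is not.** It does not model hospital stays
(reporting continues through admissions), antibiotic feedback on the
latent state, spirometry, covariate shift between patients, or any
fitted resemblance to a specific trial population: its parameters are
plausible, documented choices, not estimates. Passing tests on these
cohorts demonstrates that the pipeline recovers planted signal under
realistic structure — not that the same margins would be observed
clinically.

## Episodes and scenarios

An episode is a W-day window (default W = 7) of one patient's daily
variables ending at day *t*, labelled by the outcome at *t+1*. Calendar
gaps are materialised as all-missing rows first, so "consecutive days"
is literal. In the *complete* scenario an episode survives only if every
required variable was observed on every window day; in the *imputed*
scenario, missing values are first forward-filled per patient for up to
15 days (only from the past), an indicator matrix marks the filled
entries, and episodes still missing a required value or their outcome
are dropped. For the corticosteroid outcome only episodes with no
reported steroid use on day *t* are kept, the label being use on day
*t+1* (a course onset). Patients with more than 95% of maskable fields
missing (strictly greater, over all maskable fields) are excluded up
front. Rule predictors are evaluated on episode sets cut to each rule's
own context window (1 day for definitions 1–2, 3 for 3–4, 1+lookahead
for 5), which is why their sample sizes differ by definition exactly as
a per-definition exclusion of unevaluable days implies.

## Features

A declarative catalogue maps each feature to (variable, transform,
day-parameter). Transform families: current value, lag-k, rolling
mean/min/max/SD/count/any, least-squares trend slope, days-since-last
medication use (saturating at W), deltas, and imputed-fraction features
computed from the indicator matrix. With the default W = 7 the
telemonitoring-plus-indicators catalogue contains **exactly 153 named
features** (80 symptom, 14 score/count, 26 physiology, 10 medication, 13
imputation-indicator, 10 baseline-covariate); the manifest is a data
frame (`FeatureCatalogue.to_frame()`), so the count is auditable.
Baseline covariates are median (continuous) / mode (categorical) imputed
and treated as stationary. Every transform reads days ≤ *t* only;
translation of the day axis leaves all features unchanged.
Standardisation is a model-side transform fitted on training folds, not
part of extraction.

## Models

Three families behind one contract. The *adaptive elastic net* is
logistic regression (saga solver) where a univariate point-biserial
association filter, computed on the training fold, rescales each
standardised feature so weak features carry proportionally heavier
penalty — a reconstruction of adaptive penalty weighting via feature
scaling. The *kernel max-margin* family is an RBF SVM scored by signed
margin. The *boosted ensemble* is histogram gradient boosting; its
default grid favours shallow, heavily damped learners (7–15 leaves,
learning rate 0.05–0.1, L2 1–10, optional 40% feature subsampling,
`min_samples_leaf` 100 capped at n/5) because the episode data contain
tens of events against tens of thousands of episodes, where deep trees
memorise noise. Class imbalance is handled by inverse-prevalence
instance weights (on by default). Hyperparameters are chosen by merged
inner-validation AUC, grid or seeded random search; ties go to the
earlier candidate. A recurrent-network family is an acknowledged
plug-in slot, not implemented.

## Evaluation

All folds are partitions of *patients*, assigned greedily (heaviest
episode count to the currently lightest fold, with jittered ordering so
repeated runs differ) to balance episode counts. Inner folds are drawn
only from the outer-training patients; an audit routine walks every
(run, outer, inner) triple and fails on any shared patient. The
aggregated AUC merges test-fold predictions within a run (Mann–Whitney
with ties = ½) and averages over runs. Because each outer fold's model
carries its own score calibration, test-fold scores are converted to
within-fold fractional ranks before merging (the pooled-rank estimator):
only within-fold comparisons are meaningful, and without this step the
merged ROC — and any operating point read from it — is distorted by
scale differences between fold models. Precomputed predictors with one
global scale (rule predictors, the oracle) are pooled as-is. Confidence intervals on the
pooled predictions: DeLong structural-components normal interval; a
Chebyshev interval `± √(var/α)` on the same variance (distribution-free,
always at least as wide); and a patient-level cluster bootstrap
(percentile, default 1000 replicates) since episodes within a patient
are dependent. The reported *consensus* interval is the hull (min lower,
max upper) of the three — a deliberately conservative pooling; all three
member intervals are also reported so any alternative consensus can be
recomputed. With fewer than two events the DeLong variance is undefined
and the code falls back to the bootstrap with a warning. Operating
points report the smallest FPR reaching a target TPR, both as the
empirical step value and linearly interpolated along the ROC polyline
(the reading appropriate for binary rule predictors).

For the population-level analysis the target is the 14-day block mean
over patients of (daily weighted score − patient baseline), the baseline
being each patient's median score over their first 28 observed days.
Predictor A is the previous block's target; predictor B a linear
regression on block-averaged weather covariates fitted on training
blocks only; both are scored by Spearman and Kendall correlation on
held-out blocks (3-fold over blocks, seeded), pooled across folds via
cross-fitted predictions.

## Numerical and design choices

* Rule outputs are ternary (onset / no onset / missing); a day whose
  required context is missing yields missing, but days whose context
  falls off the series ends yield *no onset*. Definition 5's single-day
  branch short-circuits so a day satisfying both branches is flagged
  once, and its last-day two-day branch cannot fire.
* Symptom counts are all-or-nothing: any missing flag invalidates the
  day (upstream scenarios guarantee completeness where counting is
  attempted).
* Whether the 95%-missing patient exclusion counts symptom fields only
  or all maskable fields is undocumented in the rule's provenance; all
  maskable fields is used here.
* Episode/fold layouts in the shipped analyses are scaled to 1 run of
  5 outer / 2 inner folds with a 3-point random search — a problem size
  chosen so the full benchmark (135 patients × 363 days, ~48 000
  episodes × 153 features) runs on a single CPU in minutes while
  preserving the patient-grouped nested structure; the 10 × 10 × 10
  layout remains the configuration default.
* AUC ties count ½ throughout; interval ends are truncated to [0, 1];
  greedy fold balance is asserted at max/min episode ratio ≤ 2 on
  realistic cohorts.

## Known limitations

Complete-scenario AUCs rest on few events (tens), so their confidence
intervals are wide and single-seed comparisons between nearby rule
variants are noisy — the benchmark's claims are directional contrasts
(model vs best rule, imputed vs complete), not precise effect sizes.
The adaptive-penalty and feature-catalogue constructions are documented
reconstructions of common practice, configurable and swappable; the
catalogue's exact membership is a design choice, not a discovery.
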