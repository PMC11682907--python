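# Methods

This note documents the models, algorithms and numerical choices behind
gazebias, and what the synthetic-data generator does and does not emulate.

## Task and measurement model

The paradigm is a visual paired-comparison task: 48 trials of 10 s each, a
pair of images (576 × 346 px) left and right of a central fixation cross on
a 1280 × 1024 screen, gaze sampled at 60 Hz (nominal period 16.67 ms).
Sixteen trials pair a positive with a neutral image, sixteen a negative
with a neutral image, and sixteen two neutral images; the emotional image's
side is randomized per trial. Trial lists are built per participant from a
96-image set (16 positive / 16 negative / 64 neutral): one list of 48
randomly ordered neutral images, a second list of the remaining 16 neutral
plus all 32 emotional images in random order, paired index-wise — so every
image is used exactly once and condition counts are 16/16/16 by
construction.

## AOI dwell extraction

* **AOI assignment.** A sample belongs to the left/right AOI when its
  coordinates fall in the corresponding rectangle. Rectangles are half-open
  (`x0 ≤ x < x1`, `y0 ≤ y < y1`) so edge samples are classified
  deterministically. The default geometry centers each rectangle
  horizontally in its screen half and vertically on the screen; the
  geometry is config-overridable because only the image size, not the
  offsets, is fixed by the task description.
* **Binning.** Successive same-AOI samples form a bin; a new bin starts at
  an AOI change, at an inter-sample interval ≥ `gap_ms`, or after an
  intervening off-AOI/invalid sample. `gap_ms` is 33 ms at clean 60 Hz
  timing — i.e. two or more missed samples — and 66 or 133 ms for
  recordings whose clock precision was degraded (the "dialect" setting).
  Raising `gap_ms` can only merge bins, never split them.
* **100 ms filter.** A bin's duration is the last minus the first member
  timestamp; only bins with duration ≥ 100 ms (boundary inclusive) count
  toward dwell. A single-sample bin has duration 0 and is dropped.
* **Per-trial summary.** Dwell per side is the sum of surviving bin
  durations; first-saccade latency is the timestamp of the first in-AOI
  sample (anchored at trial onset, since trials begin with the eyes on the
  fixation cross); the start-in-AOI flag marks trials whose first recorded
  sample already lies in an AOI. Invalid samples are treated as absent for
  binning; by default they also do not count toward the per-trial sample
  total (configurable).
* **QC exclusions (two-pass).** Pass 1 pools all trials of all subjects and
  computes the mean and SD of latency and of per-trial sample count. Pass 2
  excludes trials that start in an AOI, have latency > mean + 3 SD, have a
  sample count < mean − 3 SD, or never enter an AOI at all. Subjects are
  dropped when more than 1/3 of their trials are excluded. Zero-variance
  cohort statistics disable the corresponding criterion rather than
  excluding everything or nothing arbitrarily.

## Derived scores

* **Emotional bias**: `dwell_emotional / (dwell_emotional + dwell_neutral)`
  per emotional-pair trial; undefined (trial dropped and logged) when both
  dwells are zero; not defined for neutral–neutral pairs, which only enter
  the location model.
* **ERQ**: reappraisal is the mean of the 6 reappraisal items, suppression
  the mean of the 4 suppression items (the instrument's standard
  partition), preference is their difference — positive values mean
  habitual preference for reappraisal.
* **Fisher r-to-z**: `z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))`,
  two-tailed normal p. Requires n > 3 per group.
* **Power**: for a g-group × m-measurement within-between interaction,
  `f² = η²/(1−η²)`, `df1 = (g−1)(m−1)`, `df2 = (N−g)(m−1)` and, under the
  Cohen noncentrality convention, `λ = f²·N`; power is the noncentral-F
  tail beyond the central-F critical value. The alternative convention
  `λ = f²·N·m` used by some power tools is exposed as an option.

## Mixed-effects models

All models are Gaussian linear mixed models with a subject random
intercept, fitted by maximum likelihood (not REML); random slopes are
deliberately not used. Factors are sum-to-zero coded so the reported F
lines are type-III marginal tests, which is the only coding under which an
interaction F is interpretable in the presence of its lower-order terms.
The continuous outcome and predictors are centered and scaled by their
sample SDs *within each model's analysis subset* (e.g. within controls for
the control-group moderation model), so coefficients are standardized β;
the scaling record is retained for back-transformation and for mapping raw
covariate grids (e.g. BDI 0–8) onto the model scale.

The suite:

| model | data | formula (fixed part) |
|---|---|---|
| M1  | two rows per emotional-pair trial (emotional / neutral image dwell) | `dwell ~ image_emotion * condition * image_location` |
| M1b | two rows per neutral–neutral trial (left / right dwell) | `dwell ~ image_location` |
| M2  | one row per emotional-pair trial | `bias ~ bdi * condition` |
| M3  | one row per emotional-pair trial, per group | `dwell_emotional ~ age * condition * erq_preference` |
| M4  | one row per emotional-pair trial, all subjects | `dwell_emotional ~ age * condition * erq_preference * bdi` |

`image_location` is the side of the emotional image. The DV for M3/M4
defaults to the per-trial dwell on the emotional image, with a config
switch to the bias proportion: the prose of such analyses alternates
between "dwell times" and bias scores, and the two DVs answer subtly
different questions (absolute engagement vs relative preference), so both
are first-class.

**Degrees of freedom.** Satterthwaite df are computed in-house because the
estimation backend does not expose them: the profile log-likelihood in
(σ²_subject, σ²_residual) — with fixed effects profiled out by GLS, using
the Woodbury identity per subject block — is differentiated numerically to
get the asymptotic covariance **A** of the variance components; for a
contrast c, `f(θ) = c'(X'V⁻¹X)⁻¹c` has gradient **g** by central
differences and `df = 2 f² / (g'Ag)`. Multi-df terms combine
per-eigencontrast dfs via `E = Σ dᵢ/(dᵢ−2)`, `df2 = 2E/(E−q)` (the
lmerTest recipe). When σ²_subject sits on the zero boundary or the
information matrix is not positive definite, the residual df `N − p` is
used and labeled `residual` in all outputs. This reproduces the
characteristic pattern — between-subject terms get near-`n_subjects` df,
within-subject terms near-`N` df. The df values are approximations and are
not themselves contractual.

**Optimizer robustness.** Several optimizers are tried (L-BFGS first) and
the best ML log-likelihood kept; when the backend fails outright on
boundary fits, the same profile likelihood is maximized directly
(Nelder–Mead on log-variances, multi-start) and the fallback is recorded in
the result's messages. Non-convergence is always flagged, never silent.

**Follow-ups.** Range-averaged marginal contrasts (e.g. the
positive-vs-negative condition contrast "for controls") average model
predictions with equal weight over an integer grid spanning the group's
observed BDI range — equal-grid weighting is a choice, observed-value
weighting being the obvious alternative — and are linear combinations c'β̂
with `SE = sqrt(c'Vc)` and Satterthwaite df. Age simple slopes at
moderator levels (default −1.5, −1, 0, +1, +1.5 SD of ERQ preference, per
condition) are the same machinery with c the difference of design rows at
age+1 vs age; labels carry the raw preference value at each level
(`mean + k·SD`).

## The synthetic-data generator

The generator's purpose is to produce data with exactly the statistical
structure the analysis estimates, so that parameter recovery and QC
behavior can be tested end to end.

* **Cohort.** Ages uniform on 35–75. BDI is a rounded truncated normal:
  controls mean 1.8, SD 1.9 on 0–8; MDD mean 27.3, SD 9.3 on 10–47. ERQ
  items come from latent per-subject (reappraisal, suppression) means —
  bivariate normal per group, controls (5.0, 2.82), MDD (4.0, 4.0), SD
  0.9 — plus item noise (SD 0.7), rounded to the 1–7 scale. The latent
  correlation (controls −0.476, MDD 0) is pre-compensated for the known
  attenuation from item noise and Likert rounding (variance ≈ 1/12), so
  the realized item-mean correlation hits the configured target. These
  defaults put the control preference distribution (mean ≈ 2.2, SD ≈ 1.8)
  and the group difference where the reference cohort sat.
* **Gaze process.** Each trial starts on the fixation cross; after a
  truncated-normal first-saccade latency (mean 310 ms, SD 250 ms, floor
  80 ms) gaze alternates between the two AOIs in gamma-distributed
  episodes (shape 2, mean 500 ms — plausible fixation-cluster dwellings;
  no distributional information about real episode dynamics exists, so
  these are config defaults, not inferences). At each episode boundary the
  emotional AOI is chosen with probability `logistic(η)`; with probability
  0.1 the episode is instead an off-AOI gap on the fixation-cross region
  (participants were instructed not to look away from the screen, so
  off-AOI gaze is parked between the images). The stationary emotional
  dwell share is therefore `logistic(η)` — the property the dwell-share
  convergence tests check.
* **Planted effects.** η sums a baseline, condition offsets (positive 0.45,
  negative 0.30 — an overall emotional bias, stronger for positive pairs),
  age × preference moderation (+0.25 for positive, −0.25 for negative
  pairs — the age-related positivity effect contingent on reappraisal
  preference), a BDI effect on negative-pair dwell (+0.15 — negativity
  rising with symptom load), and a subject random intercept (SD 0.4). Age,
  preference and BDI are standardized within the generated cohort before
  entering η, matching the analysis-side standardization. Neutral–neutral
  trials use η = b0 with the sides exchangeable.
* **Artifacts.** Injectable per-trial artifacts with a ground-truth
  manifest: trials starting inside an AOI, slow first saccades (gaze held
  at center until 3000 ms — far enough above any plausible cohort
  mean + 3 SD cutoff that injected trials are excluded by construction;
  injection rates much above ~5% would inflate the cohort SD enough to
  swallow them), truncated trials, and per-sample dropout (which also
  exercises the gap-splitting rule, since a dropped sample at 60 Hz
  creates a ≥ 33 ms gap).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: saccade kinematics and velocity profiles,
smooth pursuit, calibration drift, blink dynamics, pupillometry,
image-content effects (the synthetic normative ratings are draws around
category means, not properties of real pictures), and any serial
dependence of gaze across trials. Recovery results demonstrate that the
pipeline estimates what the generator plants, not that the substantive
findings would replicate.

## Problem sizes in the test suite

The statistical property tests run at sizes chosen to make their
conclusions meaningful while keeping the suite quick to iterate on:
dwell-share convergence at 500 replicate trials (tolerance 0.05), null
type-I calibration at 200 replicate fits of 500 observations / 50 subjects
(99% binomial band around α = 0.05), planted moderation recovery across 50
replicate pipeline runs of 12-subject cohorts (sign of the +1 SD age slope,
≥ 80% required), and QC ground-truth exactness on one 50-subject cohort.

## Known limitations

* Satterthwaite df rely on a numerical Hessian of the profile likelihood;
  near-boundary variance components fall back to residual df (labeled).
* REML, random slopes, and non-Gaussian outcomes are out of scope; the
  bias proportion is modeled as Gaussian, adequate away from the 0/1
  boundaries but not near them.
* The trial/participant exclusion thresholds are cohort-empirical, so QC
  results depend on the composition of the batch being processed.
* Exact numerical replication of analyses of the original recordings is
  not possible from synthetic data; agreement is tested at the level of
  design constants, closed-form statistics and recovered effect structure.
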