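# Methods

This note records the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Trajectory mixture model

Each subject contributes a complete 6-channel × 12-hour grid of
standardized vital signs. Conditional on latent group *g*, the value of
channel *v* at hour *t* is Gaussian around a polynomial in the centered
hour index c(t) = t − 5.5, with a channel- and group-specific residual
variance; channels and hours are conditionally independent given the
group. This is the standard multi-trajectory formulation; the conditional
independence across channels is a model assumption, not a claim about the
data (vital signs are correlated marginally — the latent group is what
carries that correlation).

Estimation is EM on the observed-data likelihood. The E-step computes
posterior membership in log space with a log-sum-exp guard. Because every
subject shares the same 12-point design matrix, the per-(group, channel)
weighted least squares of the M-step reduces to an ordinary least squares
fit to the posterior-weighted mean profile, which keeps a full EM iteration
at O(NKVT). Residual variances are floored at 1e-6 to prevent degenerate
spikes; a component whose total posterior weight falls below 1e-6 raises an
error suggesting a smaller K. Convergence is |Δ loglik| < tol (default
1e-6, ≤ 300 iterations). Initialization: k-means on the flattened 72-dim
grids for the first start; further starts perturb the k-means centers with
Gaussian noise (0.5 pooled SD) and re-assign; all seeded. The best of
`n_starts` (default 2) by final log-likelihood is returned.

Model selection fits K = 1..6 and keeps models with relative entropy > 0.7
(K = 1 is defined as entropy 1: classification is vacuous) and minimum
modal group share ≥ 5%, choosing the lowest BIC among them (ties to the
smaller K); with no eligible model the lowest-BIC fit is returned with a
warning. The free-parameter count is (K−1) mixing + Σ(order+1)
coefficients + one residual variance per (group, channel). Polynomial
orders start cubic and are pruned per (group, channel): each round, every
slot whose highest-order coefficient has Wald p ≥ α (default 0.05, z from
the final M-step WLS covariance) is decremented and the model refit
warm-started from the previous posteriors — the warm start keeps group
identities aligned across refits. Orders never fall below linear; at most
10 rounds.

Diagnostics use the conventional latent-class definitions: relative
entropy 1 − Σ(−w log w)/(N log K), AvePP as the mean posterior among modal
members of each group, and OCC as posterior odds over prior (mixing) odds,
with +∞ reported when AvePP = 1.

## Preprocessing

Fixed order: plausibility filter → winsorize → hourly aggregate →
impute/exclude → standardize. Implausible values are removed against
inclusive per-channel bounds (defaults HR 20–250, RR 4–60, SBP 40–300,
DBP 20–200, MAP 30–250, SpO₂ 50–100; config-overridable). Winsorization
clips raw observations per channel at the 1st/99th percentiles (linear
interpolation between order statistics — stated because the result depends
on the convention) *before* hourly averaging, so a single artifactual
spike cannot contaminate an hourly mean; whether raw values or hourly
means should be clipped is genuinely open, and the choice is a
sensitivity-analysis candidate. Hour bin h is the half-open [h, h+1).

Imputation rules, in priority order per channel: a run of more than 4
consecutive missing hours on any channel excludes the subject
(`long_gap`); a channel with no observations excludes (`empty_channel`);
interior runs of 1–2 missing hours between observed neighbors are linearly
interpolated; longer interior and trailing runs carry the last observation
forward; leading runs carry the first observation backward (LOCF cannot
fill hour 0; next-observation-carried-backward is its mirror). Observed
cells are never altered, retained grids are complete, and exclusion
bookkeeping reconciles exactly (input = retained + excluded, by reason).
The >4-hour rule counts runs per channel and excludes on any channel — the
conservative reading. Standardization is per channel against the pooled
mean/SD over all retained subject-hours, with the parameters kept for
inverse-transforming fitted curves to native units.

## Survival analysis

Cox partial-likelihood fitting is delegated to lifelines with Efron tie
handling (the synthetic data are day-resolution, so ties are common;
Efron is less biased than Breslow there). Clusters enter as indicator
contrasts against the reference cluster — the one with the lowest ICU
mortality among modal assignments. Wald 95% CIs are exp(β̂ ± 1.96 SE).
The "adjusted for age, sex, race" survival curves use corrected group
prognosis: fit a Cox model with cluster indicators plus the covariates
(age continuous, race a 3-level categorical dummy-coded), then for each
cluster average the predicted survival curve over the *full* cohort's
covariate distribution with that cluster's indicator forced on; pointwise
95% bands come from a seeded nonparametric bootstrap of the whole
procedure (default 200 resamples). The ICU time axis is days from ICU
admission to ICU death, censored at discharge. The product-limit estimator
with Greenwood variance and log-log bands is implemented directly (the
variance is needed explicitly) and cross-checked against lifelines.

## Spline dose–response

The restricted cubic spline basis follows the Harrell convention (linear
term plus k−2 restricted-cubic terms, normalized by (t_k−t_1)²), which is
zero below the first knot and exactly linear beyond the last. Default
4 knots at the (0.05, 0.35, 0.65, 0.95) sample quantiles (3 and 5 knots at
their conventional positions are available). Models are fitted within the
high-risk cluster on ICU mortality, adjusted for age, sex and SOFA. The
hazard-ratio curve is exp(f̂(x) − f̂(x_ref)) with x_ref the within-cluster
median, CI by the delta method on the spline coefficient block;
nonlinearity is the joint Wald test of the k−2 nonlinear coefficients
(χ², df = k−2). No multiplicity correction is applied across the six
parameters by default, matching per-parameter presentation. The gas value
analyzed is the subject's admission value as emitted by the generator
(one value per parameter; with real data, the first measurement within
the initial 12 h is the least-processed choice).

## Risk-model forests and safe zones

One random forest per gas parameter predicts ICU death from the clinical
covariates (age, sex, SOFA, APS-III, invasive ventilation, CRRT, RRT) plus
that parameter — this reconciles a univariate dose–response presentation
with covariate-aware prediction. Hyperparameters are tuned by seeded
5-fold stratified CV maximizing AUROC over a small grid (trees ∈ {200,
500}, per-split features ∈ {√p, p/3}, min leaf ∈ {5, 20}). Partial
dependence PD(x) = mean over subjects of the predicted death probability
with the parameter forced to x, on a 50-point grid spanning the
within-cluster 1st–99th percentiles (clipping avoids zones driven by
extrapolation). The safe zone is the maximal contiguous grid run
containing the (leftmost) global PD minimizer with PD ≤ PDmin +
δ(PDmax − PDmin); δ = 0.2 by default and is recorded in every report. The
zone therefore always contains the minimizer and widens monotonically
with δ; a flat profile yields the full grid span with a warning. A
bivariate PD surface is provided for visualization only; the univariate
profile drives zone extraction.

## Synthetic cohort

The generator emulates the structure the analysis assumes, not any real
database's marginals:

- **Groups.** Three latent groups with mixing (0.24, 0.35, 0.41). Mean
  trajectories are low-order polynomials in native units: group 1
  hypertensive (SBP ~152 falling, MAP ~106), group 2 hyperinflammatory
  (HR ~112 rising, RR ~28, SpO₂ ~91.5), group 3 hypo-inflammatory (low
  pressures, SpO₂ ~98). Residual SDs (HR 8, RR 3, SBP 10, DBP 7, MAP 8,
  SpO₂ 1.5) give every group pair ≥ 2 SD separation in at least one
  channel at hour 5.5. Raw observations are emitted 2–4 per subject-hour
  with jittered timestamps (real sampling frequency before hourly
  averaging is unknown; this is configurable), values drawn around the
  hour-index mean so hourly averages are unbiased for the group curve;
  SpO₂ is capped at 100 (physical ceiling of pulse oximetry).
- **Survival.** Latent event times are Weibull (scale 900 d, shape 0.9)
  with proportional hazards: group log-HRs (0, log 1.5, 0) plus mild age
  (0.004/yr) and SOFA (0.02/point) effects — mild so that the crude
  group-2 contrast stays ≈ 1.5 after marginalization. 28/90/365-day
  outcomes derive from this time with administrative censoring at 365 d
  plus a 5% uniform early-censoring fraction; times are rounded up to
  whole days, which produces realistic ties.
- **ICU death** is a separate logistic mechanism: base logit −4.0, group
  shift (0, 1.1, 0) — giving ≈ 31% ICU mortality in group 2 vs ≈ 18%
  elsewhere, mirroring the magnitude of contrast the analysis is meant to
  detect — plus mild covariate effects and, for each gas parameter, an
  excess term that is zero inside the risk-minimizing interval [a, b] and
  grows at 2.5 logit per SD of distance outside it. Gas values are
  independent truncated normals with clinically plausible centers; the
  intervals are placed with both edges within ~±1.3 SD of the mean so
  both arms of the U are inside the observed support — otherwise no
  estimator could recover an edge it never sees data beyond. ICU
  time-to-death for deaths (and discharge for survivors) is exponential,
  whole-day.
- **Corruption.** Missingness deletes subject-hour-channel cells
  independently (default 3%) and gives selected subjects (4%) one
  contiguous 5–6 h run on one channel; outliers (0.3%) replace values with
  points strictly outside the plausibility ranges. Both record exact
  bookkeeping so preprocessing can be verified cell-for-cell.

What passing tests on this generator do **not** show: robustness to
channel correlations beyond group structure, informative missingness,
correlated blood gases, non-proportional hazards, or measurement drift —
none of which the generator produces. Results on real ICU extracts depend
on those properties.

## Problem sizes and randomness

The validation suite runs the trajectory-recovery study at n = 600 × 20
seeds, Cox calibration at n = 2,000 × 200 replicates, spline-test
calibration at n = 800 × 1,000 (size) and n = 1,000 × 200 (power), and
safe-zone recovery at n = 2,000 × 20 seeds with 200-tree forests — sizes at
which each check's sampling error is small relative to its acceptance
margin. The acceptance script runs the full pipeline once at n = 2,000
with 300-tree forests and a 50-resample bootstrap. All randomness derives
from one root seed via `SeedSequence((root, stage))`; two runs with the
same configuration are byte-identical.

## Known limitations

- The entropy definition in the literature varies; the standard
  latent-class relative entropy is used.
- The ICU-death mechanism being logistic while the Cox stage models time
  to ICU death means the spline stage's proportional-hazards form is an
  approximation even on synthetic data; it is the recovered *shape* (U
  vs linear) that is validated, not the hazard scale.
- Backward elimination tests each highest-order term at α per round;
  spurious retention of a higher order occurs at roughly the test level
  per slot, which is inherent to the procedure.
- No multiple imputation, no covariates on mixing probabilities, no
  non-Gaussian channel families, no competing risks, no propensity
  weighting.
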