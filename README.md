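# traj2targets

Trajectory phenotyping of early ICU physiology, and model-derived blood-gas
target ranges for the resulting high-risk subgroup.

## The problem

In critically ill septic patients with thrombocytopenia, the first hours in
the ICU carry most of the prognostic signal, but single-timepoint summaries
discard the dynamics. This package implements a full
"trajectory-to-targets" analysis for that setting:

1. **Phenotype** patients by the joint shape of six vital-sign trajectories
   (HR, RR, SBP, DBP, MAP, SpO₂) over the first 12 ICU hours, using
   group-based multi-trajectory modeling (GBMTM): a finite mixture of
   polynomial regressions fitted jointly over all channels by EM. Subject
   *i* in latent group *g* has

   y<sub>ivt</sub> | g ~ N(Σ<sub>p</sub> β<sub>gvp</sub> c(t)<sup>p</sup>, σ²<sub>gv</sub>),
   L<sub>i</sub> = Σ<sub>g</sub> π<sub>g</sub> Π<sub>v,t</sub> φ(y<sub>ivt</sub>),

   with channels and hours conditionally independent given the group. The
   number of groups K is chosen over 1–6 by BIC among models with relative
   entropy > 0.7 and every modal group share ≥ 5%; polynomial orders are
   pruned per (group, channel) by backward elimination of non-significant
   highest-order terms; classification quality is reported as AvePP and the
   odds of correct classification (OCC).
2. **Quantify risk**: Cox proportional-hazards contrasts of the clusters
   (crude; Model 1 = age + sex; Model 2 = Model 1 + SOFA, APS-III, invasive
   ventilation, CRRT, RRT) at ICU, 28-, 90- and 365-day horizons, with
   covariate-adjusted survival curves by corrected group prognosis.
3. **Derive targets**: within the highest-ICU-mortality cluster, restricted
   cubic splines (Harrell basis, 4 knots) model the dose–response between
   each blood gas parameter (pH, PO₂, PCO₂, lactate, base excess, total
   CO₂) and ICU mortality with a joint Wald nonlinearity test; CV-tuned
   random forests plus univariate partial dependence extract the "safe
   zone" — the contiguous value range whose predicted mortality lies in the
   lowest δ-band of the PD range.

No credentialed ICU database (MIMIC-style electronic health record
extracts) is required or included. A first-class synthetic-cohort generator
(`traj2targets.synthetic`) emits cohorts with the exact latent structure the
analysis assumes — known trajectory groups, group-dependent Weibull hazards,
U-shaped blood-gas risk with known risk-minimizing intervals, realistic
missingness and outliers — so every stage can be validated against ground
truth. Users with their own ICU extract can run stages 02–06 on tables
matching the documented schema (`vitals.csv`: subject_id, time_hr, channel,
value; `cohort.csv`: one row per subject with covariates, gas values and
per-horizon time/event columns).

## Worked example

The analysis is a sequence of numbered drivers over the library:

```bash
python analysis/01_simulate.py        --n 2000 --seed 7 --out results/sim
python analysis/02_preprocess.py      --vitals results/sim/vitals.csv --out results/preprocess
python analysis/03_fit_trajectories.py --grids results/preprocess/grids.csv --seed 7 --out results/gbmtm
python analysis/04_survival.py        --out results/survival
python analysis/05_rcs.py             --out results/rcs
python analysis/06_safe_zones.py      --seed 7 --out results/targets
```

A run at `--seed 7` (2,000 subjects; 92 excluded for long gaps) prints, at
stage 03:

```
 K     loglik  n_params       bic       aic  entropy  min_share  eligible
 1 -194804.05        30 389834.71 389668.10     1.00       1.00      True
 2 -110696.25        61 221853.28 221514.49     1.00       0.23      True
 3  -37454.97        92  75604.89  75093.94     1.00       0.23      True
 4  -37418.04       123  75765.20  75082.08     0.86       0.18      True
 5  -37381.36       154  75926.00  75070.71     0.82       0.09      True
 6  -37349.70       185  76096.85  75069.40     0.83       0.01     False
chosen K = 3; entropy 1.000; min AvePP 1.000; min OCC inf
```

— a steep BIC drop to the three-group solution, which then plateaus; the
synthetic groups are well separated so classification is crisp (entropy
~1), and the recovered mixing proportions match the generating
(0.24, 0.35, 0.41). Stage 04 identifies the fitted cluster with the
highest ICU mortality (29.4% vs 16.4% in the reference) and reports its
Cox contrasts; stage 05 flags the U-shaped dose–response of all six gas
parameters (joint Wald p < 0.002 for each); stage 06 prints the safe
zones:

```
  pH 7.29–7.48
  PO2 118.05–200.31 mmHg
  PCO2 31.25–56.10 mmHg
  lactate 1.31–4.55 mmol/L
  base_excess -5.83 to 6.43 mEq/L
  total_co2 16.44–29.68 mEq/L
```

which overlap the generator's true risk-minimizing intervals (pH
7.30–7.48, PCO₂ 28–54, lactate 0.8–5.2, base excess −8 to 6.5, total CO₂
18–30.5). `pipeline.run_all(PipelineConfig(...))` performs the same
sequence in one call and writes a manifest plus a markdown report.

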