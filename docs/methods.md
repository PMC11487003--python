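# Methods

## Problem setting

One *case* is one patient at one clinic visit during warfarin follow-up after
cardiac surgery. The output is the observed INR, used either directly
(regression) or dichotomised against the closed clinical target interval
[1.8, 2.5] into `Within`/`Out` (classification). Inputs per case are:

- `Dose01..Dose63` — the warfarin dose (mg/d) administered 1..63 days before
  the INR measurement, zero-padded before the first dosed day;
- `TreatDay01..TreatDay63` — for each of those days, how many consecutive days
  the then-current dose level had been held (run length, days);
- demographics (`age` y, `height` cm, `weight` kg, `POD` = days since first
  warfarin dose, which in this setting approximates post-operative days);
- laboratory analytes and co-medication daily doses (units per variable);
- a categorical label vector: sex (`DemoCat`), surgery type (`TypeCat`),
  valve type (`ValveCat`), *CYP2C9* genotype (`PKGeneCat`), *VKORC1*
  genotype (`PDGeneCat`).

The column roster is configuration (`PartitionScheme`), not code: user tables
may register arbitrary extra continuous variables, variable groups and
partitions. Day indexing starts at day 1 = first dosed day.

## Perturbation-theory operators

For each partition P and continuous variable v_k, the first-order operator is
Δv_k(P) = v_k − α·⟨v_k | label of the case in P⟩, where the group mean is
estimated on the **training split only** and frozen (leakage contract). Labels
unseen in training, or groups below `min_group_size` (default 1), back off to
the global training mean, so prediction-time inputs are always transformable.
The second-order operator collapses a variable group g to (Σ_{k∈g} Δ_k^q)^r —
the Euclidean norm for the `ed` preset (q=2, r=½); for a singleton group it
reduces to |Δ|. The three preset levels (`raw` α=0 q=1 r=1; `ma` α=1 q=1 r=1;
`ed` α=1 q=2 r=½) are the validated configurations; other (α, q, r)
combinations are constructible but not exercised by default.

The reference function f_ref is the training prevalence of `Within` in the
case's label cell. The default conditioning is the joint label vector with
back-off to the global prevalence when the cell holds fewer than 10 training
cases (`f_ref_min_group`); `partition` and `global` modes are available
because the appropriate conditioning set is context-dependent. Deviation and
distance features are emitted unweighted; all weighting lives in the fitted
model coefficients.

## Models

`fit_lda` implements the two-class linear discriminant in closed form: pooled
within-class covariance S_w (ridge-stabilised by λ = 1e-6 × mean diagonal,
configurable), w = S_w⁻¹(μ₊ − μ₋), intercept −w·(μ₊+μ₋)/2 + log(n₊/n₋).
Constant features are dropped with a warning; of duplicated columns exactly
one is retained. The decision threshold is score > 0 with `Within` positive;
`ScoreCalibration` provides a monotone logistic map from score to
P(Within) when probabilities are needed. Forward stepwise selection uses the
OLS partial-F on the 0/1 class indicator (equivalent to the classic
F-to-enter of stepwise discriminant analysis for two groups), p-to-enter 0.05,
deterministic column-order tie-break, and a forced expert set (variables of
known physiological relevance are kept regardless of significance).

The three builtin models carry their published coefficients verbatim,
including training-set size (N=2446) and chi-squared metadata; they are
scorers only — their term namespaces (e.g. partitions `NRGeneCat`,
`ClotGeneCat`, `VKPKGeneCat`) reference the source study's roster, which is
wider than the synthetic generator's.

All other algorithms are thin adapters over scikit-learn (LinearRegression,
LogisticRegression, GaussianNB as the Bayes-net-family baseline, MLP, SVM,
KNN, Bagging, RandomForest), seeded for exact refit, behind one
`predict`/`predict_score` surface.

## Evaluation

Train/validation split defaults to case-level sampling with fraction 0.75
(round(0.75 × 3261) = 2446). Case-level splitting of longitudinal data is
optimistic — a patient's other visits inform their validation rows — so a
patient-grouped mode is provided and recommended for honest generalisation
claims. Regression metrics: Pearson correlation, MAE, RMSE, and RAE/RRSE in
percent, normalising against the mean-only predictor of the *same* evaluation
set. Predicted bias PB = 100·(pred − obs)/obs with the closed ideal band
|PB| ≤ 20%. Classification: per-class TPR/FPR/precision/recall/F-measure and
ROC area (from scores), overall accuracy, Sn/Sp of the `Within` class, and
the 2×2 confusion chi-squared (1 df, no continuity correction). The
univariate screen routes continuous×continuous to Pearson,
categorical×continuous to Mann–Whitney (2 levels) or Kruskal–Wallis (>2),
continuous×class to the Wilcoxon rank-sum and categorical×class to
chi-squared, flagging p < 0.05; it is advisory and never drops variables.

## Synthetic cohort generator

The generator emulates the *shape* of a prospective heart-valve-replacement
warfarin cohort: 246 patients, ~2900–3200 INR measurements, follow-up uniform
on 12–188 days (median ≈ 100), visit gaps = rounded normal(6.7, 7.8) truncated
at 1 day, sex 63.8% male, *CYP2C9* \*1/\*1 92.3% / \*1/\*3 7.7%, *VKORC1*
AA/AG/GG 85.5/13.8/1.2% (renormalized), age 58±13 y, weight 63.9±11.8 kg,
height 164.7±8.8 cm.

The INR response is an invented stand-in, not an estimate from any study:

    INR(t) = baseline + β · G · E(t) / weight + ε,   floored at 0.8

with E(t) the exponentially weighted mean of the previous 63 days' doses
(weights halving every `exposure_halflife_days`; a constant history of d mg/d
gives E = d exactly), G the product of genotype multipliers, and
ε ~ N(0, noise_sd). Dosing follows a bang-bang titration: start at
`dose_init`, +`dose_step` when below range, −`dose_step` when above, hold
inside. Labs are per-patient baselines plus within-patient noise, measured at
a visit with fixed probability (irregular sampling feeds the imputation
stage); co-medications are per-drug Bernoulli prevalences with constant daily
dose.

Defaults and rationale (all in `SimulationParams`, units as stated):

| parameter | default | why |
|---|---|---|
| `sensitivity_beta` | 27 INR·kg/(mg/d) | steady-state dose ≈ 2.1 mg/d at the target midpoint for the average patient |
| `genotype_multipliers` | VKORC1 AA 1.3 / AG 1.0 / GG 0.7; CYP2C9 \*1/\*3 1.4 | strong planted pharmacogenetic effect; titration then yields the negative genotype→dose correlation real cohorts show |
| `exposure_halflife_days` | 4 d | effect of a dose change builds over ~1 week, as with vitamin-K-dependent factor turnover |
| `dose_init`, `dose_step` | 1.0, 0.25 mg/d | conservative post-operative start with quarter-tablet adjustments; gives a multi-week up-titration ramp |
| `noise_sd` | 0.15 INR | low end of within-patient INR variability; the default cohort is a controlled strong-signal regime |
| `baseline_inr` | 1.0 | normal coagulation without anticoagulant |

These defaults place the default cohort firmly in a recoverable-signal
regime: the under-anticoagulated up-titration phase plus the
genotype-dependent steady state carry enough structure that the ma-level
stepwise-LDA pipeline beats majority-class prevalence by well over ten
accuracy points, while zeroing `sensitivity_beta` (with the baseline moved to
the target midpoint so both classes occur) removes all label–covariate
dependence.

What the generator does **not** emulate — hence what passing tests do not
show about real data: no mechanistic PK/PD (no compartments, clearance or
vitamin-K dynamics), linear dose–response with no saturation, no adherence
lapses or interacting-drug pharmacokinetics, no informative missingness
(visit timing is outcome-independent), and co-medication/lab values are
stationary rather than episode-driven. Performance numbers on synthetic
cohorts characterise the pipeline's machinery, not clinical accuracy.

## Numerical choices

- Target interval closed on both ends; boundary INRs are clinically in range.
- Group means, f_ref and imputation means are fitted on the training table and
  frozen for validation/prediction.
- Imputation: last-observation-carried-forward within patient, then
  training-mean fill; a variable missing everywhere is an error.
- LDA ridge default 1e-6 × mean diagonal of S_w; stepwise tie-break by column
  order; missing model terms at scoring time are an error, never a silent 0.
- CSV round trips use shortest round-trip float text on write and
  `float_precision="round_trip"` on read, so write→read is bit-identical.
- Per-run randomness: one seed, expanded per stage via
  `numpy.random.SeedSequence.spawn` in fixed stage order.
- Problem sizes in the test suite: the full 246-patient default cohort for
  recovery and self-fit checks, a 30-patient cohort for oracle-equivalence
  fixtures, and a 120-patient cohort for the end-to-end reproducibility run —
  sizes chosen to exercise every code path at full column arity while keeping
  the suite quick to iterate.

## Known limitations

- The builtin published models can score user-supplied feature tables but are
  not re-derivable here: their training data, full variable roster and the
  exact software settings behind them are not public.
- The paper-facing posterior-probability procedure is unspecified upstream;
  the logistic calibration here is this package's own choice.
- Case-level splitting (the default, matching the printed training-set size)
  overstates validation performance on longitudinal data; use
  `split_mode="patient"` for generalisation estimates.
- The univariate screen applies no multiple-testing correction (by design,
  matching its advisory role).
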