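# warfptml

Information-fusion + perturbation-theory + machine-learning (IFPTML) modelling
of longitudinal warfarin anticoagulation data.

Warfarin dosing is individually titrated against the INR (international
normalized ratio), a standardized measure of anticoagulation intensity, with a
narrow clinical target range (1.8–2.5 for the heart-valve-replacement setting
this package emulates). Response varies strongly between patients — with body
weight, co-medication, and variants of the pharmacogenes *CYP2C9* and
*VKORC1* — and within a patient over the weeks of follow-up. `warfptml`
implements a reusable pipeline for modelling visit-structured INR data: each
clinic visit becomes one *case* carrying the observed INR, a 63-day look-back
window of daily doses and treatment-day run lengths, demographic/lab/
co-medication covariates, and a categorical label vector. Because real
anticoagulation records are generally not depositable, the package includes a
fully parameterised synthetic cohort generator with the same statistical shape,
so the whole pipeline is testable end to end.

## The model

Continuous variables v_k are centered against *moving averages* — the mean of
v_k over training cases that share a categorical label s_j (a *partition*:
surgery type, genotype, sex, …):

    Δv_k(s_j) = v_k − α·⟨v_k | s_j⟩                 (first-order operator)

    ‖Δg(s_j)‖ = ( Σ_{k∈g} Δv_k(s_j)^q )^r           (second-order operator)

with hyperparameters α (switching), q (moment power) and r (distance power).
Three preset data levels are exposed: **raw** (α=0, q=1, r=1 — untransformed
variables), **ma** (α=1, q=1, r=1 — all per-partition deviations) and **ed**
(α=1, q=2, r=½ — the Euclidean norm of each variable group's deviation
vector). A scalar reference function f_ref — the training prevalence of the
in-range outcome in the case's label cell — completes the feature set. The
linear classification model is the discriminant score

    f_calc = a_0 + a_1·f_ref + Σ_k a_k·feature_k ,      score > 0 ⇒ "Within"

fitted by two-class LDA with forward-stepwise variable selection (partial-F,
p-to-enter 0.05, with an always-included expert set). Three published fitted
instances of this score — one per data level — ship as builtin models
(`builtin_model("eq2_raw" | "eq3_ma" | "eq4_ed")`) with their coefficients
verbatim. A standard scikit-learn battery (logistic, naive Bayes, MLP, SVM,
KNN, bagging, random forest, linear regression) sits behind the same feature
tables for both the regression task (predict the INR) and the classification
task (predict Within/Out of range). Group means, reference prevalences and
imputation means are always fitted on the training split only and frozen —
validation rows are transformed, never re-estimated.

## Worked example

Run the default pipeline (simulate a 246-patient cohort, fuse, build ma-level
features, stepwise-LDA, evaluate):

```python
from warfptml.cli import run_pipeline
from warfptml.io import RunConfig

manifest = run_pipeline(RunConfig(out_dir="demo_run", seed=1))
```

which logs the fused case count (`fused 2945 cases from 246 patients`), the
per-variable imputation counts, and writes `report.csv`:

```
       set level algorithm  Within_tpr  Within_fpr  accuracy     sn     sp     chi2
  training    ma       LDA       0.954       0.286    87.823 95.430 71.388 1116.817
validation    ma       LDA       0.952       0.297    88.043 95.229 70.283  358.841
```

Validation accuracy (88.0%) sits ~14 points above the majority-class
prevalence of this cohort, i.e. the pipeline recovers the planted
dose/genotype signal from the deviation features; sensitivity (sn) and
specificity (sp) are the true-positive and true-negative rates of the
in-range class, and chi2 is the 2×2 confusion-table chi-squared. The same
config with `level="raw", task="regression", algorithm="RF", stepwise=False`
produces the regression layout instead (correlation, MAE, RMSE, relative
errors, and the predicted-bias bins PB<−20% / ideal / PB>20%):

```
       set level algorithm  corr   mae  rmse    rae   rrse  pb_low  pb_ideal  pb_high
  training   raw        RF 0.982 0.049 0.063 20.111 20.001   0.000   100.000    0.000
validation   raw        RF 0.823 0.137 0.172 59.222 56.865   0.815    95.109    4.076
```

The same stages are scriptable from a shell:

```sh
warfptml simulate --out cohort/ --seed 1
warfptml fuse     --cohort cohort/ --out cases.csv
warfptml features --cases cases.csv --out feats.csv --level ma --means-out means.json
warfptml run      --config config.yaml
warfptml predict  --model run/model.json --means run/group_means.json \
                  --cases cases.csv --out predictions.csv
warfptml evaluate --predictions predictions.csv --cases cases.csv
```

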