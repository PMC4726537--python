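# mbdforest

Random-forest analysis of the mineral-bone-disorder (CKD-MBD) biochemistry
of hemodialysis patients: serum calcium (Ca), phosphate (P) and parathyroid
hormone (PTH).

In dialysis populations these three parameters are regulated jointly —
nonlinearly, with feedback, and under treatment given *because* a value is
extreme (confounding by indication).  Classical linear regression between
any pair therefore understates how tightly the system is coupled.
`mbdforest` implements the forest-based alternative end to end, for
biostatisticians and nephrology researchers working with monthly dialysis
lab records:

- **Regression forests from scratch** — bagged CART trees with per-split
  random feature subsets (100 trees, `mtry = ⌈f/3⌉`, `min_leaf = 5` by
  default), exposed as a statsmodels-style model/results pair.  Accuracy is
  the test-set mean absolute error (MAE) and the Pearson correlation r
  between predicted and observed values on a random 70/30 record split.
- **Drop-column importance in clinical units** — the increase in test MAE
  (mg/dL, pg/mL) when the model is refit without one input, with paired
  Wilcoxon significance matrices comparing any two reduced models on
  shared test records.
- **Counterfactual perturbation analysis** — impose a random change
  δP ∈ [−3, +3] mg/dL on phosphate with all other inputs held fixed and
  correlate δP with the predicted change in PTH.  The model-mediated
  correlation r(δP, ΔPTH) is systematically stronger than the marginal
  observational r(P, PTH), because the model carries the concurrent
  effects of all covariates.
- **A synthetic cohort generator** — the real cohorts of this kind are not
  public, so the package generates populations of 1758 patients × 26
  monthly records whose marginals match a published hemodialysis
  population (Ca 9.4 ± 0.9 mg/dL, P 4.7 ± 1.4 mg/dL, PTH 317 ± 320 pg/mL,
  …) and whose dependence structure encodes saturating phosphate→PTH
  stimulation, Ca↔PTH feedback, vintage/age effects and
  treatment-by-indication rules for 8 drug classes.

## Worked example

```python
from mbdforest import (CohortConfig, generate_cohort, encode_features,
                       split_train_test, ForestConfig, RandomForest)
from mbdforest.importance import drop_feature_importance
from mbdforest.perturbation import (PerturbationConfig, marginal_correlation,
                                    perturbation_response)
from mbdforest.pipeline import fit_linear_baseline

table = generate_cohort(CohortConfig(seed=3)).sample(4000, random_state=3).reset_index(drop=True)
matrix = encode_features(table, "pth")           # 16 inputs, PTH output
split = split_train_test(matrix, seed=3)         # 2800 train / 1200 test
res = RandomForest.from_feature_matrix(matrix, ForestConfig(seed=3),
                                       train_idx=split.train_idx).fit()

rf = res.evaluate(matrix.X[split.test_idx], matrix.y[split.test_idx])
lin = fit_linear_baseline(matrix, split)
print(f"forest r = {rf.pearson_r:.2f}, MAE = {rf.mae:.0f} pg/mL")
print(f"linear r = {lin.pearson_r:.2f}, MAE = {lin.mae:.0f} pg/mL")

r_marg, _ = marginal_correlation(table, "p", "pth")
pert = perturbation_response(res, matrix, PerturbationConfig(seed=3),
                             records=split.test_idx)
print(f"marginal r(P, PTH) = {r_marg:.2f}")
print(f"perturbation r(dP, dPTH) = {pert.pearson_r:.2f}")
```

prints (exact values; the run is seed-deterministic):

```
forest r = 0.71, MAE = 128 pg/mL
linear r = 0.65, MAE = 140 pg/mL
marginal r(P, PTH) = 0.38
perturbation r(dP, dPTH) = 0.66
```

The forest predicts held-out PTH better than the multivariate linear model
(r 0.71 vs 0.65), and the counterfactual phosphate→PTH correlation (0.66)
is far stronger than the marginal observational one (0.38): predicting the
*change* in PTH from an imposed change in P is much more informative than
the raw scatter suggests, which is the central point of this analysis
style.  `drop_feature_importance(matrix, split, ForestConfig(seed=3))`
then attributes the forest's accuracy to individual inputs: alkaline
phosphatase is the dominant predictor of PTH, phosphate, vintage and
calcium follow, and the deliberately uncoupled potassium lands at zero.

The same pipeline is scriptable from the shell:

```bash
mbdforest simulate --seed 1 --out cohort_dir
mbdforest run --seed 1 --out run_dir --max-records 4000
```

`run` writes per-output metrics (`metrics.json`), importance tables and
figures, the perturbation scatter, and a manifest with the config hash.

## Layout

| module | contents |
| --- | --- |
| `mbdforest.cohort` | `CohortConfig`, `generate_cohort`, `summarize_cohort`, CSV/YAML IO |
| `mbdforest.dataset` | `read_records`, `filter_complete`, `encode_features`, `split_train_test` |
| `mbdforest.tree` / `.forest` | CART engine, `RandomForest` / `RandomForestResults`, metrics, serialisation |
| `mbdforest.importance` | drop-column and permutation importance, pairwise Wilcoxon matrices |
| `mbdforest.perturbation` | marginal correlation, perturbation responses, response bands |
| `mbdforest.pipeline` / `.cli` | `run_pipeline`, OLS baseline, `mbdforest` CLI |

See `docs/methods.md` for the full model description, generator
assumptions and limitations.
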