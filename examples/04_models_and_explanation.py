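"""Tune a boosted-tree model, compare original vs augmented training data,
and explain the fit with tiered Shapley attribution.

The tuner is a tree-structured Parzen estimator over a log-uniform/uniform
search space, scored by 5-fold CV RMSE; the test set is touched exactly once
per run. Attribution uses the first applicable tier: the booster's native
per-feature contributions, the package's path-dependent Tree SHAP, or Kernel
SHAP with a k-means background.
"""

from sdml.augment import augment_dataset
from sdml.data import SplitSpec, split_train_test
from sdml.explain import explain_model, rank_importance
from sdml.models import compare_runs, fit_and_report
from sdml.synthdata import GeneratorSpec, simulate_dataset

table, _ = simulate_dataset(GeneratorSpec(n=350, seed=3))
train, test = split_train_test(table, SplitSpec(0.75, seed=3))
augmented, _ = augment_dataset(train, seed=3)

reports, models = [], {}
for label, data in (("original", train), ("augmented", augmented)):
    rep, model = fit_and_report(data, test, "lightgbm_like", label, budget=10, seed=3)
    reports.append(rep)
    models[label] = model
    print(f"{label:9s}: CV RMSE {rep.cv_rmse:.4f}, test R^2 {rep.test_r2:.4f}, "
          f"test RMSE {rep.test_rmse:.4f}")
row = compare_runs(reports).iloc[0]
print(f"test RMSE change after augmentation: {row['test_rmse_improvement_pct']:+.1f}%")

expl = explain_model(models["augmented"], test)
print(f"attribution tier: {expl.tier_used}")
imp = rank_importance({"lightgbm_like": expl})
print("top features by mean |SHAP| share:")
print(imp.head(4).round(3).to_string())
print("MW and species should dominate — they carry most of the planted signal")
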