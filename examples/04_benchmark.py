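"""Run a reduced version of the end-to-end suitability benchmark.

Objects are rendered from ground truth, featurized, the 7 best features are
selected, and an rbf-kernel SVM is tuned by cross-validation and evaluated
on held-out objects with bootstrap confidence intervals.
(The full-scale run uses 1000 training / 360 testing objects; see
scripts/acceptance.py.)
"""

from cellcull.benchmark import compare_classifiers, run_benchmark

result = run_benchmark(seed=0, n_train=200, n_test=100, folds=5,
                       grid={"C": [1.0, 8.0, 64.0], "sigma": [1.0, 4.0, 16.0]},
                       bootstrap=300)

print("selected features:", ", ".join(result.selected_features))
r = result.report
print(f"test error rate:  {r.error_rate:.3f}")
print(f"test sensitivity: {r.sensitivity:.3f} "
      f"(90% CI {r.ci['sensitivity'][0]:.3f}-{r.ci['sensitivity'][1]:.3f})")
print(f"test AUC:         {r.auc:.4f} "
      f"(90% CI {r.ci['auc'][0]:.4f}-{r.ci['auc'][1]:.4f})")

errors = compare_classifiers(result, seed=0,
                             grid={"C": [1.0, 8.0, 64.0],
                                   "sigma": [1.0, 4.0, 16.0]}, folds=5)
print("classifier test errors:", {k: round(v, 3) for k, v in errors.items()})
# Sensitivity is suitable-cell recall; AUC is the probability that a random
# suitable object outscores a random unsuitable one.
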