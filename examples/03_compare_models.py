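"""Compare two models' paired cross-validation losses.

Both models are evaluated on the same fold plan, so their per-repetition MSE
vectors are paired; the Wilcoxon signed-rank statistic is then thresholded
against a within-pair sign-flip permutation null.
"""

import numpy as np

import lesionpls as lp

syn = lp.make_cohort(seed=0)
plan = lp.make_fold_plan(syn.cohort.n_patients, k=10, n_repetitions=200, seed=1)

model_cv = lp.cross_validate(syn.cohort, lp.ModelSpec(("hours", "lesions"), 2), plan)
null_cv = lp.cross_validate(syn.cohort, lp.ModelSpec(()), plan)

print(f"lesions+hours median MSE: {model_cv.median_mse:.1f} (IQR {model_cv.iqr_mse:.1f})")
print(f"null          median MSE: {null_cv.median_mse:.1f} (IQR {null_cv.iqr_mse:.1f})")
print(f"model wins in {np.mean(model_cv.mse < null_cv.mse):.0%} of repetitions")

result = lp.paired_permutation_test(model_cv.mse, null_cv.mse,
                                    n_permutations=5000, seed=2,
                                    label_a="hours+lesions", label_b="null")
print(f"signed-rank W+ = {result.statistic:.0f}, permutation p = {result.p_value:.4f}")
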