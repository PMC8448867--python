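# lesionpls

Prognostic modelling of post-stroke anomia treatment response from lesion
anatomy and therapy dose, using partial least squares (PLS) regression.

## The problem

After a left-hemisphere stroke, many people have anomia — difficulty naming
common objects — and intensive naming therapy helps some patients far more
than others. Clinically one would like to predict, before committing to weeks
of therapy, how much a given patient stands to gain. Two kinds of information
are plausibly prognostic: *where* the lesion sits (damage to some regions may
remove the substrate therapy relies on) and *how much* therapy the patient
receives.

`lesionpls` implements a complete small-cohort modelling workflow for this
question:

1. **Lesion encoding** — each patient's binary lesion mask is reduced to a
   vector of *lesion loads*: for every atlas region, the fraction of the
   region's voxels covered by the lesion (0 = spared, 1 = fully lesioned).
   Probabilistic atlas regions are binarised at a configurable threshold
   (default 0.5, inclusive), and regions no patient's lesion touches are
   pruned.
2. **Model fitting** — PLS regression (few latent components, no predictor
   selection) maps predictor blocks (demographics, initial naming severity,
   therapy hours, lesion loads) to treatment response, which is measured as
   the change in naming accuracy on treated items. Predictors are z-scored
   with training-fold statistics only.
3. **Evaluation** — repeated k-fold cross-validation (default 1000 × 10-fold)
   on a *shared* fold plan, so that every model's per-repetition losses are
   paired with every other model's, including the null model that simply
   predicts the training-fold mean response.
4. **Comparison** — models are compared with the null via the Wilcoxon
   signed-rank statistic on paired losses, thresholded against a within-pair
   sign-flip permutation null, with familywise error control over the model
   grid (Bonferroni by default).
5. **Interpretation** — data-perturbation influence weights: the frozen
   model's predictions are recorded while random halves of the variables are
   shuffled; each variable's weight is the pooled correlation between its
   perturbed values and the predictions. A stability check repeats the whole
   procedure with independent sub-seeds. A proxy-region analysis explains
   counter-intuitive positive lesion weights via lesion covariance.
6. **Synthetic cohorts** — no patient data ship with the package; a generator
   produces toy-atlas cohorts with contiguous growth-process lesions, planted
   region weights, a therapy-hours effect, and controlled noise, so every
   claim the package makes is testable against known ground truth.

## Worked example

Compare the lesions+hours model with the null on a synthetic cohort
(`examples/03_compare_models.py`):

```python
import numpy as np
import lesionpls as lp

syn = lp.make_cohort(seed=0)
plan = lp.make_fold_plan(syn.cohort.n_patients, k=10, n_repetitions=200, seed=1)

model_cv = lp.cross_validate(syn.cohort, lp.ModelSpec(("hours", "lesions"), 2), plan)
null_cv = lp.cross_validate(syn.cohort, lp.ModelSpec(()), plan)
result = lp.paired_permutation_test(model_cv.mse, null_cv.mse,
                                    n_permutations=5000, seed=2)
```

prints

```
lesions+hours median MSE: 355.9 (IQR 89.9)
null          median MSE: 2503.5 (IQR 125.8)
model wins in 100% of repetitions
signed-rank W+ = 0, permutation p = 0.0002
```

and interpreting the fitted model (`examples/04_interpret_weights.py`) yields
negative influence weights on the planted harmful regions and a stability of

```
stability: minimum pairwise r over ten runs = 0.9986
```

The other scripts in `examples/` cover lesion encoding, the full
all-combinations model grid, and the proxy-region effect, each in a few
seconds.

## Layout

- `src/lesionpls/` — the library: `lesion_encoding`, `model_core`,
  `evaluation`, `comparison`, `interpretation`, `synthetic_data`,
  `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `scripts/acceptance.py` — recomputes the stability figure.
- `docs/methods.md` — models, assumptions, parameters, and design decisions.
- `tests/` — unit, property, and acceptance tests.
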