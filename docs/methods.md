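# Methods

This document records the models the package implements, the conventions and
numerical choices behind them, and the reasoning for the main design
decisions. Parameter defaults are listed with units where they have any.

## 1. Lesion-load encoding (`lesion_encoding`)

A patient's lesion is a binary 3-D mask; an atlas is an ordered set of
regions on the same voxel grid. The **lesion load** of region *R* for mask
*M* is

```
load(M, R) = |M ∩ R| / |R|
```

— the fraction of the region's voxels the lesion covers, in [0, 1].

Conventions:

- **Binarisation of probabilistic regions** uses an *inclusive* threshold
  (`probability ≥ threshold`, default 0.5), so a voxel with exactly 50%
  membership counts as part of the region. Input probabilities outside
  [0, 1] are rejected rather than clipped.
- **Empty regions** (no member voxels after binarisation) make the load
  undefined and raise an error rather than returning 0 or NaN.
- **Pruning** removes regions whose load is exactly zero for *every*
  patient — regions outside the lesion territory carry no information and
  would be degenerate predictors. Pruned region ids are recorded on the
  returned matrix, never silently discarded.
- **Overlapping regions are retained.** Multi-atlas encodings deliberately
  keep duplicated or overlapping parcels; collinearity between predictors is
  the PLS model's job, not the encoder's.
- All masks and regions must share a `space_tag` and grid shape; mismatches
  name the offending patient.

NIfTI input is read with `nibabel`; atlases are described by a TSV manifest
with columns `region_id`, `atlas_id`, `path`.

## 2. Models (`model_core`)

A `Cohort` holds aligned predictor blocks — canonical order `demographics`,
`initial`, `hours`, `behavioural`, `lesions` — and a response vector
(response scale: change in items named correctly). A `ModelSpec` names the
blocks a model uses; the empty spec is the **null model**, which predicts
every patient's response as the training group's mean.

Fitting conventions:

- **Standardisation**: predictors are z-scored using training-fold mean and
  *sample* standard deviation (ddof = 1). Columns with zero training sd are
  mapped to zero (they carry no information) rather than producing division
  errors; the same training statistics are applied to test rows. The
  response is centred internally by the PLS fit but never scaled, so losses
  stay on the response scale.
- **PLS regression** uses scikit-learn's `PLSRegression` (NIPALS) with
  `scale=False` (we standardise ourselves). Default **2 components**; when a
  spec requests more components than a design supports, the effective count
  is capped at `min(requested, p, n_train − 1)` — necessary because the grid
  includes single-predictor models (e.g. hours only) that cannot support two
  components. The low-level `fit_pls` is strict about bounds; only the
  cohort-level `fit_model` caps.
- With the number of components equal to the rank of the centred design, PLS
  coincides with ordinary least squares; this is the package's main internal
  correctness oracle for the fit.
- A constant training response yields a zero coefficient vector (PLS is
  undefined without response variance).
- Prediction from a DataFrame aligns columns *by name* and errors on
  missing or extra columns; positional arrays are accepted for internal use.

## 3. Evaluation (`evaluation`)

Repeated k-fold cross-validation, default **1000 repetitions × 10 folds**.

- A `FoldPlan` fixes the fold assignment of every patient for every
  repetition. Partitions are balanced (fold sizes differ by at most one; 18
  patients into 10 folds gives sizes {2×8, 1×2}) and are drawn once, then
  **shared by every model**, so per-repetition losses are paired and the
  signed-rank comparison below is valid.
- Per repetition, out-of-fold predictions are pooled across folds before
  computing the loss — one MSE per repetition (and its square root as RMSE),
  not a mean of per-fold losses. Pooling weighs every patient equally even
  when folds have unequal sizes.
- Summaries use median and interquartile range over repetitions, which are
  robust to the occasional catastrophic split inevitable with n = 18.
- The null model has a closed-form fast path (training-fold means), verified
  against the generic loop.

## 4. Model comparison (`comparison`)

Two models evaluated on the same plan yield paired per-repetition MSE
vectors `a` and `b`. The test statistic is the **Wilcoxon signed-rank W⁺**
of `a − b`: zero differences are dropped, ties receive mean ranks
(`scipy.stats.rankdata`), and W⁺ sums the ranks of positive differences.

Rather than using the asymptotic normal null (repetition losses from shared
data are not independent draws), the statistic is thresholded against a
**within-pair sign-flip permutation null**: each difference's sign is
flipped independently with probability ½. Two-sidedness is obtained by
centring — the reference statistic is `|W⁺ − m(m+1)/4|`, whose null
distribution is symmetric around zero by construction. The Monte-Carlo
p-value uses add-one smoothing, `p = (1 + #{null ≥ observed}) / (1 + B)`,
with default **B = 10,000** permutations (minimum 999 enforced); for m ≤ 24
an exact path enumerates all 2^m sign patterns. Degenerate comparisons
(all differences zero) report p = 1.

Familywise error over the model grid uses **Bonferroni** by default —
conservative but assumption-free and appropriate for 15 comparisons. A
max-statistic permutation adjustment (`method="maxstat"`), which exploits
the comparisons' shared null draws and is never more conservative than
Bonferroni, is available when tests are run with `keep_null=True`.

## 5. Interpretation (`interpretation`)

**Data-perturbation influence weights.** With the fitted model frozen, each
of `n_iterations` (default 1000) iterations independently selects each
variable with probability `inclusion_p` (default 0.5) and shuffles the
selected variables' values across patients; the model predicts from the
perturbed design. All `n_patients × n_iterations` rows are pooled, and each
variable's **weight** is the Pearson correlation between its (perturbed)
values and the predictions. Weights are signed, bounded in [−1, 1], and
reflect each variable's *marginal* association with the model output —
under strong collinearity a variable's weight can differ in sign from its
partial coefficient, which is exactly the phenomenon the proxy-region
analysis explains. Zero-variance variables get weight 0 with a warning.

**Stability check**: the whole procedure is repeated `n_runs` (default 10)
times with sub-seeds spawned from one seed via `numpy.random.SeedSequence`;
the summary is the minimum pairwise Pearson correlation among the weight
vectors. On default-scale problems this exceeds 0.99.

**Proxy-region analysis**: for a chosen region, correlate (i) the vector of
pairwise correlations between that region's load and every other region's
load with (ii) the other regions' influence weights. A high summary
correlation shows the region's weight is carried by lesion covariance —
damage there implies sparing of genuinely harmful regions — rather than by
a direct effect.

## 6. Synthetic cohorts (`synthetic_data`)

No patient data ship with the package, so all end-to-end claims are tested
on generated cohorts with known ground truth.

Generator defaults (all overridable on `GeneratorConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 18 | small-cohort regime the methods target |
| `grid_shape` | 20³ voxels | smallest grid with meaningful parcellation |
| `n_regions` | 40 | ~0.5× patients after pruning, strongly collinear |
| `territory_fraction` | 0.5 | lesions confined to one "hemisphere" |
| `blob_size_range` | 500–900 voxels | large territory lesions; small blobs leave rarely-hit regions whose near-zero training sd destabilises test-fold z-scores |
| `n_blobs_range` | 1–2 | mostly single contiguous lesions |
| `lesion_shape` | `"walk"` | stochastic Eden growth → irregular contiguous blobs |
| `harmful_zone_fraction` | 0.4 | cluster of negative-weight regions at low y |
| `harmful_weight` | −40 points | full damage costs ~40 response points, ±20% jitter |
| `hours_mean`, `hours_sd` | 73, 25 hours | realistic intensive-therapy dose, clipped at 1 |
| `beta_hours` | 0.4 points/hour | hours effect comparable to one harmful region |
| `response_intercept` | 65 points | mean response ≈ +40 items |
| `noise_sd` | `None` → 10% of the noiseless response's sd | high-signal regime for recovery tests |
| `n_behavioural` | 28 | collinear nuisance battery (noisy lesion mixtures) |

Structure: the atlas is a Voronoi partition of the grid (contiguous convex
cells); lesions are unions of growth blobs seeded in the territory, so
neighbouring regions' loads correlate positively and opposite ends of the
territory anticorrelate — the covariance that produces proxy-region
weights. Demographics are independent of the response (a designed negative
control); initial severity and the behavioural battery are noisy functions
of total/mixed lesion load (collinear with the lesion block but adding no
signal). The response is a planted linear model:

```
y = intercept + Σ_r w_r·load_r + β_h·hours (+ β_int·hours·lesion term) + ε
```

`proxy_generator_config` is a preset (60 regions, single 600–700-voxel
blobs, seeds concentrated near the territory's long axis) in which lesion
variation is dominated by one anterior–posterior gradient, yielding a
clean spared-region proxy; `select_proxy_target` picks the highest-weighted
region among those anticorrelated with harmful-zone load.

Known limitations, accepted deliberately: Voronoi cells are convex unlike
anatomical parcels; lesion growth is isotropic rather than vascular; blocks
other than lesions/hours carry no planted signal; responses are continuous
(item counts can be rounded via `round_response`). None of these affect the
statistical properties under test.

Seeding: every stage draws from `SeedSequence([config.seed, stage_index])`,
so regenerating any single stage is reproducible in isolation.

## 7. Pipeline (`pipeline`) and CLI

`run_grid` evaluates the null model plus all 15 non-empty combinations of
{demographics, initial, hours, lesions} (16 models) on one shared fold plan,
compares each with the null under FWE control, summarises the best
(lowest median MSE) model's mean out-of-fold predictions against the
empirical responses (Pearson r with a 2000-resample percentile bootstrap
CI), and computes the best model's influence weights. The grid table has 16
data rows — 17 CSV lines with the header.

A single `master_seed` is expanded via `SeedSequence.generate_state` into
named sub-seeds (generator, fold plan, comparisons, interpretation,
bootstrap), each masked to < 2³¹; reruns under the same master seed are
byte-identical, and `manifest.json` records the seeds plus a SHA-256 hash of
the run configuration.

The CLI (`lesionpls encode|simulate|grid|compare|interpret`) is a thin
wrapper: each subcommand maps onto one library call, with JSON files
overriding dataclass defaults field-by-field.

## 8. Numerical and testing choices

- Established libraries are used for standard primitives: scikit-learn for
  PLS, scipy for ranking and as a cross-check oracle for the signed-rank
  statistic, nibabel for NIfTI, pandas for tables. The signed-rank
  *permutation* machinery is implemented in-package because the sign-flip
  null on paired CV losses is the method itself.
- Permutation nulls are vectorised (rank vector × Bernoulli sign matrix), so
  calibration simulations with thousands of tests run in seconds.
- Tests are oracle-first: brute-force voxel counting, single-step NIPALS,
  `numpy.linalg.lstsq`, exhaustive 2^m sign-flip enumeration, and
  `scipy.stats.wilcoxon` are implemented independently of the library code
  they check. Property-based tests (hypothesis) are derandomised for
  reproducibility.
- "Above the noise floor" in the sign-recovery acceptance test means planted
  variables whose marginal correlation with the *noiseless* response is at
  least 0.3 in magnitude: influence weights measure marginal association, so
  under strong lesion collinearity only variables with a clear marginal
  signal have an identified sign.
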