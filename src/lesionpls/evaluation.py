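"""Repeated k-fold cross-validation with fold plans shared across models.

Because every model configuration is evaluated on literally the same fold
assignments, the per-repetition losses of two models form matched pairs and
can be compared with paired tests.  Each repetition partitions the cohort
into k near-equal folds; out-of-fold predictions are pooled over the k folds
before the squared error is averaged, giving one MSE (and RMSE) per
repetition.  All fitting — including standardisation statistics — is
confined to the training folds of each split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Cohort, ModelSpec, fit_model, fit_null, predict

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_fold_plan",
    "cross_validate",
    "repeated_oof_predictions",
]


@dataclass(frozen=True)
class FoldPlan:
    """R repetitions × n patients fold assignments, reproducible from a seed.

    ``assignments[r, i]`` is the fold index (0..k−1) of patient i in
    repetition r.  Within every repetition each patient is in exactly one
    fold and fold sizes differ by at most one.
    """

    n_patients: int
    k: int
    n_repetitions: int
    assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.shape != (self.n_repetitions, self.n_patients):
            raise ValueError("assignments shape mismatch")
        object.__setattr__(self, "assignments", a)

    def permute_patients(self, perm: np.ndarray) -> "FoldPlan":
        """The same plan after relabelling patients by ``perm`` (new[i] = old[perm[i]])."""
        return FoldPlan(
            self.n_patients, self.k, self.n_repetitions,
            self.assignments[:, np.asarray(perm)], self.seed,
        )


@dataclass(frozen=True)
class CVResult:
    """Per-repetition cross-validated loss for one model configuration."""

    label: str
    mse: np.ndarray
    rmse: np.ndarray
    plan_seed: int

    @property
    def median_mse(self) -> float:
        return float(np.median(self.mse))

    @property
    def iqr_mse(self) -> float:
        q1, q3 = np.percentile(self.mse, [25, 75])
        return float(q3 - q1)

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse))

    @property
    def iqr_rmse(self) -> float:
        q1, q3 = np.percentile(self.rmse, [25, 75])
        return float(q3 - q1)


def make_fold_plan(n_patients: int, k: int = 10, n_repetitions: int = 1000,
                   seed: int = 0) -> FoldPlan:
    """Draw R independent balanced k-fold partitions of the cohort.

    With n = 18 and k = 10 every repetition has eight folds of two patients
    and two folds of one.  Deterministic given the seed.
    """
    if k > n_patients:
        raise ValueError(f"k={k} exceeds n_patients={n_patients}")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    # fold sizes differing by at most one, larger folds first
    base, extra = divmod(n_patients, k)
    sizes = np.full(k, base)
    sizes[:extra] += 1
    fold_of_position = np.repeat(np.arange(k), sizes)
    assignments = np.empty((n_repetitions, n_patients), dtype=np.int64)
    for r in range(n_repetitions):
        perm = rng.permutation(n_patients)
        assignments[r, perm] = fold_of_position
    return FoldPlan(n_patients, k, n_repetitions, assignments, seed)


def cross_validate(cohort: Cohort, spec: ModelSpec, plan: FoldPlan) -> CVResult:
    """Evaluate one model spec over every repetition of a shared fold plan.

    For each repetition, out-of-fold predictions from the k train/test splits
    are pooled into one length-n vector, then scored against the response as
    a single mean squared error.
    """
    if plan.n_patients != cohort.n_patients:
        raise ValueError("fold plan and cohort disagree on n_patients")
    y = cohort.response
    n = cohort.n_patients

    if spec.is_null:
        # closed form: the test-fold prediction is the training-fold mean
        mse = np.empty(plan.n_repetitions)
        total = y.sum()
        for r in range(plan.n_repetitions):
            folds = plan.assignments[r]
            preds = np.empty(n)
            for f in range(plan.k):
                test = folds == f
                n_test = test.sum()
                preds[test] = (total - y[test].sum()) / (n - n_test)
            mse[r] = np.mean((preds - y) ** 2)
        return CVResult(spec.label, mse, np.sqrt(mse), plan.seed)

    design = cohort.design(spec.block_names)
    X = design.to_numpy(float)
    mse = np.empty(plan.n_repetitions)
    for r in range(plan.n_repetitions):
        folds = plan.assignments[r]
        preds = np.empty(n)
        for f in range(plan.k):
            test = folds == f
            train_idx = np.flatnonzero(~test)
            model = fit_model(cohort, spec, train_idx)
            preds[test] = predict(model, X[test])
        mse[r] = np.mean((preds - y) ** 2)
    return CVResult(spec.label, mse, np.sqrt(mse), plan.seed)


def repeated_oof_predictions(cohort: Cohort, spec: ModelSpec, plan: FoldPlan) -> np.ndarray:
    """Out-of-fold predictions for every repetition (R × n matrix).

    Row r holds the pooled out-of-fold predictions of repetition r; the mean
    over rows is the per-patient predicted response used for the
    predicted-vs-empirical summary.
    """
    n = cohort.n_patients
    preds = np.empty((plan.n_repetitions, n))
    if spec.is_null:
        y = cohort.response
        total = y.sum()
        for r in range(plan.n_repetitions):
            folds = plan.assignments[r]
            for f in range(plan.k):
                test = folds == f
                preds[r, test] = (total - y[test].sum()) / (n - test.sum())
        return preds
    design = cohort.design(spec.block_names)
    X = design.to_numpy(float)
    for r in range(plan.n_repetitions):
        folds = plan.assignments[r]
        for f in range(plan.k):
            test = folds == f
            model = fit_model(cohort, spec, np.flatnonzero(~test))
            preds[r, test] = predict(model, X[test])
    return preds
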