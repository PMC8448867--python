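"""PLS prognostic models over configurable predictor blocks, plus the group-mean null.

A cohort carries named predictor blocks (demographics, initial severity,
therapy hours, optional behavioural battery, lesion loads) and one response
(change in trained-item naming accuracy).  A model specification selects a
subset of blocks; predictors are z-scored with training-set statistics only
(sample sd, n−1 denominator; constant columns map to zero so they cannot
influence predictions), and a partial-least-squares regression with a small
number of latent components is fitted on the standardised design.  The null
model ignores all predictors and predicts the training group's mean response.

The fitted object stores the model as one affine map in raw-predictor space,
so prediction is deterministic, cheap and independent of how the fit was
obtained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "Cohort",
    "ModelSpec",
    "FittedModel",
    "standardize",
    "fit_pls",
    "fit_null",
    "fit_model",
    "predict",
]

# canonical block order; blocks are assembled in this order regardless of
# the order the spec lists them, so a model's design matrix is reproducible
BLOCK_ORDER = ("demographics", "initial", "hours", "behavioural", "lesions")


@dataclass(frozen=True)
class Cohort:
    """Aligned predictor blocks and response for one patient cohort.

    Every block is a DataFrame with one row per patient, in the same order as
    ``patient_ids``; the response is the change in trained-item naming
    accuracy (may be negative).  Missing values are rejected.
    """

    patient_ids: tuple[str, ...]
    blocks: Mapping[str, pd.DataFrame]
    response: np.ndarray

    def __post_init__(self) -> None:
        pids = tuple(str(p) for p in self.patient_ids)
        y = np.asarray(self.response, dtype=float)
        n = len(pids)
        if y.shape != (n,):
            raise ValueError(f"response length {y.shape} does not match {n} patients")
        if np.isnan(y).any():
            raise ValueError("response contains missing values")
        blocks = dict(self.blocks)
        for name, df in blocks.items():
            if len(df) != n:
                raise ValueError(f"block {name!r} has {len(df)} rows, expected {n}")
            if df.isna().any().any():
                raise ValueError(f"block {name!r} contains missing values")
        object.__setattr__(self, "patient_ids", pids)
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "response", y)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def design(self, block_names: Sequence[str]) -> pd.DataFrame:
        """Horizontal concatenation of the named blocks, in canonical order."""
        missing = [b for b in block_names if b not in self.blocks]
        if missing:
            raise KeyError(f"cohort has no block(s) {missing}; available: {sorted(self.blocks)}")
        ordered = [b for b in BLOCK_ORDER if b in block_names]
        ordered += [b for b in block_names if b not in BLOCK_ORDER]
        parts = [self.blocks[b] for b in ordered]
        out = pd.concat(parts, axis=1)
        if out.columns.duplicated().any():
            raise ValueError("duplicate column names across selected blocks")
        return out

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset (or reorder) the cohort by positional index."""
        idx = np.asarray(idx)
        return Cohort(
            patient_ids=tuple(np.asarray(self.patient_ids, dtype=object)[idx]),
            blocks={k: v.iloc[idx].reset_index(drop=True) for k, v in self.blocks.items()},
            response=self.response[idx],
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which predictor blocks a model uses, and how many PLS components.

    An empty ``block_names`` denotes the null (group-mean) model.
    """

    block_names: tuple[str, ...] = ()
    n_components: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_names", tuple(self.block_names))
        if self.block_names and self.n_components < 1:
            raise ValueError("n_components must be ≥ 1 for PLS specs")

    @property
    def is_null(self) -> bool:
        return not self.block_names

    @property
    def label(self) -> str:
        if self.is_null:
            return "null"
        ordered = [b for b in BLOCK_ORDER if b in self.block_names]
        ordered += [b for b in self.block_names if b not in BLOCK_ORDER]
        return "+".join(ordered)


@dataclass(frozen=True)
class FittedModel:
    """A fitted model as a single affine map on raw predictors.

    prediction = ((x − mean) / sd) · coef + intercept, with sd = 0 columns
    contributing zero.  For the null model the coefficient vector is empty
    and the intercept is the training mean response.
    """

    spec: ModelSpec
    column_names: tuple[str, ...]
    train_mean: np.ndarray
    train_sd: np.ndarray
    coef: np.ndarray
    intercept: float
    training_patient_ids: tuple[str, ...]
    fitted_values: np.ndarray = field(repr=False, default=None)


def standardize(train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None):
    """Column-wise z-scoring with training statistics (sample sd, ddof=1).

    Returns ``(standardised apply_matrix, train_mean, train_sd)``; columns
    whose training sd is zero are mapped to zero everywhere.  When
    ``apply_matrix`` is omitted the training matrix is transformed.
    """
    train = np.asarray(train_matrix, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train_matrix must be 2-D with at least 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    target = train if apply_matrix is None else np.asarray(apply_matrix, dtype=float)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (target - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return z, mean, sd


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int):
    """Fit PLS regression on (already standardised) predictors.

    Returns ``(coef, intercept)`` such that prediction = X·coef + intercept;
    the response is centred internally but not scaled.  With n_components
    equal to the rank of the centred design this reduces to ordinary least
    squares.  A constant response yields a zero coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("X and y have incompatible shapes")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} must satisfy 1 ≤ c ≤ min(n_train−1={n-1}, p={p})"
        )
    if np.ptp(y) == 0:
        return np.zeros(p), float(y[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when components exhaust y variance
        pls = PLSRegression(n_components=n_components, scale=False).fit(X, y)
    coef = np.asarray(pls.coef_, dtype=float).reshape(-1)
    # sklearn's intercept_ applies to mean-centred predictors; fold the
    # centring in so that prediction = X·coef + intercept holds as documented
    intercept = float(np.asarray(pls.intercept_).reshape(-1)[0] - X.mean(axis=0) @ coef)
    return coef, intercept


def fit_null(y_train: np.ndarray) -> FittedModel:
    """The empty model: predicts the training group's mean response for everyone."""
    y = np.asarray(y_train, dtype=float)
    if y.size == 0:
        raise ValueError("y_train is empty")
    mean = float(y.mean())
    return FittedModel(
        spec=ModelSpec(()),
        column_names=(),
        train_mean=np.zeros(0),
        train_sd=np.zeros(0),
        coef=np.zeros(0),
        intercept=mean,
        training_patient_ids=(),
        fitted_values=np.full(y.shape, mean),
    )


def fit_model(cohort: Cohort, spec: ModelSpec,
              train_idx: np.ndarray | None = None) -> FittedModel:
    """Fit a spec on (a training subset of) a cohort.

    Standardisation statistics and all fitting use training rows only.
    """
    if train_idx is None:
        train_idx = np.arange(cohort.n_patients)
    train_idx = np.asarray(train_idx)
    y = cohort.response[train_idx]
    pids = tuple(np.asarray(cohort.patient_ids, dtype=object)[train_idx])

    if spec.is_null:
        model = fit_null(y)
        return FittedModel(
            spec=spec, column_names=(), train_mean=model.train_mean,
            train_sd=model.train_sd, coef=model.coef, intercept=model.intercept,
            training_patient_ids=pids, fitted_values=model.fitted_values,
        )

    design = cohort.design(spec.block_names)
    X_train = design.to_numpy(float)[train_idx]
    Z, mean, sd = standardize(X_train)
    # a 1-predictor model cannot carry 2 latent components; cap at the
    # mathematical maximum rather than rejecting the spec
    n_components = min(spec.n_components, Z.shape[1], Z.shape[0] - 1)
    coef, intercept = fit_pls(Z, y, n_components)
    fitted = Z @ coef + intercept
    return FittedModel(
        spec=spec,
        column_names=tuple(design.columns),
        train_mean=mean,
        train_sd=sd,
        coef=coef,
        intercept=intercept,
        training_patient_ids=pids,
        fitted_values=fitted,
    )


def predict(model: FittedModel, X_new: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Apply a fitted model to new patients.

    A DataFrame is aligned to the model's column set by name (order-free);
    missing or extra columns raise.  A bare array must already be in the
    model's column order.
    """
    if model.spec.is_null or not model.column_names:
        n = len(X_new)
        return np.full(n, model.intercept)
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.column_names if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in model.column_names]
        if missing or extra:
            raise ValueError(f"column mismatch: missing {missing}, extra {extra}")
        X = X_new.loc[:, list(model.column_names)].to_numpy(float)
    else:
        X = np.asarray(X_new, dtype=float)
        if X.shape[1] != len(model.column_names):
            raise ValueError(
                f"expected {len(model.column_names)} columns, got {X.shape[1]}"
            )
    safe_sd = np.where(model.train_sd == 0, 1.0, model.train_sd)
    Z = (X - model.train_mean) / safe_sd
    Z[:, model.train_sd == 0] = 0.0
    return Z @ model.coef + model.intercept
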