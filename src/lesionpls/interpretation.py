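"""Data-perturbation interpretation of fitted models, and the proxy-region analysis.

PLS component weights are hard to read directly (signs of components are
arbitrary and several components superpose), so a fitted model is interpreted
by perturbing its inputs instead: on each iteration a random subset of
predictor variables is selected (each independently with probability ½) and
each selected variable's values are shuffled across patients, the frozen
model predicts the perturbed cohort, and all patients × iterations rows are
pooled.  The influence weight of a variable is the Pearson correlation, over
that pooled sample, between its (perturbed) values and the model's
predictions.  Weights live in [−1, 1]; a variable the model ignores gets a
weight near zero.

Because lesions are spatially contiguous, loads of nearby regions are highly
correlated and a model may assign a *positive* weight to a region whose
damage merely proxies sparing of genuinely harmful regions.  The
proxy-region analysis quantifies this: it correlates a target region's load
with every other region's load, then correlates that profile with the
perturbation weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .lesion_encoding import LesionLoadMatrix
from .model_core import FittedModel, predict

__all__ = [
    "InfluenceWeights",
    "ProxyRegionResult",
    "perturb_and_weigh",
    "stability_check",
    "proxy_region_analysis",
    "weight_report",
]


@dataclass(frozen=True)
class InfluenceWeights:
    """Per-variable perturbation-derived influence weights of one fitted model."""

    variable_ids: tuple[str, ...]
    weights: np.ndarray
    n_iterations: int
    inclusion_p: float
    seed: int | None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.variable_ids),):
            raise ValueError("weights length must equal variable count")
        if w.size and np.nanmax(np.abs(w)) > 1 + 1e-12:
            raise ValueError("correlation weights must lie in [−1, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.variable_ids), name="weight")


@dataclass(frozen=True)
class ProxyRegionResult:
    """Pairwise load correlations of a target region, and their match to model weights."""

    target_region: str
    other_region_ids: tuple[str, ...]
    load_correlations: np.ndarray
    summary_correlation: float


def _pooled_columnwise_pearson(X: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Pearson r between each column of X and yhat; zero-variance columns → 0 + warning."""
    Xc = X - X.mean(axis=0)
    yc = yhat - yhat.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    bad = sx == 0
    if sy == 0:
        warnings.warn("predictions have zero variance; all weights set to 0")
        return np.zeros(X.shape[1])
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pooled column(s) have zero variance; weights set to 0")
    r = np.zeros(X.shape[1])
    ok = ~bad
    r[ok] = (Xc[:, ok] * yc[:, None]).sum(axis=0) / (sx[ok] * sy)
    return np.clip(r, -1.0, 1.0)


def perturb_and_weigh(
    model: FittedModel,
    X: pd.DataFrame,
    n_iterations: int = 1000,
    inclusion_p: float = 0.5,
    seed: int | None = 0,
    perturbation: str = "shuffle",
    correlation: str = "pearson",
) -> InfluenceWeights:
    """Influence weights of a frozen model via data perturbation.

    Per iteration, each variable is independently selected with probability
    ``inclusion_p``; selected variables are shuffled across patients
    (``perturbation="shuffle"``, preserving marginals) or resampled with
    replacement (``"resample"``); unselected variables keep their empirical
    values.  The frozen model predicts each perturbed design, all
    n_patients × n_iterations rows are pooled, and each variable's weight is
    the pooled correlation between its values and the predictions
    (Pearson by default, Spearman via ``correlation="spearman"``).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be ≥ 1")
    if not 0 < inclusion_p <= 1:
        raise ValueError("inclusion_p must lie in (0, 1]")
    if perturbation not in ("shuffle", "resample"):
        raise ValueError(f"unknown perturbation {perturbation!r}")
    cols = list(model.column_names)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"X lacks model columns {missing}")
    base = X.loc[:, cols].to_numpy(float)
    n, p = base.shape
    rng = np.random.default_rng(seed)

    pooled_X = np.empty((n_iterations * n, p))
    pooled_pred = np.empty(n_iterations * n)
    for it in range(n_iterations):
        Xp = base.copy()
        selected = rng.random(p) < inclusion_p
        for j in np.flatnonzero(selected):
            if perturbation == "shuffle":
                Xp[:, j] = base[rng.permutation(n), j]
            else:
                Xp[:, j] = base[rng.integers(0, n, size=n), j]
        sl = slice(it * n, (it + 1) * n)
        pooled_X[sl] = Xp
        pooled_pred[sl] = predict(model, Xp)

    if correlation == "spearman":
        pooled_X = np.apply_along_axis(rankdata, 0, pooled_X)
        pooled_pred = rankdata(pooled_pred)
    elif correlation != "pearson":
        raise ValueError(f"unknown correlation {correlation!r}")
    weights = _pooled_columnwise_pearson(pooled_X, pooled_pred)
    return InfluenceWeights(tuple(cols), weights, n_iterations, inclusion_p, seed)


def stability_check(
    model: FittedModel,
    X: pd.DataFrame,
    n_runs: int = 10,
    n_iterations: int = 1000,
    seed: int | None = 0,
    **kwargs,
) -> tuple[float, np.ndarray]:
    """Minimum pairwise Pearson correlation between independent weight vectors.

    Runs :func:`perturb_and_weigh` ``n_runs`` times with independent
    sub-seeds spawned from ``seed`` and returns ``(min pairwise r, the full
    n_runs × n_runs correlation matrix)``.  High values mean the chosen
    iteration count suffices for stable interpretation.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be ≥ 2")
    sub_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    vectors = [
        perturb_and_weigh(model, X, n_iterations=n_iterations,
                          seed=np.random.default_rng(s), **kwargs).weights
        for s in sub_seeds
    ]
    W = np.vstack(vectors)
    C = np.corrcoef(W)
    min_r = min(C[i, j] for i, j in combinations(range(n_runs), 2))
    return float(min_r), C


def proxy_region_analysis(
    loads: LesionLoadMatrix,
    target_region: str,
    weights: InfluenceWeights,
) -> ProxyRegionResult:
    """How well a region's lesion-load correlations explain the model's weights.

    Computes the Pearson correlation between the target region's load column
    and every other region's column (the target itself is excluded), then the
    Pearson correlation between that profile and the corresponding influence
    weights.  A high summary correlation indicates the target region's weight
    is driven by the cohort's lesion covariance (a proxy effect) rather than
    by the region itself.
    """
    region_ids = list(loads.region_ids)
    if target_region not in region_ids:
        raise ValueError(f"target region {target_region!r} not in lesion-load matrix")
    weight_map = dict(zip(weights.variable_ids, weights.weights))
    others = [r for r in region_ids if r != target_region]
    missing = [r for r in others if r not in weight_map]
    if missing:
        raise ValueError(f"influence weights lack region(s) {missing[:5]}")
    V = loads.values
    t = V[:, region_ids.index(target_region)]
    if np.std(t) == 0:
        raise ValueError(f"target region {target_region!r} has zero load variance")
    corrs = np.empty(len(others))
    for i, r in enumerate(others):
        col = V[:, region_ids.index(r)]
        if np.std(col) == 0:
            corrs[i] = 0.0
        else:
            corrs[i] = np.corrcoef(t, col)[0, 1]
    w = np.array([weight_map[r] for r in others])
    summary = float(np.corrcoef(corrs, w)[0, 1])
    return ProxyRegionResult(target_region, tuple(others), corrs, summary)


def weight_report(
    weights: InfluenceWeights,
    manifest: pd.DataFrame | None = None,
    by_magnitude: bool = False,
) -> pd.DataFrame:
    """Ranked table of influence weights, optionally joined with atlas provenance.

    Sorted by signed weight descending by default; ``by_magnitude`` sorts by
    |weight| instead.  ``manifest`` may carry region_id/atlas_id columns as
    produced by :func:`lesionpls.lesion_encoding.region_manifest_table`.
    """
    df = pd.DataFrame({
        "variable_id": list(weights.variable_ids),
        "weight": weights.weights,
    })
    if manifest is not None and len(df):
        df = df.merge(
            manifest.rename(columns={"region_id": "variable_id"}),
            on="variable_id", how="left",
        )
    if len(df):
        key = df["weight"].abs() if by_magnitude else df["weight"]
        df = df.loc[key.sort_values(ascending=False, kind="mergesort").index]
    return df.reset_index(drop=True)
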