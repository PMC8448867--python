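"""End-to-end orchestration: the all-combinations model grid on one shared fold plan.

Runs every configured predictor-block combination (by default all 15
non-empty subsets of demographics / initial severity / therapy hours /
lesion loads) plus the group-mean null model through repeated k-fold
cross-validation on a single shared fold plan, compares every model with the
null via the permutation-thresholded signed-rank test under FWE control,
summarises the best model's predictions against the empirical responses
(Pearson r with a bootstrap CI), and derives its data-perturbation influence
weights.  One master seed makes the whole run bit-for-bit reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import ComparisonResult, fwe_adjust, paired_permutation_test
from .evaluation import cross_validate, make_fold_plan, repeated_oof_predictions
from .model_core import Cohort, ModelSpec, fit_model
from .interpretation import perturb_and_weigh
from .synthetic_data import GeneratorConfig, make_cohort

__all__ = ["RunConfig", "GridReport", "run_grid", "default_block_combinations"]

GRID_BLOCKS = ("demographics", "initial", "hours", "lesions")


def default_block_combinations() -> list[tuple[str, ...]]:
    """All 15 non-empty subsets of the four standard predictor blocks."""
    combos: list[tuple[str, ...]] = []
    for size in range(1, len(GRID_BLOCKS) + 1):
        combos.extend(combinations(GRID_BLOCKS, size))
    return combos


@dataclass(frozen=True)
class RunConfig:
    """Everything one grid run needs, including the master seed.

    Either supply a ``generator`` config (a synthetic cohort is drawn from
    the master seed) or pass a ready-made cohort to :func:`run_grid`.
    """

    generator: GeneratorConfig | None = None
    block_combinations: tuple[tuple[str, ...], ...] = tuple(default_block_combinations())
    k: int = 10
    n_repetitions: int = 1000
    n_components: int = 2
    n_permutations: int = 10_000
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    interpretation_iterations: int = 1000
    inclusion_p: float = 0.5
    bootstrap_resamples: int = 2000
    master_seed: int = 0

    def spawn_seeds(self) -> dict[str, int]:
        """Named integer sub-seeds derived from the master seed (all < 2³¹)."""
        state = np.random.SeedSequence(self.master_seed).generate_state(5)
        names = ("generator", "fold_plan", "comparisons", "interpretation", "bootstrap")
        return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


@dataclass(frozen=True)
class GridReport:
    """Tables and summaries from one grid run."""

    grid: pd.DataFrame
    comparisons: tuple[ComparisonResult, ...]
    comparisons_table: pd.DataFrame
    best_label: str
    predictions: pd.DataFrame
    predicted_vs_empirical_r: float
    predicted_vs_empirical_ci: tuple[float, float]
    best_weights: pd.DataFrame
    manifest: dict


def _bootstrap_correlation_ci(x: np.ndarray, y: np.ndarray, n_resamples: int,
                              seed: int, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for Pearson r of paired observations."""
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            rs[b] = np.nan
        else:
            rs[b] = np.corrcoef(xb, yb)[0, 1]
    rs = rs[~np.isnan(rs)]
    lo, hi = np.percentile(rs, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def run_grid(config: RunConfig, cohort: Cohort | None = None,
             out_dir: str | Path | None = None) -> GridReport:
    """Run the full model grid and, optionally, write its CSV/JSON artifacts.

    Artifacts (when ``out_dir`` is given): ``grid.csv`` (one row per model,
    null first, with median/IQR of MSE and RMSE), ``comparisons.csv`` (each
    model vs null), ``predictions.csv`` (the best model's mean out-of-fold
    prediction per patient alongside the empirical response),
    ``weights.csv`` (the best model's influence weights) and
    ``manifest.json`` (seeds, config hash, package version).
    """
    seeds = config.spawn_seeds()
    if cohort is None:
        gen = config.generator or GeneratorConfig()
        gen = replace(gen, seed=seeds["generator"])
        cohort = make_cohort(gen).cohort

    for combo in config.block_combinations:
        missing = [b for b in combo if b not in cohort.blocks]
        if missing:
            raise ValueError(f"configured blocks {missing} absent from cohort")

    plan = make_fold_plan(cohort.n_patients, config.k, config.n_repetitions,
                          seed=seeds["fold_plan"])

    specs = [ModelSpec(())] + [
        ModelSpec(c, n_components=config.n_components) for c in config.block_combinations
    ]
    try:
        results = {s.label: cross_validate(cohort, s, plan) for s in specs}
    except Exception as err:  # pragma: no cover - stage labelling only
        raise RuntimeError(f"grid stage 'cross-validation' failed: {err}") from err

    grid_rows = []
    for s in specs:
        r = results[s.label]
        grid_rows.append({
            "model": s.label,
            "median_mse": r.median_mse,
            "iqr_mse": r.iqr_mse,
            "median_rmse": r.median_rmse,
            "iqr_rmse": r.iqr_rmse,
        })
    grid = pd.DataFrame(grid_rows)

    null_mse = results["null"].mse
    comp_rng = np.random.SeedSequence(seeds["comparisons"])
    raw_comparisons = []
    for s, sub in zip(specs[1:], comp_rng.spawn(len(specs) - 1)):
        raw_comparisons.append(paired_permutation_test(
            results[s.label].mse, null_mse,
            n_permutations=config.n_permutations,
            seed=np.random.default_rng(sub),
            label_a=s.label, label_b="null",
            keep_null=(config.fwe_method == "maxstat"),
        ))
    comparisons = fwe_adjust(raw_comparisons, alpha=config.alpha, method=config.fwe_method)
    comparisons_table = pd.DataFrame([
        {
            "model": c.label_a,
            "vs": c.label_b,
            "signed_rank_statistic": c.statistic,
            "p_permutation": c.p_value,
            "p_fwe_adjusted": c.p_adjusted,
            "significant": c.significant,
            "median_mse": results[c.label_a].median_mse,
            "better_than_null": results[c.label_a].median_mse < results["null"].median_mse,
        }
        for c in comparisons
    ])

    non_null = grid[grid["model"] != "null"]
    best_label = str(non_null.sort_values("median_mse", kind="mergesort").iloc[0]["model"])
    best_spec = next(s for s in specs if s.label == best_label)

    oof = repeated_oof_predictions(cohort, best_spec, plan)
    mean_pred = oof.mean(axis=0)
    y = cohort.response
    r = float(np.corrcoef(mean_pred, y)[0, 1])
    ci = _bootstrap_correlation_ci(mean_pred, y, config.bootstrap_resamples,
                                   seed=seeds["bootstrap"])
    predictions = pd.DataFrame({
        "patient_id": list(cohort.patient_ids),
        "empirical_response": y,
        "predicted_response": mean_pred,
    })

    best_model = fit_model(cohort, best_spec)
    weights = perturb_and_weigh(
        best_model, cohort.design(best_spec.block_names),
        n_iterations=config.interpretation_iterations,
        inclusion_p=config.inclusion_p,
        seed=seeds["interpretation"],
    )
    best_weights = pd.DataFrame({
        "variable_id": list(weights.variable_ids),
        "weight": weights.weights,
    })

    cfg_repr = json.dumps(
        {
            "block_combinations": [list(c) for c in config.block_combinations],
            "k": config.k, "n_repetitions": config.n_repetitions,
            "n_components": config.n_components,
            "n_permutations": config.n_permutations, "alpha": config.alpha,
            "fwe_method": config.fwe_method,
            "interpretation_iterations": config.interpretation_iterations,
            "inclusion_p": config.inclusion_p,
            "bootstrap_resamples": config.bootstrap_resamples,
        },
        sort_keys=True,
    )
    from . import __version__

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "derived_seeds": seeds,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "n_patients": cohort.n_patients,
        "n_models": len(specs),
        "best_model": best_label,
        "predicted_vs_empirical_r": r,
        "predicted_vs_empirical_ci95": list(ci),
    }

    report = GridReport(
        grid=grid,
        comparisons=tuple(comparisons),
        comparisons_table=comparisons_table,
        best_label=best_label,
        predictions=predictions,
        predicted_vs_empirical_r=r,
        predicted_vs_empirical_ci=ci,
        best_weights=best_weights,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out / "grid.csv", index=False)
        comparisons_table.to_csv(out / "comparisons.csv", index=False)
        predictions.to_csv(out / "predictions.csv", index=False)
        best_weights.to_csv(out / "weights.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
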