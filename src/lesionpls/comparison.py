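"""Paired model comparison: Wilcoxon signed-rank thresholded by a sign-flip permutation null.

The per-repetition losses of two models evaluated on identical fold plans are
matched pairs, but repetitions share overlapping training sets, so the
signed-rank test's nominal null distribution is not trustworthy.  Instead the
observed signed-rank statistic is referred to a permutation null built by
randomly swapping the two models' labels within each pair (equivalently,
flipping the sign of each paired difference with probability ½) and
recomputing the statistic.  Familywise error over a grid of comparisons is
controlled by Bonferroni (default) or a max-statistic permutation adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ComparisonResult",
    "signed_rank_statistic",
    "paired_permutation_test",
    "fwe_adjust",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one paired permutation-thresholded signed-rank comparison.

    ``statistic`` is W⁺ (sum of ranks of positive differences a−b after
    dropping zeros); ``centered_statistic`` is |W⁺ − m(m+1)/4|, the two-sided
    quantity actually referred to the permutation null.  ``significant`` is
    populated by :func:`fwe_adjust`.
    """

    label_a: str
    label_b: str
    statistic: float
    centered_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    degenerate: bool = False
    p_adjusted: float | None = None
    significant: bool | None = None
    null_statistics: np.ndarray | None = None


def signed_rank_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Wilcoxon signed-rank statistic W⁺ for paired vectors.

    Zero differences are dropped before ranking (Wilcoxon's convention);
    tied absolute differences receive mean ranks.  Returns ``(W⁺,
    degenerate)`` where degenerate means every difference was zero (W⁺
    defined as 0, the comparison carries no evidence).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D with equal lengths")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, True
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), False


def _centered(w_plus: float, m: int) -> float:
    """Two-sided statistic: distance of W⁺ from its null mean m(m+1)/4."""
    return abs(w_plus - m * (m + 1) / 4.0)


def paired_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    label_a: str = "a",
    label_b: str = "b",
    exact: bool = False,
    keep_null: bool = False,
) -> ComparisonResult:
    """Within-pair label-permutation test of the signed-rank statistic.

    Swapping the model labels of pair i flips the sign of its difference, so
    the null is built by sign-flipping each nonzero difference independently
    with probability ½ and recomputing W⁺; the two-sided p-value uses the
    centred magnitude |W⁺ − m(m+1)/4| and the add-one rule
    p = (1 + #{null ≥ observed}) / (1 + B), which bounds p below by 1/(B+1).

    With ``exact=True`` all 2^m sign patterns are enumerated instead
    (feasible for m ≤ ~20) and p = #{null ≥ observed}/2^m.  ``keep_null``
    retains the null centred statistics for max-statistic FWE adjustment.
    """
    if not exact and n_permutations < 999:
        raise ValueError("use at least 999 permutations")
    w_obs, degenerate = signed_rank_statistic(a, b)
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    m = d.size
    if degenerate:
        return ComparisonResult(label_a, label_b, 0.0, 0.0, 1.0,
                                n_permutations, seed, degenerate=True,
                                null_statistics=np.zeros(0) if keep_null else None)
    ranks = rankdata(np.abs(d))
    t_obs = _centered(w_obs, m)

    if exact:
        if m > 24:
            raise ValueError(f"exact enumeration infeasible for m={m} nonzero pairs")
        # W⁺ under each sign pattern = sum of ranks of positions flipped positive
        signs = ((np.arange(2 ** m)[:, None] >> np.arange(m)[None, :]) & 1).astype(float)
        w_null = signs @ ranks
        t_null = np.abs(w_null - m * (m + 1) / 4.0)
        p = float(np.count_nonzero(t_null >= t_obs - 1e-12) / len(t_null))
        n_used = len(t_null)
    else:
        rng = np.random.default_rng(seed)
        # positives under a flip pattern: original sign XOR flip; W⁺ is a
        # Bernoulli(½)-weighted sum of the fixed ranks
        keep = rng.integers(0, 2, size=(n_permutations, m)).astype(float)
        w_null = keep @ ranks
        t_null = np.abs(w_null - m * (m + 1) / 4.0)
        p = float((1 + np.count_nonzero(t_null >= t_obs - 1e-12)) / (1 + n_permutations))
        n_used = n_permutations

    return ComparisonResult(
        label_a, label_b, w_obs, t_obs, p, n_used, seed,
        null_statistics=t_null if keep_null else None,
    )


def fwe_adjust(
    results: Sequence[ComparisonResult],
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> list[ComparisonResult]:
    """Familywise-error adjustment over a family of comparisons.

    ``bonferroni`` multiplies each p-value by the family size (capped at 1).
    ``maxstat`` compares each observed centred statistic with the permutation
    distribution of the familywise maximum centred statistic; it requires
    every result to carry ``null_statistics`` of equal length (same
    permutation count, ideally a shared seed so flips are synchronised).
    """
    results = list(results)
    if not results:
        return []
    if method == "bonferroni":
        k = len(results)
        out = []
        for r in results:
            p_adj = min(1.0, r.p_value * k)
            out.append(replace(r, p_adjusted=p_adj, significant=bool(p_adj < alpha)))
        return out
    if method == "maxstat":
        nulls = [r.null_statistics for r in results]
        if any(x is None for x in nulls):
            raise ValueError("maxstat needs results built with keep_null=True")
        lengths = {len(x) for x in nulls}
        if len(lengths) != 1:
            raise ValueError("maxstat needs equal permutation counts across the family")
        max_null = np.max(np.vstack(nulls), axis=0)
        B = len(max_null)
        out = []
        for r in results:
            p_adj = float((1 + np.count_nonzero(max_null >= r.centered_statistic - 1e-12)) / (1 + B))
            out.append(replace(r, p_adjusted=p_adj, significant=bool(p_adj < alpha)))
        return out
    raise ValueError(f"unknown FWE method {method!r}")
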