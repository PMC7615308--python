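"""Group-level comparisons of per-cell isoform readouts.

Covers the three comparative questions the quantifiers feed into:

* fold change of mean per-cell -KTS units between two genotypes, with a
  percentile bootstrap CI (e.g. transcriptional compensation doubling -KTS
  output in the +KTS knockout);
* a permutation test on any per-cell readout (mean-difference statistic,
  two-sided, add-one-corrected p so p is never 0);
* a dose-ordered trend statistic across an allelic series (pairwise
  concordances minus discordances between dose-ordered groups, a
  Jonckheere-Terpstra-style statistic), with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GroupComparisonResult:
    """Fold change of group means (B over A) with bootstrap CI and
    permutation p; ``defined`` is False when the denominator mean is 0."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    fold_change: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    n_perm: int
    seed: int
    defined: bool = True


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_perm: int
    exhaustive: bool


@dataclass(frozen=True)
class TrendResult:
    """Dose-ordered trend across >= 2 groups; ``statistic`` is the sum over
    dose-ordered group pairs of concordant minus discordant value pairs."""

    statistic: float
    p_value: float
    dose_levels: tuple
    n_perm: int
    seed: int


def _as_values(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError(f"group {name!r} is empty")
    return v


def fold_change(
    values_a,
    values_b,
    n_boot: int = 2000,
    seed: int = 0,
    n_perm: int = 999,
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparisonResult:
    """Fold change mean(B)/mean(A) of per-cell values.

    The CI is a percentile bootstrap resampling cells within each group;
    the p-value is the two-sided permutation test on the mean difference.
    Deterministic given ``seed``.
    """
    a = _as_values(values_a, label_a)
    b = _as_values(values_b, label_b)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0.0:
        return GroupComparisonResult(
            label_a, label_b, mean_a, mean_b, a.size, b.size,
            float("nan"), float("nan"), float("nan"), float("nan"),
            n_boot, n_perm, seed, defined=False,
        )
    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_fold = boot_b / boot_a
    boot_fold = boot_fold[np.isfinite(boot_fold)]
    lo, hi = np.percentile(boot_fold, [2.5, 97.5]) if boot_fold.size else (np.nan, np.nan)
    perm = permutation_test(a, b, n_perm=n_perm, seed=seed + 1)
    return GroupComparisonResult(
        label_a, label_b, mean_a, mean_b, a.size, b.size,
        mean_b / mean_a, float(lo), float(hi), perm.p_value,
        n_boot, n_perm, seed,
    )


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationResult:
    """Two-sided permutation test of the mean difference mean(B) - mean(A).

    Sampled mode draws ``n_perm`` random relabelings and applies the
    add-one correction ``p = (b + 1) / (n_perm + 1)``, so p is in
    (0, 1]. With ``exhaustive=True`` all ``C(n, n_a)`` relabelings are
    enumerated and p is the exact tail fraction (the identity relabeling
    keeps p > 0).
    """
    a = _as_values(values_a, "A")
    b = _as_values(values_b, "B")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    t_obs = b.mean() - a.mean()
    tol = 1e-9 * max(1.0, np.abs(pooled).max())

    if exhaustive:
        total = comb(n, na)
        if total > 2_000_000:
            raise ValueError(f"exhaustive enumeration infeasible: {total} relabelings")
        s = pooled.sum()
        hits = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            t = (s - sa) / (n - na) - sa / na
            if abs(t) >= abs(t_obs) - tol:
                hits += 1
        return PermutationResult(float(t_obs), hits / total, total, True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    t_star = perms[:, na:].mean(axis=1) - perms[:, :na].mean(axis=1)
    hits = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs) - tol))
    return PermutationResult(float(t_obs), (hits + 1) / (n_perm + 1), n_perm, False)


def _trend_statistic(groups: list[np.ndarray]) -> float:
    """Sum over dose-ordered group pairs of sign(higher - lower) across all
    cross-group value pairs (concordances minus discordances)."""
    s = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = groups[j][None, :] - groups[i][:, None]
            s += float(np.sign(diff).sum())
    return s


def dose_trend(
    values,
    doses,
    n_perm: int = 999,
    seed: int = 0,
) -> TrendResult:
    """Test for a monotone trend of per-cell values across ordered doses.

    ``doses`` gives each cell's dose level (sortable; e.g. the number of
    -KTS-encoding alleles). The statistic is antisymmetric under reversal
    of the dose order; the p-value is a two-sided add-one-corrected
    permutation p over random reassignments of values to cells.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    d = np.asarray(doses).ravel()
    if v.size != d.size:
        raise ValueError("values and doses differ in length")
    levels = np.unique(d)
    if levels.size < 2:
        raise ValueError("need >= 2 dose levels")
    masks = [d == lv for lv in levels]
    groups = [v[m] for m in masks]
    if any(g.size == 0 for g in groups):
        raise ValueError("every dose level needs at least one cell")
    t_obs = _trend_statistic(groups)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(v)
        t = _trend_statistic([perm[m] for m in masks])
        if abs(t) >= abs(t_obs) - 1e-9:
            hits += 1
    return TrendResult(
        t_obs, (hits + 1) / (n_perm + 1), tuple(levels.tolist()), n_perm, seed
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a set of planned contrasts."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def compare_table(
    counts: pd.DataFrame,
    group_col: str,
    comparisons: list[tuple[str, str]],
    value_col: str = "n_minus",
    n_boot: int = 2000,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`fold_change` for each (A, B) pair of groups in a per-cell
    counts table and return one row per comparison."""
    rows = []
    for k, (a, b) in enumerate(comparisons):
        va = counts.loc[counts[group_col] == a, value_col]
        vb = counts.loc[counts[group_col] == b, value_col]
        res = fold_change(
            va, vb, n_boot=n_boot, seed=seed + k, n_perm=n_perm, label_a=a, label_b=b
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "value": value_col,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "fold_change": res.fold_change,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
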