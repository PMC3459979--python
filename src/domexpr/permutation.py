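"""Variance-partitioning statistics and permutation/bootstrap inference.

Per gene, the fraction of expression variance attributable to domestication
is the partial R-squared of the domestication term: 1 - RSS_full/RSS_null,
where the null model drops domestication but keeps sex when both sexes are
present. Significance of summary statistics is assessed by enumerating all
possible reassignments of the domestication labels; the observed
arrangement is one of them, so p-values are strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable

import numpy as np
import pandas as pd

from domexpr.de import bh_adjust, estimate_dispersions, estimate_size_factors, nb_exact_test


# ---------------------------------------------------------------------------
# variance explained


def _design(n: int, dom: np.ndarray, sex: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if sex is not None:
        cols.append(sex.astype(float))
    cols.append(dom.astype(float))
    return np.column_stack(cols)


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y under OLS on X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return (resid**2).sum(axis=0)


def variance_explained(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    include_sex: bool = True,
) -> pd.DataFrame:
    """Per-gene fraction of variance explained by domestication.

    Fits, per gene, y ~ sex + domestication (or y ~ domestication when
    ``include_sex`` is off) and the same model without domestication, and
    returns RSS_domestication, RSS_null and the fraction
    1 - RSS_domestication / RSS_null (0 for a constant gene).
    """
    meta = samples.loc[expr.columns]
    dom = (meta["status"] == "domesticated").to_numpy()
    if dom.all() or not dom.any():
        raise ValueError("need both status groups")
    sex = None
    if include_sex:
        sex = (meta["sex"] == "M").to_numpy()
        if (sex == dom).all() or (sex == ~dom).all():
            raise ValueError("sex is confounded with domestication status")
        if sex.all() or not sex.any():
            sex = None  # single sex present: the term is vacuous

    Y = expr.to_numpy(dtype=float).T  # samples x genes
    n = Y.shape[0]
    X_full = _design(n, dom, sex)
    X_null = X_full[:, :-1]
    rss_full = _rss(Y, X_full)
    rss_null = _rss(Y, X_null)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(rss_null > 0, 1.0 - rss_full / np.where(rss_null > 0, rss_null, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return pd.DataFrame(
        {"rss_domestication": rss_full, "rss_null": rss_null, "variance_fraction": frac},
        index=expr.index,
    )


def summary_statistics(
    de: pd.DataFrame,
    fits: pd.DataFrame,
    fdr: float = 0.1,
) -> dict:
    """Per-pair summary: DE count, mean variance fraction, mean |fold change|.

    The mean absolute fold change is reported as a percentage,
    100 * (2^mean(|log2 FC|) - 1).
    """
    if len(de) == 0 or len(fits) == 0:
        raise ValueError("empty gene set")
    common = de.index.intersection(fits.index)
    if len(common) == 0:
        raise ValueError("DE results and variance fits share no genes")
    n_de = int((de.loc[common, "q"] < fdr).sum())
    mean_frac = float(fits.loc[common, "variance_fraction"].mean())
    mean_abs_lfc = float(de.loc[common, "log2_fold_change"].abs().mean())
    return {
        "n_de": n_de,
        "mean_variance_fraction": mean_frac,
        "mean_abs_fold_change_pct": 100.0 * (2.0**mean_abs_lfc - 1.0),
    }


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p: float
    n_arrangements: int


def _arrangements(n: int, n_dom: int):
    """Every subset of samples that could carry the 'domesticated' label."""
    return combinations(range(n), n_dom)


def exhaustive_permutation_test(
    stat_fn: Callable[[pd.DataFrame, pd.DataFrame], float],
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    cap: int = 100_000,
) -> PermutationResult:
    """Enumerate every reassignment of the domestication labels.

    ``stat_fn(expr, samples)`` maps a dataset to a scalar. All C(n, n_dom)
    subsets of samples are labeled domesticated in turn (the observed
    arrangement included); p is the fraction of arrangements whose
    statistic matches or exceeds the observed one.
    """
    meta = samples.loc[expr.columns]
    dom = (meta["status"] == "domesticated").to_numpy()
    n, n_dom = len(dom), int(dom.sum())
    total = comb(n, n_dom)
    if total > cap:
        raise ValueError(
            f"{total} arrangements exceed the cap of {cap}; use sampled permutations"
        )
    observed = stat_fn(expr, meta)
    null_stats = np.empty(total)
    for i, subset in enumerate(_arrangements(n, n_dom)):
        status = np.full(n, "wild", dtype=object)
        status[list(subset)] = "domesticated"
        perm = meta.copy()
        perm["status"] = status
        null_stats[i] = stat_fn(expr, perm)
    p = float((null_stats >= observed).sum()) / total
    return PermutationResult(float(observed), null_stats, p, total)


def mean_variance_explained_stat(include_sex: bool = False) -> Callable:
    """Statistic factory: mean across genes of the domestication variance fraction."""

    def stat(expr: pd.DataFrame, samples: pd.DataFrame) -> float:
        return float(
            variance_explained(expr, samples, include_sex=include_sex)[
                "variance_fraction"
            ].mean()
        )

    return stat


def permuted_de_count(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fdr: float = 0.1,
    n_perm: int | None = None,
    seed: int = 0,
    cap: int = 100_000,
) -> PermutationResult:
    """Permutation null for the number of DE genes.

    Re-runs the full DE stage per label arrangement: size factors are held
    fixed (they do not depend on the labels) while dispersions are
    re-estimated, a conservative choice. With ``n_perm`` unset, all
    arrangements are enumerated; otherwise ``n_perm`` random arrangements
    are drawn (the observed one is always included).
    """
    size_factors = estimate_size_factors(counts)
    meta = samples.loc[counts.columns]
    dom = (meta["status"] == "domesticated").to_numpy()
    n, n_dom = len(dom), int(dom.sum())

    def de_count(labels: np.ndarray) -> float:
        perm = meta.copy()
        perm["status"] = np.where(labels, "domesticated", "wild")
        disp = estimate_dispersions(counts, perm, size_factors)
        res = nb_exact_test(counts, perm, disp, size_factors)
        return float((res["q"] < fdr).sum())

    observed = de_count(dom)
    if n_perm is None:
        total = comb(n, n_dom)
        if total > cap:
            raise ValueError(
                f"{total} arrangements exceed the cap of {cap}; pass n_perm"
            )
        null_stats = np.empty(total)
        for i, subset in enumerate(_arrangements(n, n_dom)):
            labels = np.zeros(n, dtype=bool)
            labels[list(subset)] = True
            null_stats[i] = de_count(labels)
        n_arr = total
    else:
        rng = np.random.default_rng(seed)
        null_stats = np.empty(n_perm + 1)
        null_stats[0] = observed
        for i in range(n_perm):
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, n_dom, replace=False)] = True
            null_stats[i + 1] = de_count(labels)
        n_arr = n_perm + 1
    p = float((null_stats >= observed).sum()) / n_arr
    return PermutationResult(observed, null_stats, p, n_arr)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_mean_ci(
    values,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean, resampling genes with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    lo = float(np.quantile(means, (1 - level) / 2))
    hi = float(np.quantile(means, 1 - (1 - level) / 2))
    return lo, hi
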