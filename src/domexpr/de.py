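"""Per-pair negative-binomial differential expression.

The testing strategy follows the classic count-based DE recipe: library
size normalization by median-of-ratios, per-gene dispersion estimated both
directly (method of moments) and from a mean-dispersion curve fitted across
genes, a conditional NB exact test on the two group sums using the maximum
of the two dispersion estimates, and Benjamini-Hochberg FDR control.
A variance-stabilizing transform and a simple FPKM computation provide the
continuous expression scales used by the linear-model analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene with nonzero counts in every sample, the ratio of its
    count to its geometric mean across samples is formed; the size factor
    of a sample is the median of these ratios.
    """
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter the matrix "
            "or supply size factors explicitly"
        )
    log_geo = logs[usable].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs[usable] - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionModel:
    """Per-gene dispersion estimates and the fitted mean-dispersion curve.

    ``used`` is the per-gene maximum of the direct (method-of-moments)
    estimate and the value of the fitted curve alpha(mu) = a0 + a1/mu,
    a deliberately conservative choice.
    """

    raw: pd.Series
    fitted: pd.Series
    used: pd.Series
    a0: float
    a1: float
    base_mean: pd.Series

    def curve(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a0 + self.a1 / mu


def estimate_dispersions(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series | None = None,
) -> DispersionModel:
    """Method-of-moments dispersions pooled within status groups.

    On the normalized scale q = k/s, Var(q) = mu * E[1/s] + alpha * mu^2,
    so the moment estimator is alpha = (v - mu * xi) / mu^2 with xi the
    mean reciprocal size factor; it is floored at zero. The curve
    alpha(mu) = a0 + a1/mu is fitted by non-negative least squares across
    genes and the per-gene working value is max(raw, fitted).
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    s = size_factors.loc[counts.columns].to_numpy()
    q = counts.to_numpy(dtype=float) / s[None, :]

    groups = [samples.index[samples["status"] == st] for st in ("domesticated", "wild")]
    for g, st in zip(groups, ("domesticated", "wild")):
        if len(g) < 2:
            raise ValueError(f"need >= 2 replicates in status group {st!r}")
    cols = {c: i for i, c in enumerate(counts.columns)}

    base_mean = q.mean(axis=1)
    num = np.zeros(counts.shape[0])
    dof = 0
    for g in groups:
        idx = [cols[c] for c in g]
        num += q[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
        dof += len(idx) - 1
    pooled_var = num / dof

    xi = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - base_mean * xi) / base_mean**2
    raw = np.where(base_mean > 0, np.maximum(raw, 0.0), 0.0)

    fit_mask = base_mean > 0
    X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / base_mean[fit_mask]])
    coef, _ = optimize.nnls(X, raw[fit_mask])
    a0, a1 = float(coef[0]), float(coef[1])

    with np.errstate(divide="ignore"):
        fitted = np.where(base_mean > 0, a0 + a1 / base_mean, a0)
    used = np.maximum(raw, fitted)
    idx = counts.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="raw"),
        fitted=pd.Series(fitted, index=idx, name="fitted"),
        used=pd.Series(used, index=idx, name="used"),
        a0=a0,
        a1=a1,
        base_mean=pd.Series(base_mean, index=idx, name="base_mean"),
    )


# ---------------------------------------------------------------------------
# exact test


def _group_sum_pmf(total: int, q0: float, s_sum: float, s_sq: float,
                   alpha: float) -> np.ndarray:
    """pmf of a group's count sum on 0..total under the pooled null.

    The group sum is NB with mean q0 * sum(s_j) and variance
    q0 * sum(s_j) + alpha * q0^2 * sum(s_j^2); when the dispersion term
    vanishes the Poisson pmf is used.
    """
    a = np.arange(total + 1)
    mu = q0 * s_sum
    var_extra = alpha * q0**2 * s_sq
    if var_extra <= 0:
        return stats.poisson.pmf(a, mu)
    r = mu**2 / var_extra
    return stats.nbinom.pmf(a, r, r / (r + mu))


def nb_exact_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    disp: DispersionModel,
    size_factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Conditional NB exact test of domesticated vs wild group sums.

    Per gene, the joint probability of every split (a, total - a) of the
    observed total count between the two groups is evaluated under the
    null of a common normalized mean; the p-value is the probability mass
    of all splits no more likely than the observed one, renormalized over
    all splits. Genes whose total is zero get p = 1. The reported fold
    change is (mean_dom + pseudocount) / (mean_wild + pseudocount) on the
    normalized scale.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if not np.isfinite(disp.used.to_numpy()).all():
        raise ValueError("non-finite dispersion estimates")
    s = size_factors.loc[counts.columns].to_numpy()
    dom = (samples.loc[counts.columns, "status"] == "domesticated").to_numpy()
    if dom.all() or not dom.any():
        raise ValueError("need both status groups")

    values = counts.to_numpy()
    q = values / s[None, :]
    mean_dom = q[:, dom].mean(axis=1)
    mean_wild = q[:, ~dom].mean(axis=1)
    q0 = q.mean(axis=1)

    sA, s2A = s[dom].sum(), (s[dom] ** 2).sum()
    sB, s2B = s[~dom].sum(), (s[~dom] ** 2).sum()
    kA = values[:, dom].sum(axis=1)
    kB = values[:, ~dom].sum(axis=1)
    alpha = disp.used.to_numpy()

    p = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        total = int(kA[i] + kB[i])
        if total == 0:
            continue
        pA = _group_sum_pmf(total, q0[i], sA, s2A, alpha[i])
        pB = _group_sum_pmf(total, q0[i], sB, s2B, alpha[i])
        joint = pA * pB[::-1]
        denom = joint.sum()
        if denom <= 0:
            continue
        obs = joint[int(kA[i])]
        # numerical slack so ties with the observed split are included
        p[i] = joint[joint <= obs * (1 + 1e-12)].sum() / denom

    p = np.clip(p, 0.0, 1.0)
    fold = (mean_dom + pseudocount) / (mean_wild + pseudocount)
    result = pd.DataFrame(
        {
            "base_mean": q0,
            "mean_domesticated": mean_dom,
            "mean_wild": mean_wild,
            "fold_change": fold,
            "log2_fold_change": np.log2(fold),
            "p": p,
        },
        index=counts.index,
    )
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# expression scales


def vst_transform(u: np.ndarray, a0: float) -> np.ndarray:
    """Antiderivative of 1/sqrt(u + a0 u^2): (2/sqrt(a0)) asinh(sqrt(a0 u)).

    As a0 -> 0 this tends to 2 sqrt(u), the Poisson (Anscombe-type) limit.
    """
    if a0 < 0:
        raise ValueError("asymptotic dispersion a0 must be >= 0")
    u = np.asarray(u, dtype=float)
    if a0 == 0:
        return 2.0 * np.sqrt(u)
    return (2.0 / np.sqrt(a0)) * np.arcsinh(np.sqrt(a0 * u))


def variance_stabilize(
    counts: pd.DataFrame,
    disp: DispersionModel,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Variance-stabilized expression on a scale that matches log2 for
    large counts.

    Each count is divided by its sample's size factor and passed through
    the integral transform for the fitted asymptotic dispersion a0; the
    result is affinely rescaled so that it coincides with log2(u) as
    u -> infinity. Strictly increasing in the count for a fixed sample.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    s = size_factors.loc[counts.columns].to_numpy()
    u = counts.to_numpy(dtype=float) / s[None, :]
    a0 = max(disp.a0, 1e-8)  # degenerate Poisson-like fit: keep the scale finite
    t = vst_transform(u, a0)
    # asinh(z) ~ ln(2z) for large z  =>  t ~ (ln(4 a0 u)) / sqrt(a0)
    vst = t * np.sqrt(a0) / np.log(2.0) - np.log2(4.0 * a0)
    return pd.DataFrame(vst, index=counts.index, columns=counts.columns)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    pseudo_log: bool = False,
) -> pd.DataFrame:
    """Fragments per kilobase of gene model per million mapped reads.

    fpkm = count * 1e9 / (length_bp * column_total); with ``pseudo_log``
    the values are returned as log2(fpkm + 1).
    """
    lengths = gene_lengths.loc[counts.index].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.to_numpy().sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"zero column totals for samples: {bad}")
    fpkm = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    if pseudo_log:
        fpkm = np.log2(fpkm + 1.0)
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)
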