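"""Joint multi-pair analysis and the domestication-related gene screen.

All domesticated and wild samples from several species pairs enter
gene-wise models of the form expression ~ pair + sex + domestication.
Because between-pair differences dwarf the domestication effect, random
permutations of the domestication labels are anticonservative for the
across-pair domestication term; the null used instead is the set of
"extreme" permutations, in which every sample of one or more whole species
pairs swaps its domesticated/wild status. Such flips preserve the
magnitude of within-pair differences and randomize only their direction
relative to the other pairs. With k pairs there are 2^(k-1) - 1 distinct
non-identity flips (a global swap of all pairs is equivalent to the
identity for the domestication contrast).

The screen calls a gene "domestication-related" when the domestication
term is significant in three models - ordinary least squares on
variance-stabilized data, OLS on log2(FPKM+1), and a negative-binomial
GLM likelihood-ratio test - and the median expression difference has the
same sign in every pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from domexpr.de import (
    compute_fpkm,
    estimate_dispersions,
    estimate_size_factors,
    variance_stabilize,
)
from domexpr.permutation import PermutationResult

_MIN_PHI = 1e-8


# ---------------------------------------------------------------------------
# joint ANOVA


def _joint_designs(samples: pd.DataFrame) -> list[np.ndarray]:
    """Nested design matrices: intercept; +pair; +sex; +domestication."""
    n = len(samples)
    pair_d = pd.get_dummies(samples["pair"], drop_first=True).to_numpy(dtype=float)
    sex_d = pd.get_dummies(samples["sex"], drop_first=True).to_numpy(dtype=float)
    dom = (samples["status"] == "domesticated").to_numpy(dtype=float)[:, None]
    X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, pair_d])
    X2 = np.column_stack([X1, sex_d]) if sex_d.shape[1] else X1
    X3 = np.column_stack([X2, dom])
    return [X0, X1, X2, X3]


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(np.abs(np.diag(R)).max(), 1.0)
    Q = Q[:, keep]
    resid = Y - Q @ (Q.T @ Y)
    return (resid**2).sum(axis=0)


def joint_variance_components(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Sequential (type-I) variance decomposition pair -> sex -> domestication.

    Each factor's fraction is its sequential reduction in residual sum of
    squares divided by the total (intercept-only) sum of squares; constant
    genes get all-zero fractions.
    """
    meta = samples.loc[expr.columns]
    if meta["pair"].nunique() < 2:
        raise ValueError("joint models need >= 2 species pairs")
    Y = expr.to_numpy(dtype=float).T
    X0, X1, X2, X3 = _joint_designs(meta)
    if np.linalg.matrix_rank(X3) < X3.shape[1]:
        raise ValueError("singular design (confounded factors)")
    rss = [_rss(Y, X) for X in (X0, X1, X2, X3)]
    tss = rss[0]
    # constant genes: TSS is zero up to rounding in the projection
    nonzero = tss > 1e-12 * np.maximum((Y**2).sum(axis=0), 1.0)
    tss = np.where(nonzero, tss, 0.0)
    safe = np.where(tss > 0, tss, 1.0)
    out = pd.DataFrame(index=expr.index)
    out["pair_fraction"] = np.where(tss > 0, (rss[0] - rss[1]) / safe, 0.0)
    out["sex_fraction"] = np.where(tss > 0, (rss[1] - rss[2]) / safe, 0.0)
    out["domestication_fraction"] = np.where(tss > 0, (rss[2] - rss[3]) / safe, 0.0)
    out["residual_fraction"] = np.where(tss > 0, rss[3] / safe, 0.0)
    return out


def anova_domestication_pvalues(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> pd.Series:
    """Per-gene F-test p-value for the domestication term in
    expr ~ pair + sex + domestication."""
    meta = samples.loc[expr.columns]
    Y = expr.to_numpy(dtype=float).T
    _, _, X2, X3 = _joint_designs(meta)
    rss_red = _rss(Y, X2)
    rss_full = _rss(Y, X3)
    df_resid = Y.shape[0] - X3.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / df_resid)
    f = np.where(rss_full > 0, f, 0.0)
    p = stats.f.sf(np.maximum(f, 0.0), 1, df_resid)
    return pd.Series(p, index=expr.index, name="p")


def structured_permutation_test(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    factor: str,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "median",
) -> PermutationResult:
    """Permutation p-value for the variance fraction of one factor.

    The statistic is the median (default) or mean across genes of the
    factor's variance fraction. The species-pair factor is permuted by
    randomly reassigning samples to pairs across the whole dataset; sex
    and domestication are permuted strictly within each species pair,
    because between-pair differences would otherwise leak into the
    permuted factor and make the test anticonservative. The observed
    arrangement counts as one arrangement.

    The median is robust but has limited power when only a small fraction
    of genes carries the effect (the bulk of genes pins the median); the
    mean responds to sparse effects.
    """
    if factor not in ("pair", "sex", "domestication"):
        raise ValueError("factor must be pair, sex or domestication")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be median or mean")
    meta = samples.loc[expr.columns]
    if meta[factor if factor != "domestication" else "status"].nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant")
    col = "status" if factor == "domestication" else factor
    key = f"{factor}_fraction"
    agg = (lambda s: float(s.median())) if statistic == "median" else (
        lambda s: float(s.mean())
    )

    observed = agg(joint_variance_components(expr, meta)[key])
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_perm + 1)
    null_stats[0] = observed
    pair_codes = meta["pair"].to_numpy()
    for b in range(n_perm):
        perm = meta.copy()
        if factor == "pair":
            perm["pair"] = rng.permutation(pair_codes)
        else:
            vals = perm[col].to_numpy().copy()
            for pr in np.unique(pair_codes):
                idx = np.flatnonzero(pair_codes == pr)
                vals[idx] = vals[rng.permutation(idx)]
            perm[col] = vals
        null_stats[b + 1] = agg(joint_variance_components(expr, perm)[key])
    p = float((null_stats >= observed).sum()) / (n_perm + 1)
    return PermutationResult(observed, null_stats, p, n_perm + 1)


# ---------------------------------------------------------------------------
# negative-binomial GLM with likelihood-ratio test


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi is per gene."""
    r = (1.0 / np.maximum(phi, _MIN_PHI))[:, None]
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)
    ).sum(axis=-1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-link GLMs sharing a design matrix.

    ``y`` is genes x samples, ``phi`` per gene. Returns (mu, converged).
    """
    G, n = y.shape
    mu = np.maximum(y, 0.5) + 0.1
    eta = np.log(mu)
    phi_col = phi[:, None]
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        w = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, w, X)
        rhs = np.einsum("ni,gn,gn->gi", X, w, z)
        A[:, np.arange(X.shape[1]), np.arange(X.shape[1])] += 1e-10
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        new_eta = beta @ X.T + offset[None, :]
        new_eta = np.clip(new_eta, -30.0, 30.0)
        delta = np.abs(new_eta - eta).max(axis=1)
        eta = new_eta
        mu = np.exp(eta)
        mu = np.maximum(mu, 1e-8)
        converged |= delta < tol
        if converged.all():
            break
    return mu, converged


def _cox_reid_apl(
    y: np.ndarray, mu: np.ndarray, X: np.ndarray, phi_grid: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood on a dispersion grid.

    Fitted means are held fixed (they depend only weakly on the
    dispersion); returns an array genes x grid.
    """
    G = y.shape[0]
    apl = np.empty((G, phi_grid.size))
    for j, phi in enumerate(phi_grid):
        ll = _nb_loglik(y, mu, np.full(G, phi))
        w = mu / (1.0 + phi * mu)
        info = np.einsum("ni,gn,nj->gij", X, w, X)
        sign, logdet = np.linalg.slogdet(info)
        apl[:, j] = ll - 0.5 * np.where(sign > 0, logdet, np.inf)
    return apl


def nb_glm_lrt(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series | None = None,
    prior_weight: float = 10.0,
    phi_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test for the domestication term in a NB GLM.

    Per gene, a log-link negative-binomial GLM with design
    pair + sex + domestication and offset log(size factor) is fitted. The
    per-gene dispersion maximizes a weighted Cox-Reid adjusted profile
    likelihood that shrinks toward the common (across-gene) estimate with
    weight ``prior_weight``. The LRT statistic compares the full model to
    the model without domestication and is referred to chi-squared with
    one degree of freedom. Non-converged genes are flagged and given
    p = NaN.
    """
    meta = samples.loc[counts.columns]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    offset = np.log(size_factors.loc[counts.columns].to_numpy(dtype=float))
    y = counts.to_numpy(dtype=float)
    _, _, X2, X3 = _joint_designs(meta)
    if np.linalg.matrix_rank(X3) < X3.shape[1]:
        raise ValueError("singular design (confounded factors)")
    if phi_grid is None:
        phi_grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 31))

    G = y.shape[0]
    # stage 1: fit means at a moderate dispersion, estimate dispersions on grid
    mu0, _ = _irls(y, X3, offset, np.full(G, 0.1))
    apl = _cox_reid_apl(y, mu0, X3, phi_grid)
    common_apl = apl.mean(axis=0)
    weighted = apl + prior_weight * common_apl[None, :]
    phi = phi_grid[np.argmax(weighted, axis=1)]

    # stage 2: final fits at the shrunken dispersions
    mu_full, conv_full = _irls(y, X3, offset, phi)
    mu_red, conv_red = _irls(y, X2, offset, phi)
    ll_full = _nb_loglik(y, mu_full, phi)
    ll_red = _nb_loglik(y, mu_red, phi)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    converged = conv_full & conv_red
    p = np.where(converged, p, np.nan)
    return pd.DataFrame(
        {"lrt": lrt, "p": p, "dispersion": phi, "converged": converged},
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# extreme permutations


def enumerate_extreme_permutations(k: int) -> list[tuple[bool, ...]]:
    """All distinct whole-pair label flips for k species pairs.

    A pattern says, per pair, whether its domesticated/wild labels are
    swapped. Globally complementary patterns are equivalent for the
    domestication contrast, so the first pair is fixed unflipped; the
    identity is excluded, leaving 2^(k-1) - 1 patterns in a deterministic
    (binary-counting) order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    patterns = []
    for bits in product([False, True], repeat=k - 1):
        pattern = (False, *bits)
        if any(pattern):
            patterns.append(pattern)
    return patterns


def apply_flip(samples: pd.DataFrame, pattern: tuple[bool, ...],
               pair_order: list[str] | None = None) -> pd.DataFrame:
    """Swap domesticated/wild labels for every pair flagged in the pattern."""
    flipped = samples.copy()
    pairs = pair_order if pair_order is not None else sorted(samples["pair"].unique())
    if len(pattern) != len(pairs):
        raise ValueError("pattern length must equal the number of pairs")
    swap = {"domesticated": "wild", "wild": "domesticated"}
    for flip, pr in zip(pattern, pairs):
        if flip:
            rows = flipped["pair"] == pr
            flipped.loc[rows, "status"] = flipped.loc[rows, "status"].map(swap)
    return flipped


# ---------------------------------------------------------------------------
# three-model screen


@dataclass
class JointModels:
    """Domestication p-values from the three joint models plus directions."""

    p: pd.DataFrame  # columns: vst, fpkm, nb
    directions: pd.DataFrame  # per-pair sign of (median dom - median wild), VST scale
    vst: pd.DataFrame

    @property
    def consistent(self) -> pd.Series:
        """Genes whose direction of change is the same (and nonzero) in all pairs."""
        d = self.directions.to_numpy()
        same = (d == d[:, [0]]).all(axis=1) & (d[:, 0] != 0)
        return pd.Series(same, index=self.directions.index, name="consistent")

    @property
    def consensus_sign(self) -> pd.Series:
        """Sign of the summed per-pair directions (0 when balanced)."""
        return pd.Series(
            np.sign(self.directions.sum(axis=1)), index=self.directions.index
        )


def pair_direction_signs(expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per pair, the sign of (median domesticated - median wild) per gene."""
    meta = samples.loc[expr.columns]
    out = {}
    for pr in sorted(meta["pair"].unique()):
        sub = meta[meta["pair"] == pr]
        dom_cols = sub.index[sub["status"] == "domesticated"]
        wild_cols = sub.index[sub["status"] == "wild"]
        diff = expr[dom_cols].median(axis=1) - expr[wild_cols].median(axis=1)
        out[pr] = np.sign(diff)
    return pd.DataFrame(out, index=expr.index)


def run_joint_models(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
    prior_weight: float = 10.0,
    size_factors: pd.Series | None = None,
) -> JointModels:
    """Fit the three joint models and compute per-pair direction signs.

    Models: OLS F-test on variance-stabilized counts; OLS F-test on
    log2(FPKM+1) (unit gene lengths of 1 kb when none are supplied, which
    makes FPKM a per-million rate); NB GLM likelihood-ratio test on the
    raw counts. Directions are taken on the variance-stabilized scale.
    """
    meta = samples.loc[counts.columns]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, meta, size_factors)
    vst = variance_stabilize(counts, disp, size_factors)
    if gene_lengths is None:
        gene_lengths = pd.Series(1000.0, index=counts.index)
    fpkm = compute_fpkm(counts, gene_lengths, pseudo_log=True)

    p = pd.DataFrame(index=counts.index)
    p["vst"] = anova_domestication_pvalues(vst, meta)
    p["fpkm"] = anova_domestication_pvalues(fpkm, meta)
    p["nb"] = nb_glm_lrt(counts, meta, size_factors, prior_weight)["p"]
    return JointModels(p=p, directions=pair_direction_signs(vst, meta), vst=vst)


def screen_domestication_genes(
    model_ps: pd.DataFrame,
    directions: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select genes significant in every model with one shared direction.

    A gene is selected iff its p-value is below ``alpha`` in all models
    and its per-pair direction signs are identical and nonzero; genes with
    a zero sign in any pair are excluded (flagged in the output).
    """
    d = directions.to_numpy()
    consistent = (d == d[:, [0]]).all(axis=1) & (d[:, 0] != 0)
    has_zero = (d == 0).any(axis=1)
    significant = (model_ps < alpha).all(axis=1).to_numpy()
    significant &= model_ps.notna().all(axis=1).to_numpy()
    out = pd.DataFrame(index=model_ps.index)
    out["significant_all_models"] = significant
    out["consistent_direction"] = consistent
    out["excluded_zero_sign"] = has_zero
    out["selected"] = significant & consistent
    return out


def significance_curve(
    p, consistent, thresholds
) -> np.ndarray:
    """Number of consistent-direction genes at or below each p threshold.

    Thresholds may include 1, which counts every consistent-direction gene
    regardless of significance. Monotone non-decreasing in the threshold.
    """
    p = np.asarray(p, dtype=float)
    consistent = np.asarray(consistent, dtype=bool)
    thresholds = np.asarray(thresholds, dtype=float)
    ok = consistent & ~np.isnan(p)
    return np.array([(ok & (p <= t)).sum() for t in thresholds])


def extreme_null_curves(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds,
    model: str = "vst",
    gene_lengths: pd.Series | None = None,
    prior_weight: float = 10.0,
) -> dict:
    """Observed significance curve plus one curve per extreme permutation.

    For each whole-pair flip, the chosen model (``vst``, ``fpkm`` or
    ``nb``) and the per-pair directions are recomputed under the flipped
    labels; within-pair difference magnitudes are untouched by
    construction, only their directions change.
    """
    meta = samples.loc[counts.columns]
    pairs = sorted(meta["pair"].unique())
    if len(pairs) < 2:
        raise ValueError("extreme permutations need >= 2 pairs")
    size_factors = estimate_size_factors(counts)

    def one(labels: pd.DataFrame) -> np.ndarray:
        if model == "nb":
            p = nb_glm_lrt(counts, labels, size_factors, prior_weight)["p"]
            disp = estimate_dispersions(counts, labels, size_factors)
            expr = variance_stabilize(counts, disp, size_factors)
        else:
            disp = estimate_dispersions(counts, labels, size_factors)
            if model == "vst":
                expr = variance_stabilize(counts, disp, size_factors)
            elif model == "fpkm":
                gl = gene_lengths if gene_lengths is not None else pd.Series(
                    1000.0, index=counts.index
                )
                expr = compute_fpkm(counts, gl, pseudo_log=True)
            else:
                raise ValueError("model must be vst, fpkm or nb")
            p = anova_domestication_pvalues(expr, labels)
        signs = pair_direction_signs(expr, labels)
        d = signs.to_numpy()
        consistent = (d == d[:, [0]]).all(axis=1) & (d[:, 0] != 0)
        return significance_curve(p.to_numpy(), consistent, thresholds)

    patterns = enumerate_extreme_permutations(len(pairs))
    return {
        "thresholds": np.asarray(thresholds, dtype=float),
        "observed": one(meta),
        "patterns": patterns,
        "flips": [one(apply_flip(meta, pat, pairs)) for pat in patterns],
    }


# ---------------------------------------------------------------------------
# hold-out prediction


def _direction_or(selected: np.ndarray, same: np.ndarray) -> tuple[tuple, float, float]:
    a = int((selected & same).sum())
    b = int((selected & ~same).sum())
    c = int((~selected & same).sum())
    d = int((~selected & ~same).sum())
    n = a + b + c + d
    p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = a * d / (b * c)
    return (a, b, c, d), odds, p


def holdout_direction_prediction(
    screen: pd.DataFrame,
    models: JointModels,
    heldout_expr: pd.DataFrame,
    heldout_samples: pd.DataFrame,
    omap: pd.DataFrame,
    heldout_pair: str,
    flip_models: list[JointModels] | None = None,
):
    """Do screened genes predict the direction of change in a held-out pair?

    The held-out pair does not enter the screen. Over held-out expressed
    orthologues with a nonzero direction in both the screen pairs
    (consensus sign) and the held-out pair, genes are cross-classified as
    selected / unselected x same / opposite direction and a one-sided FET
    for enrichment of agreement among selected genes is computed.

    For each extreme permutation (``flip_models``), an equally sized gene
    set is re-selected by summed p-value ranks across the three models
    among genes with a consistent direction under that flip, and its odds
    ratio recomputed.

    Returns ``(OverlapResult-like tuple, per-flip odds ratios)`` as a dict.
    """
    from domexpr.crosspair import OverlapResult

    held_meta = heldout_samples.loc[heldout_expr.columns]
    dom_cols = held_meta.index[held_meta["status"] == "domesticated"]
    wild_cols = held_meta.index[held_meta["status"] == "wild"]
    held_diff = heldout_expr[dom_cols].median(axis=1) - heldout_expr[wild_cols].median(axis=1)
    held_sign = np.sign(held_diff)

    # orthologue ids whose held-out gene is expressed (present in heldout_expr)
    if heldout_pair not in omap.columns:
        raise KeyError(f"orthologue map lacks held-out pair {heldout_pair!r}")
    held_genes = omap[heldout_pair]
    expressed = held_genes.isin(heldout_expr.index)
    orth = omap.index[expressed]
    orth = orth.intersection(screen.index)
    held_sign_by_orth = pd.Series(
        held_sign.reindex(omap.loc[orth, heldout_pair]).to_numpy(), index=orth
    )

    consensus = models.consensus_sign.reindex(orth)
    usable = (consensus != 0) & (held_sign_by_orth != 0)
    orth = orth[usable.to_numpy()]
    if len(orth) == 0:
        raise ValueError("no screened gene has an expressed held-out orthologue")
    consensus = consensus[orth]
    held_s = held_sign_by_orth[orth]
    same = (np.sign(consensus) == np.sign(held_s)).to_numpy()

    selected = screen.loc[orth, "selected"].to_numpy()
    if not selected.any():
        raise ValueError("no selected gene has an expressed held-out orthologue")
    table, odds, p = _direction_or(selected, same)
    observed = OverlapResult(table, odds, p, "selected->heldout", len(orth))

    n_sel = int(selected.sum())
    flip_ors = []
    for fm in flip_models or []:
        ranks = fm.p.loc[orth].rank(method="average")
        summed = ranks.sum(axis=1)
        consistent = fm.consistent.reindex(orth).to_numpy()
        cons_sign = fm.consensus_sign.reindex(orth)
        candidates = summed[consistent & (cons_sign != 0).to_numpy()]
        chosen = candidates.nsmallest(n_sel).index
        sel = orth.isin(chosen)
        f_same = (np.sign(cons_sign) == np.sign(held_s)).to_numpy()
        _, f_odds, _ = _direction_or(sel, f_same)
        flip_ors.append(f_odds)
    return {"observed": observed, "flip_odds_ratios": flip_ors, "n_selected": n_sel}
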