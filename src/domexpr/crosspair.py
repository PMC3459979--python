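"""Pairwise comparisons between domestication events.

Three tests per pair of events, each over the universe of 1:1 orthologues
expressed in both events: (i) a one-sided Fisher exact test for overlap of
the DE gene sets, (ii) a directional Fisher test asking whether genes DE in
one event change in the same direction in the other more often than
non-DE genes, run in both directions with the more significant reported,
and (iii) a Spearman correlation of per-gene median expression differences
with a label-permutation p-value. A fourth test intersects DE genes with
genomic maps of positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapResult:
    table: tuple  # (a, b, c, d)
    odds_ratio: float
    p_one_sided: float
    direction_tested: str
    n_universe: int


def _one_sided_fet(a: int, b: int, c: int, d: int) -> float:
    """P(overlap >= a) under the hypergeometric null of the 2x2 table."""
    n = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else 0.0
    return a * d / (b * c)


def orthologue_universe(
    pair_a: str,
    pair_b: str,
    expressed: dict,
    omap: pd.DataFrame,
) -> pd.DataFrame:
    """Orthologues expressed in both events.

    ``expressed`` maps each pair label to the set of expressed gene ids in
    that pair's gene-id space. Returns the orthologue-map rows (indexed by
    orthologue id, deterministic order) whose genes are expressed in both
    events.
    """
    for p in (pair_a, pair_b):
        if p not in omap.columns:
            raise KeyError(f"orthologue map has no column for pair {p!r}")
    in_a = omap[pair_a].isin(set(expressed[pair_a]))
    in_b = omap[pair_b].isin(set(expressed[pair_b]))
    universe = omap.loc[in_a & in_b, [pair_a, pair_b]].sort_index()
    if universe.empty:
        raise ValueError(f"no shared expressed orthologues between {pair_a} and {pair_b}")
    return universe


def de_overlap_fet(de_a: set, de_b: set, universe: pd.Index | list) -> OverlapResult:
    """One-sided FET for sharing of DE genes between two events.

    ``de_a`` and ``de_b`` are sets of orthologue ids; the table splits the
    universe into DE-in-both / A-only / B-only / neither.
    """
    uni = list(universe)
    de_a = set(de_a) & set(uni)
    de_b = set(de_b) & set(uni)
    a = len(de_a & de_b)
    b = len(de_a - de_b)
    c = len(de_b - de_a)
    d = len(uni) - a - b - c
    if not de_a or not de_b:
        return OverlapResult((a, b, c, d), 0.0, 1.0, "A&B", len(uni))
    p = _one_sided_fet(a, b, c, d)
    return OverlapResult((a, b, c, d), _sample_or(a, b, c, d), p, "A&B", len(uni))


def _directional_table(de: np.ndarray, same: np.ndarray) -> tuple:
    a = int((de & same).sum())
    b = int((de & ~same).sum())
    c = int((~de & same).sum())
    d = int((~de & ~same).sum())
    return a, b, c, d


def directional_fet(
    de_a: set,
    de_b: set,
    signs_a: pd.Series,
    signs_b: pd.Series,
    universe: pd.Index | list,
) -> OverlapResult:
    """Does DE in one event predict the direction of change in the other?

    Genes with a zero direction in either event are excluded from the
    universe. Both asymmetric tests (A's DE genes vs agreement, and B's)
    are run; the more significant is returned, labeled by
    ``direction_tested``.
    """
    uni = pd.Index(universe)
    sa = signs_a.reindex(uni)
    sb = signs_b.reindex(uni)
    nonzero = (sa != 0) & (sb != 0) & sa.notna() & sb.notna()
    uni = uni[nonzero]
    if len(uni) == 0:
        raise ValueError("all universe genes have tied (zero) directions")
    same = (np.sign(sa[uni]) == np.sign(sb[uni])).to_numpy()

    results = []
    for de_set, label in ((de_a, "A->B"), (de_b, "B->A")):
        de = uni.isin(set(de_set))
        a, b, c, d = _directional_table(de, same)
        p = _one_sided_fet(a, b, c, d)
        results.append(OverlapResult((a, b, c, d), _sample_or(a, b, c, d), p, label, len(uni)))
    return min(results, key=lambda r: r.p_one_sided)


def median_diff_correlation(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
    universe: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of median domesticated-wild differences.

    ``universe`` is an orthologue frame as returned by
    :func:`orthologue_universe` (columns: gene ids per pair, in the order
    A, B). Significance is assessed by permuting the domestication labels
    independently within each event ``n_perm`` times; p is the fraction of
    permutations (observed arrangement included) with rho at least the
    observed value.
    """
    if len(universe) < 3:
        raise ValueError("need >= 3 universe genes")
    col_a, col_b = universe.columns[:2]

    def median_diff(expr, samples, genes):
        meta = samples.loc[expr.columns]
        dom = meta["status"] == "domesticated"
        sub = expr.loc[genes].to_numpy(dtype=float)
        return np.median(sub[:, dom.to_numpy()], axis=1) - np.median(
            sub[:, (~dom).to_numpy()], axis=1
        )

    da = median_diff(expr_a, samples_a, universe[col_a])
    db = median_diff(expr_b, samples_b, universe[col_b])
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("zero-variance difference vector")
    rho = float(stats.spearmanr(da, db).statistic)

    rng = np.random.default_rng(seed)
    hits = 1  # the observed arrangement
    for _ in range(n_perm):
        pa = samples_a.copy()
        pa["status"] = rng.permutation(samples_a["status"].to_numpy())
        pb = samples_b.copy()
        pb["status"] = rng.permutation(samples_b["status"].to_numpy())
        ra = median_diff(expr_a, pa, universe[col_a])
        rb = median_diff(expr_b, pb, universe[col_b])
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            continue
        if stats.spearmanr(ra, rb).statistic >= rho:
            hits += 1
    return rho, hits / (n_perm + 1)


def selection_region_overlap_fet(
    de_genes: set,
    gene_coords: pd.DataFrame,
    selected: pd.DataFrame,
    universe: pd.Index | list,
) -> OverlapResult:
    """FET for DE genes falling in positively selected regions.

    ``gene_coords`` has columns chrom/start/end per gene id (0-based
    half-open); a gene counts as selected iff its interval intersects any
    selected region. The 2x2 table is DE&selected / DE-only /
    selected-only / neither over the expressed universe.
    """
    uni = pd.Index(universe)
    missing = uni.difference(gene_coords.index)
    if len(missing) > 0:
        raise ValueError(f"genes without coordinates: {sorted(missing)[:10]}")
    coords = gene_coords.loc[uni]

    sel_flag = np.zeros(len(uni), dtype=bool)
    for chrom, regions in selected.groupby("chrom"):
        on = coords["chrom"] == chrom
        if not on.any():
            continue
        starts = regions["start"].to_numpy()
        ends = regions["end"].to_numpy()
        gs = coords.loc[on, "start"].to_numpy()
        ge = coords.loc[on, "end"].to_numpy()
        # half-open intersection: gene [gs, ge) meets region [rs, re)
        hit = (gs[:, None] < ends[None, :]) & (starts[None, :] < ge[:, None])
        sel_flag[on.to_numpy()] |= hit.any(axis=1)

    de = uni.isin(set(de_genes))
    a = int((de & sel_flag).sum())
    b = int((de & ~sel_flag).sum())
    c = int((~de & sel_flag).sum())
    d = int((~de & ~sel_flag).sum())
    if a + c == 0:  # nothing selected anywhere
        return OverlapResult((a, b, c, d), 0.0, 1.0, "DE&selected", len(uni))
    p = _one_sided_fet(a, b, c, d)
    return OverlapResult((a, b, c, d), _sample_or(a, b, c, d), p, "DE&selected", len(uni))
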