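"""SNV site/genotype filtering and population-genetic summaries.

RNA-seq reads double as a (sparse) resequencing experiment: where exonic
coverage is high enough, diploid genotypes can be called per individual.
Because cDNA alignments are error-prone, candidate sites pass a series of
filters before any genotype is trusted: a minimum number of supporting
reads across individuals, no second SNV within a small window (clustered
calls are usually alignment artifacts), a minimum distance to the nearest
indel, and exclusion of repeat-masked regions. Individual genotypes are
then kept only when coverage, consensus quality and RMS mapping quality
all meet their thresholds; anything else is set to missing.

Downstream summaries: classification of complete-data sites into fixed
differences, shared polymorphisms and private polymorphisms; nucleotide
diversity (pi) per 1,000 callable bases; pairwise between-group
divergence; and a genotype PCA on 0/1/2 allele-dosage codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class SiteTable:
    """Per-site, per-individual diploid calls with quality covariates.

    ``genotypes`` holds alt-allele dosages 0/1/2 with -1 for missing.
    ``sites`` has columns chrom, pos (1-based), ref, alt, total_reads.
    All per-individual frames share the same row index (sites) and
    columns (individuals); ``samples`` maps individuals to their
    domesticated/wild status.
    """

    sites: pd.DataFrame
    genotypes: pd.DataFrame
    coverage: pd.DataFrame
    consensus_quality: pd.DataFrame
    rms_mapping_quality: pd.DataFrame
    samples: pd.DataFrame

    def subset(self, mask: np.ndarray) -> "SiteTable":
        idx = pd.RangeIndex(int(np.asarray(mask).sum()))

        def take(df: pd.DataFrame) -> pd.DataFrame:
            out = df.loc[np.asarray(mask)].copy()
            out.index = idx
            return out

        return SiteTable(
            sites=take(self.sites),
            genotypes=take(self.genotypes),
            coverage=take(self.coverage),
            consensus_quality=take(self.consensus_quality),
            rms_mapping_quality=take(self.rms_mapping_quality),
            samples=self.samples,
        )


@dataclass
class FilterConfig:
    """Thresholds of the site and genotype filters (all inclusive bounds).

    ``max_snvs_in_window`` distinguishes the stricter discovery rule (no
    other SNV within the window, i.e. 1) from the genotyping rule (at most
    2 SNVs in the window).
    """

    min_site_reads: int = 8
    cluster_window_bp: int = 10
    max_snvs_in_window: int = 1
    min_indel_distance_bp: int = 10
    min_coverage: int = 8
    min_consensus_qual: float = 30.0
    min_rms_mapq: float = 25.0

    def validate(self) -> None:
        for name in ("min_site_reads", "cluster_window_bp", "max_snvs_in_window",
                     "min_indel_distance_bp", "min_coverage",
                     "min_consensus_qual", "min_rms_mapq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# site discovery


def _cluster_counts(chroms: np.ndarray, pos: np.ndarray, window: int) -> np.ndarray:
    """Number of SNVs (including the site itself) within +-window of each site."""
    counts = np.ones(len(pos), dtype=int)
    for ch in np.unique(chroms):
        on = chroms == ch
        p = pos[on]
        lo = np.searchsorted(p, p - window, side="left")
        hi = np.searchsorted(p, p + window, side="right")
        counts[on] = hi - lo
    return counts


def _near_interval(chroms: np.ndarray, pos: np.ndarray,
                   intervals: pd.DataFrame) -> np.ndarray:
    """True where a 1-based position falls inside a 0-based half-open interval."""
    inside = np.zeros(len(pos), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return inside
    for ch, sub in intervals.groupby("chrom"):
        on = chroms == ch
        if not on.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        p0 = pos[on] - 1  # 0-based coordinate of the base
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = k >= 0
        hit = np.zeros(p0.shape, dtype=bool)
        hit[ok] = p0[ok] < ends[k[ok]]
        inside[on] = hit
    return inside


def _indel_distance(chroms: np.ndarray, pos: np.ndarray,
                    indels: pd.DataFrame) -> np.ndarray:
    """Distance in bp to the nearest indel position (inf when none on the chrom)."""
    dist = np.full(len(pos), np.inf)
    if indels is None or len(indels) == 0:
        return dist
    for ch, sub in indels.groupby("chrom"):
        on = chroms == ch
        if not on.any():
            continue
        ipos = np.sort(sub["pos"].to_numpy())
        p = pos[on]
        k = np.searchsorted(ipos, p)
        left = np.where(k > 0, p - ipos[np.maximum(k - 1, 0)], np.inf)
        right = np.where(k < len(ipos), ipos[np.minimum(k, len(ipos) - 1)] - p, np.inf)
        dist[on] = np.minimum(np.abs(left), np.abs(right))
    return dist


def discover_snv_sites(
    table: SiteTable,
    repeats: pd.DataFrame | None,
    indels: pd.DataFrame | None,
    cfg: FilterConfig | None = None,
) -> SiteTable:
    """Apply the site-level discovery filters.

    A candidate survives iff its total supporting reads meet
    ``min_site_reads``, at most ``max_snvs_in_window`` SNVs (itself
    included) lie within ``cluster_window_bp``, the nearest indel is
    farther than ``min_indel_distance_bp`` away, and it is outside every
    repeat interval. Input must be sorted by (chrom, pos).
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    chroms = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    order = np.lexsort((pos, chroms))
    if not np.array_equal(order, np.arange(len(pos))):
        raise ValueError("site table must be sorted by (chrom, pos)")

    keep = table.sites["total_reads"].to_numpy() >= cfg.min_site_reads
    keep &= _cluster_counts(chroms, pos, cfg.cluster_window_bp) <= cfg.max_snvs_in_window
    keep &= _indel_distance(chroms, pos, indels) > cfg.min_indel_distance_bp
    keep &= ~_near_interval(chroms, pos, repeats)
    return table.subset(keep)


def call_genotypes(table: SiteTable, cfg: FilterConfig | None = None) -> SiteTable:
    """Mask genotypes that fail any per-individual quality threshold.

    A genotype is retained iff coverage >= ``min_coverage``, consensus
    quality >= ``min_consensus_qual`` and RMS mapping quality >=
    ``min_rms_mapq`` (boundaries inclusive); otherwise it is set missing.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    ok = (
        (table.coverage.to_numpy() >= cfg.min_coverage)
        & (table.consensus_quality.to_numpy() >= cfg.min_consensus_qual)
        & (table.rms_mapping_quality.to_numpy() >= cfg.min_rms_mapq)
    )
    geno = np.where(ok, table.genotypes.to_numpy(), MISSING).astype(np.int8)
    out = SiteTable(
        sites=table.sites.copy(),
        genotypes=pd.DataFrame(geno, index=table.genotypes.index,
                               columns=table.genotypes.columns),
        coverage=table.coverage.copy(),
        consensus_quality=table.consensus_quality.copy(),
        rms_mapping_quality=table.rms_mapping_quality.copy(),
        samples=table.samples,
    )
    return out


# ---------------------------------------------------------------------------
# classification and summaries


def _group_columns(table: SiteTable) -> tuple[list, list]:
    status = table.samples["status"]
    dom = [s for s in table.genotypes.columns if status.get(s) == "domesticated"]
    wild = [s for s in table.genotypes.columns if status.get(s) == "wild"]
    if not dom or not wild:
        raise ValueError("need individuals in both status groups")
    return dom, wild


def classify_snvs(
    table: SiteTable,
    complete_only: bool = True,
) -> pd.DataFrame:
    """Classify sites as fixed difference / shared polymorphism / private / other.

    Only sites where every individual has a genotype are analyzed when
    ``complete_only`` (the default). Fixed: each group homozygous for a
    different allele. Shared: both alleles present within both groups.
    Private: polymorphic in exactly one group, monomorphic in the other.
    """
    dom, wild = _group_columns(table)
    g = table.genotypes
    gd = g[dom].to_numpy()
    gw = g[wild].to_numpy()
    complete = (g.to_numpy() != MISSING).all(axis=1)

    def group_alleles(x):
        has_ref = ((x == 0) | (x == 1)).any(axis=1)
        has_alt = ((x == 2) | (x == 1)).any(axis=1)
        return has_ref, has_alt

    dr, da = group_alleles(gd)
    wr, wa = group_alleles(gw)
    fixed = (
        ((gd == 0).all(axis=1) & (gw == 2).all(axis=1))
        | ((gd == 2).all(axis=1) & (gw == 0).all(axis=1))
    )
    shared = dr & da & wr & wa
    poly_d = dr & da
    poly_w = wr & wa
    private = (poly_d ^ poly_w) & ~fixed

    label = np.full(len(g), "other", dtype=object)
    label[private] = "private"
    label[shared] = "shared"
    label[fixed] = "fixed"
    out = table.sites[["chrom", "pos"]].copy()
    out["complete"] = complete
    out["label"] = label
    if complete_only:
        out.loc[~complete, "label"] = "incomplete"
    return out


def popgen_summary(
    table: SiteTable,
    callable_bases: int,
    complete_only: bool = True,
) -> dict:
    """Counts and fractions of fixed and shared SNVs plus diversity per group."""
    cls = classify_snvs(table, complete_only=complete_only)
    analyzed = cls[cls["label"] != "incomplete"]
    n = len(analyzed)
    n_fixed = int((analyzed["label"] == "fixed").sum())
    n_shared = int((analyzed["label"] == "shared").sum())
    dom, wild = _group_columns(table)
    summary = {
        "n_snvs_complete": n,
        "n_fixed": n_fixed,
        "frac_fixed": n_fixed / n if n else 0.0,
        "n_shared": n_shared,
        "frac_shared": n_shared / n if n else 0.0,
        "callable_bases": callable_bases,
        "pi_domesticated_per_kb": nucleotide_diversity(table, "domesticated", callable_bases),
        "pi_wild_per_kb": nucleotide_diversity(table, "wild", callable_bases),
    }
    return summary


def nucleotide_diversity(
    table: SiteTable,
    group: str,
    callable_bases: int,
) -> float:
    """Nucleotide diversity pi per 1,000 callable bases for one group.

    Per site, the unbiased estimator n/(n-1) * 2 p (1-p) with n = 2 x
    group size alleles and p the alt-allele frequency over non-missing
    calls; summed over sites and scaled to 1 kb of callable sequence.
    """
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    status = table.samples["status"]
    cols = [s for s in table.genotypes.columns if status.get(s) == group]
    if len(cols) < 2:
        raise ValueError(f"group {group!r} needs >= 2 individuals")
    g = table.genotypes[cols].to_numpy().astype(float)
    g[g == MISSING] = np.nan
    n_alleles = 2 * len(cols)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=1) / 2.0
    p = np.nan_to_num(p)
    per_site = (n_alleles / (n_alleles - 1)) * 2.0 * p * (1.0 - p)
    return float(per_site.sum() / callable_bases * 1000.0)


def pairwise_divergence(table: SiteTable, n_positions: int | None = None):
    """Between-group divergence per (domesticated, wild) individual pair.

    Over positions where every individual has a genotype, two individuals
    differ at a position iff their diploid genotypes are not identical.
    ``n_positions`` is the total number of compared positions (defaults to
    the number of complete sites, appropriate when the table already holds
    every callable position). Returns (per-pair fractions, median).
    """
    dom, wild = _group_columns(table)
    g = table.genotypes.to_numpy()
    complete = (g != MISSING).all(axis=1)
    if n_positions is None:
        n_positions = int(complete.sum())
    if n_positions <= 0:
        raise ValueError("no complete positions to compare")
    gd = table.genotypes.loc[complete, dom].to_numpy()
    gw = table.genotypes.loc[complete, wild].to_numpy()
    fractions = {}
    for i, d in enumerate(dom):
        for j, w in enumerate(wild):
            diff = int((gd[:, i] != gw[:, j]).sum())
            fractions[(d, w)] = diff / n_positions
    values = np.array(list(fractions.values()))
    return fractions, float(np.median(values))


def genotype_pca(table: SiteTable) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of individuals on allele-dosage-coded genotypes.

    Sites with any missing genotype are dropped; dosages are centered per
    site and the scores come from the SVD of the individuals x sites
    matrix. Returns (scores frame indexed by individual, variance
    fractions per component).
    """
    g = table.genotypes.to_numpy().astype(float)
    complete = (g != MISSING).all(axis=1)
    M = g[complete].T  # individuals x sites
    if M.shape[1] < 2 or M.shape[0] < 3:
        raise ValueError("need >= 2 complete sites and >= 3 individuals")
    M = M - M.mean(axis=0, keepdims=True)
    if np.allclose(M, 0):
        raise ValueError("constant genotype matrix")
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    scores = U * S
    var_frac = S**2 / (S**2).sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=table.genotypes.columns, columns=cols),
        var_frac,
    )
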