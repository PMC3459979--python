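"""Synthetic data with known ground truth.

Two generators: multi-pair negative-binomial count matrices with
species-pair, sex, pair-specific and shared domestication effects on a
dispersion-mean relation, and diploid genotype tables with configurable
fractions of fixed differences and shared polymorphisms plus coverage and
quality covariates that exercise the SNV filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from domexpr.popgen import SiteTable

LOG2 = np.log(2.0)


@dataclass
class ExprSimConfig:
    """Parameters of the expression simulator.

    Counts are drawn per gene and sample from a negative binomial with
    mean = baseline x pair x sex x domestication x library size factor and
    variance mu + alpha * mu^2, where the per-gene dispersion follows
    alpha(mu) = dispersion_a0 + dispersion_a1 / mu evaluated at the gene's
    baseline mean. All effect sizes are on the log2 scale.
    """

    n_pairs: int = 3
    samples_per_group: int = 5
    n_genes: int = 5000
    baseline_log_mean: float = 5.0  # natural-log mean of gene baselines
    baseline_log_sd: float = 1.2
    dispersion_a0: float = 0.05
    dispersion_a1: float = 2.0
    pair_effect_sd: float = 1.0
    sex_effect_sd: float = 0.1
    frac_pair_specific_de: float = 0.0
    frac_shared_de: float = 0.0
    shared_lfc_mean: float = 1.0
    shared_lfc_sd: float = 0.25
    pair_lfc_mean: float = 1.0
    pair_lfc_sd: float = 0.5
    library_size_factors: object = "auto"  # "auto" or sequence of positives
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 <= self.frac_pair_specific_de <= 1 and 0 <= self.frac_shared_de <= 1):
            raise ValueError("DE fractions must be in [0, 1]")
        if self.frac_pair_specific_de + self.frac_shared_de > 1:
            raise ValueError("frac_pair_specific_de + frac_shared_de must be <= 1")
        for name in ("baseline_log_sd", "pair_effect_sd", "sex_effect_sd",
                     "shared_lfc_sd", "pair_lfc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion coefficients must be >= 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with var = mu + alpha mu^2; alpha == 0 falls back to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-pair count matrix.

    Returns ``(counts, samples, orthologue_map, truth)``. The orthologue map
    is the identity across pairs (every gene is its own 1:1 orthologue).
    The truth table records, per gene, the shared-DE flag, per-pair DE flags,
    the true per-pair log2 fold changes (domesticated vs wild) and the true
    dispersion. Shared genes carry the same fold-change sign in every pair;
    pair-specific effects are drawn independently per pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, k, m = config.n_genes, config.n_pairs, config.samples_per_group
    n_samples = k * 2 * m

    pairs = [f"pair{i + 1}" for i in range(k)]
    genes = [f"g{i + 1}" for i in range(G)]

    rows = []
    for p in pairs:
        for status in ("domesticated", "wild"):
            for j in range(m):
                # alternate sexes so both are present in every group
                rows.append(
                    (f"{p}_{status[0]}{j + 1}", p, status, "F" if j % 2 == 0 else "M")
                )
    samples = pd.DataFrame(rows, columns=["sample", "pair", "status", "sex"])
    samples = samples.set_index("sample")

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, G))
    alpha = config.dispersion_a0 + config.dispersion_a1 / base

    pair_shift = rng.normal(0.0, config.pair_effect_sd, (G, k))
    sex_shift = rng.normal(0.0, config.sex_effect_sd, G)

    n_shared = int(round(config.frac_shared_de * G))
    n_pairspec = int(round(config.frac_pair_specific_de * G))
    de_genes = rng.choice(G, size=n_shared + n_pairspec, replace=False)
    shared_idx = de_genes[:n_shared]
    pairspec_idx = de_genes[n_shared:]

    lfc = np.zeros((G, k))
    shared_sign = rng.choice([-1.0, 1.0], n_shared)
    shared_mag = np.abs(rng.normal(config.shared_lfc_mean, config.shared_lfc_sd, n_shared))
    lfc[shared_idx, :] = (shared_sign * shared_mag)[:, None]
    pair_sign = rng.choice([-1.0, 1.0], (n_pairspec, k))
    pair_mag = np.abs(rng.normal(config.pair_lfc_mean, config.pair_lfc_sd, (n_pairspec, k)))
    lfc[pairspec_idx, :] = pair_sign * pair_mag

    if isinstance(config.library_size_factors, str):
        if config.library_size_factors != "auto":
            raise ValueError("library_size_factors must be 'auto' or a sequence")
        size = np.exp(rng.normal(0.0, 0.15, n_samples))
    else:
        size = np.asarray(config.library_size_factors, dtype=float)
        if size.shape != (n_samples,) or (size <= 0).any():
            raise ValueError("library_size_factors must be positive, one per sample")

    pair_idx = np.array([pairs.index(p) for p in samples["pair"]])
    is_dom = (samples["status"] == "domesticated").to_numpy()
    is_male = (samples["sex"] == "M").to_numpy()

    log2_mu = (
        np.log2(base)[:, None]
        + pair_shift[:, pair_idx]
        + np.where(is_male, sex_shift[:, None], 0.0)
        + np.where(is_dom, lfc[:, pair_idx], 0.0)
    )
    mu = np.exp(log2_mu * LOG2) * size[None, :]
    counts = _nb_draw(rng, mu, np.broadcast_to(alpha[:, None], mu.shape))

    counts = pd.DataFrame(counts, index=genes, columns=samples.index)
    omap = pd.DataFrame({p: genes for p in pairs},
                        index=pd.Index(genes, name="orthologue_id"))

    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    truth["is_shared_de"] = False
    truth.iloc[shared_idx, truth.columns.get_loc("is_shared_de")] = True
    for pi, p in enumerate(pairs):
        flag = np.zeros(G, dtype=bool)
        flag[shared_idx] = True
        flag[pairspec_idx] = True
        truth[f"is_de_{p}"] = flag
        truth[f"lfc_{p}"] = lfc[:, pi]
    truth["dispersion"] = alpha
    return counts, samples, omap, truth


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenoSimConfig:
    """Parameters of the diploid genotype simulator.

    Sites are labeled by construction: ``frac_fixed_diff`` of them are fixed
    differences (all domesticated individuals homozygous for one allele, all
    wild for the other), ``frac_shared_poly`` are shared polymorphisms (both
    alleles segregate in both groups), and the remainder are private
    polymorphisms of one group. Coverage and quality covariates are drawn
    independently of the genotype so filters can be exercised orthogonally
    to the truth labels.
    """

    n_sites: int = 200
    n_dom: int = 4
    n_wild: int = 4
    frac_fixed_diff: float = 0.1
    frac_shared_poly: float = 0.2
    coverage_mean: float = 25.0
    coverage_disp: float = 0.2
    consensus_qual_mean: float = 45.0
    consensus_qual_sd: float = 8.0
    mapq_mean: float = 38.0
    mapq_sd: float = 6.0
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_indels: int = 10
    frac_repeat: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_dom < 1 or self.n_wild < 1:
            raise ValueError("need at least one individual per group")
        if not (0 <= self.frac_fixed_diff <= 1 and 0 <= self.frac_shared_poly <= 1):
            raise ValueError("site fractions must be in [0, 1]")
        if self.frac_fixed_diff + self.frac_shared_poly > 1:
            raise ValueError("frac_fixed_diff + frac_shared_poly must be <= 1")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")


_BASES = np.array(list("ACGT"))


def _segregating(rng: np.random.Generator, n: int) -> np.ndarray:
    """Diploid dosages for n individuals with both alleles present."""
    while True:
        g = rng.binomial(2, 0.5, n)
        if g.min() < 2 and g.max() > 0:  # both alleles present in the group
            return g


def simulate_genotypes(
    config: GenoSimConfig,
) -> tuple[SiteTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a diploid genotype table.

    Returns ``(site_table, truth, repeats, indels)`` where ``truth`` holds
    the constructed per-site class (fixed / shared / private), ``repeats``
    is a BED-style frame of repeat-masked intervals and ``indels`` a frame
    of indel positions (1-based).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = config.n_sites
    n_ind = config.n_dom + config.n_wild
    individuals = [f"dom{i + 1}" for i in range(config.n_dom)] + [
        f"wild{i + 1}" for i in range(config.n_wild)
    ]
    status = ["domesticated"] * config.n_dom + ["wild"] * config.n_wild

    pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), S, replace=False))
    ref_i = rng.integers(0, 4, S)
    alt_i = (ref_i + rng.integers(1, 4, S)) % 4

    n_fixed = int(round(config.frac_fixed_diff * S))
    n_shared = int(round(config.frac_shared_poly * S))
    labels = np.array(["private"] * S, dtype=object)
    order = rng.permutation(S)
    fixed_idx = order[:n_fixed]
    shared_idx = order[n_fixed:n_fixed + n_shared]
    labels[fixed_idx] = "fixed"
    labels[shared_idx] = "shared"

    geno = np.zeros((S, n_ind), dtype=np.int8)
    dom_sl = slice(0, config.n_dom)
    wild_sl = slice(config.n_dom, n_ind)
    for i in range(S):
        if labels[i] == "fixed":
            dom_alt = rng.random() < 0.5
            geno[i, dom_sl] = 2 if dom_alt else 0
            geno[i, wild_sl] = 0 if dom_alt else 2
        elif labels[i] == "shared":
            geno[i, dom_sl] = _segregating(rng, config.n_dom)
            geno[i, wild_sl] = _segregating(rng, config.n_wild)
        else:  # private: polymorphic in one group, monomorphic ref in the other
            in_dom = rng.random() < 0.5
            if in_dom:
                geno[i, dom_sl] = _segregating(rng, config.n_dom)
            else:
                geno[i, wild_sl] = _segregating(rng, config.n_wild)

    # covariates are independent of genotype
    r = 1.0 / max(config.coverage_disp, 1e-8)
    coverage = rng.negative_binomial(r, r / (r + config.coverage_mean), (S, n_ind))
    consqual = rng.normal(config.consensus_qual_mean, config.consensus_qual_sd, (S, n_ind))
    mapq = rng.normal(config.mapq_mean, config.mapq_sd, (S, n_ind))
    total_reads = coverage.sum(axis=1)

    n_rep = int(round(config.frac_repeat * 20))
    rep_starts = np.sort(rng.choice(config.chrom_length - 5000, max(n_rep, 1), replace=False))
    rep_len = int(config.frac_repeat * config.chrom_length / max(n_rep, 1))
    repeats = pd.DataFrame({
        "chrom": config.chrom,
        "start": rep_starts,
        "end": np.minimum(rep_starts + max(rep_len, 1), config.chrom_length),
    })
    indel_pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1),
                                   config.n_indels, replace=False))
    indels = pd.DataFrame({"chrom": config.chrom, "pos": indel_pos})

    sites = pd.DataFrame({
        "chrom": config.chrom,
        "pos": pos,
        "ref": _BASES[ref_i],
        "alt": _BASES[alt_i],
        "total_reads": total_reads,
    })
    idx = pd.RangeIndex(S)
    table = SiteTable(
        sites=sites,
        genotypes=pd.DataFrame(geno, index=idx, columns=individuals),
        coverage=pd.DataFrame(coverage, index=idx, columns=individuals),
        consensus_quality=pd.DataFrame(np.round(consqual, 2), index=idx, columns=individuals),
        rms_mapping_quality=pd.DataFrame(np.round(mapq, 2), index=idx, columns=individuals),
        samples=pd.DataFrame({"status": status}, index=pd.Index(individuals, name="sample")),
    )
    truth = pd.DataFrame({"chrom": config.chrom, "pos": pos, "label": labels})
    return table, truth, repeats, indels


# ---------------------------------------------------------------------------
# VCF serialization

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: SiteTable, path) -> None:
    """Write a SiteTable as uncompressed VCF 4.2 with GT:DP:GQ:MQ per sample.

    The output is deterministic (byte-identical for identical inputs).
    """
    individuals = list(table.genotypes.columns)
    chroms = list(dict.fromkeys(table.sites["chrom"]))
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##INFO=<ID=TR,Number=1,Type=Integer,Description="Total supporting reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Consensus quality">',
        '##FORMAT=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals),
    ]
    geno = table.genotypes.to_numpy()
    cov = table.coverage.to_numpy()
    gq = table.consensus_quality.to_numpy()
    mq = table.rms_mapping_quality.to_numpy()
    for i, row in enumerate(table.sites.itertuples(index=False)):
        fields = [row.chrom, str(row.pos), ".", row.ref, row.alt, ".", ".",
                  f"TR={row.total_reads}", "GT:DP:GQ:MQ"]
        for j in range(len(individuals)):
            fields.append(
                f"{_GT_STR[int(geno[i, j])]}:{int(cov[i, j])}:{gq[i, j]:g}:{mq[i, j]:g}"
            )
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> SiteTable:
    """Read a VCF 4.x file with GT:DP:GQ:MQ FORMAT fields into a SiteTable.

    Group status is inferred later from separate metadata; the returned
    ``samples`` frame carries status ``unknown`` for every individual.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    individuals = list(vcf.header.samples)
    rows, geno, cov, gq, mq = [], [], [], [], []
    for rec in vcf:
        tr = rec.info.get("TR", 0)
        rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".",
                     int(tr)))
        g_row, c_row, q_row, m_row = [], [], [], []
        for ind in individuals:
            call = rec.samples[ind]
            alleles = call.get("GT")
            if alleles is None or any(a is None for a in alleles):
                g_row.append(-1)
            else:
                g_row.append(int(sum(alleles)))
            c_row.append(call.get("DP") if call.get("DP") is not None else 0)
            q_row.append(call.get("GQ") if call.get("GQ") is not None else 0.0)
            m_row.append(call.get("MQ") if call.get("MQ") is not None else 0.0)
        geno.append(g_row)
        cov.append(c_row)
        gq.append(q_row)
        mq.append(m_row)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "total_reads"])
    idx = pd.RangeIndex(len(rows))
    return SiteTable(
        sites=sites,
        genotypes=pd.DataFrame(geno, index=idx, columns=individuals, dtype=np.int8),
        coverage=pd.DataFrame(cov, index=idx, columns=individuals),
        consensus_quality=pd.DataFrame(gq, index=idx, columns=individuals, dtype=float),
        rms_mapping_quality=pd.DataFrame(mq, index=idx, columns=individuals, dtype=float),
        samples=pd.DataFrame({"status": "unknown"},
                             index=pd.Index(individuals, name="sample")),
    )
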