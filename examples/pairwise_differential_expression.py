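"""Pairwise differential expression within one domestication event.

Simulates a dog/wolf-style comparison (5 domesticated vs 5 wild brains)
in which 5% of genes truly differ, then runs the count-based DE stage:
median-of-ratios normalization, conservative dispersion estimation, the
NB exact test with BH correction, and the variance-explained summary
with its exhaustive label-permutation p-value.
"""

import numpy as np

import domexpr as dx
from domexpr.permutation import mean_variance_explained_stat

cfg = dx.ExprSimConfig(
    n_pairs=1, samples_per_group=5, n_genes=3000,
    frac_pair_specific_de=0.05, pair_lfc_mean=1.5, seed=1,
)
counts, samples, _, truth = dx.simulate_counts(cfg)
counts = dx.filter_expressed(counts)          # >0 counts in >= half the samples

size_factors = dx.estimate_size_factors(counts)
disp = dx.estimate_dispersions(counts, samples, size_factors)
de = dx.nb_exact_test(counts, samples, disp, size_factors)

vst = dx.variance_stabilize(counts, disp, size_factors)
fits = dx.variance_explained(vst, samples, include_sex=True)
summary = dx.summary_statistics(de, fits, fdr=0.1)
perm = dx.exhaustive_permutation_test(
    mean_variance_explained_stat(include_sex=True), vst, samples
)

truly_de = truth.loc[counts.index, "is_de_pair1"]
called = de["q"] < 0.1
print(f"expressed genes analysed:        {len(de)}")
print(f"DE genes at 10% FDR:             {summary['n_de']} "
      f"(of {int(truly_de.sum())} with a true effect)")
print(f"  recall {100 * (called & truly_de).sum() / truly_de.sum():.0f}%, "
      f"false discoveries {int((called & ~truly_de).sum())}")
print(f"mean variance explained by domestication: "
      f"{100 * summary['mean_variance_fraction']:.1f}%")
print(f"mean absolute fold change:       {summary['mean_abs_fold_change_pct']:.1f}%")
print(f"permutation p (mean variance explained, all "
      f"{perm.n_arrangements} label arrangements): {perm.p:.4f}")
print()
print("The permutation p-value is the fraction of all possible domesticated/"
      "wild label assignments whose mean variance explained matches or "
      "exceeds the observed one; small values mean the domestication "
      "signal is not an artefact of one particular labelling.")
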