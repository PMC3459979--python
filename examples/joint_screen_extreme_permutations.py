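"""The joint multi-pair screen and its extreme-permutation null.

Simulates three species pairs in which 5% of genes carry a shared
domestication effect, fits the three joint models (OLS on
variance-stabilized counts, OLS on log2(FPKM+1), NB GLM LRT), screens
for genes significant in all three with one direction of change in every
pair, and compares the resulting significance curve against all three
whole-pair label flips - the only permutations that preserve within-pair
difference magnitudes.
"""

import numpy as np

import domexpr as dx

cfg = dx.ExprSimConfig(
    n_pairs=3, samples_per_group=5, n_genes=3000,
    frac_shared_de=0.05, shared_lfc_mean=1.0, seed=4,
)
counts, samples, _, truth = dx.simulate_counts(cfg)
counts = dx.filter_expressed(counts)
truth = truth.loc[counts.index]

models = dx.run_joint_models(counts, samples)
screen = dx.screen_domestication_genes(models.p, models.directions, alpha=0.05)
sel = screen["selected"]
shared = truth["is_shared_de"]

print(f"genes analysed: {len(counts)}; truth-shared: {int(shared.sum())}")
print(f"screen selected {int(sel.sum())} domestication-related genes")
print(f"  recall of truth-shared genes: "
      f"{100 * (sel & shared).sum() / shared.sum():.0f}%")
print(f"  false selections: {int((sel & ~shared).sum())}")

vc = dx.joint_variance_components(models.vst, samples)
print("median variance fractions: "
      f"pair {100 * vc['pair_fraction'].median():.1f}%, "
      f"sex {100 * vc['sex_fraction'].median():.2f}%, "
      f"domestication {100 * vc['domestication_fraction'].median():.2f}%")

thresholds = [0.001, 0.01, 0.05, 1.0]
curves = dx.extreme_null_curves(counts, samples, thresholds, model="vst")
print(f"\nconsistent-direction gene counts at p <= {thresholds}:")
print(f"  observed:            {curves['observed'].tolist()}")
for pattern, curve in zip(curves["patterns"], curves["flips"]):
    flipped = [f"pair{i + 1}" for i, f in enumerate(pattern) if f]
    print(f"  flip {','.join(flipped):<14} {curve.tolist()}")
print()
print("When real shared effects exist, the observed curve lies above every "
      "extreme permutation at all thresholds: flipping whole pairs destroys "
      "cross-pair agreement while leaving within-pair differences intact. "
      "The p = 1 column counts direction agreement alone.")
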