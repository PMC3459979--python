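"""Hold-out validation of the domestication-related gene screen.

Simulates four species pairs sharing domestication effects in 10% of
genes, screens on three of them, and asks whether the selected genes
predict the direction of expression change in the held-out fourth pair
(the guinea-pig-style validation). The observed odds ratio is compared
to equally sized gene sets re-selected under each extreme permutation.
"""

import numpy as np

import domexpr as dx

cfg = dx.ExprSimConfig(
    n_pairs=4, samples_per_group=5, n_genes=2000,
    frac_shared_de=0.10, shared_lfc_mean=1.5, seed=5,
)
counts, samples, omap, truth = dx.simulate_counts(cfg)
counts = dx.filter_expressed(counts)
omap = omap.loc[counts.index]

held_pair = "pair4"
train = samples.index[samples["pair"] != held_pair]
held = samples.index[samples["pair"] == held_pair]

models = dx.run_joint_models(counts[train], samples.loc[train])
screen = dx.screen_domestication_genes(models.p, models.directions)

flip_models = [
    dx.run_joint_models(counts[train], dx.apply_flip(samples.loc[train], pattern))
    for pattern in dx.enumerate_extreme_permutations(3)
]

held_expr = np.log2(counts[held] + 1.0)
result = dx.holdout_direction_prediction(
    screen, models, held_expr, samples.loc[held], omap, held_pair,
    flip_models=flip_models,
)
obs = result["observed"]
a, b, c, d = obs.table
print(f"screened genes with an expressed held-out orthologue: {obs.n_universe}")
print(f"selected genes: {result['n_selected']} "
      f"({a} same direction in the held-out pair, {b} opposite)")
print(f"background agreement: {c} same / {d} opposite")
print(f"one-sided FET: OR = {obs.odds_ratio:.1f}, p = {obs.p_one_sided:.2e}")
print("odds ratios from equally sized extreme-permutation selections: "
      + ", ".join(f"{v:.2f}" for v in result["flip_odds_ratios"]))
print()
print("A large observed OR that exceeds every permutation OR says the "
      "screen's genes carry direction information about an independent "
      "domestication event, not just within-training-set structure.")
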