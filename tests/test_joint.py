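import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import domexpr as dx
from domexpr.joint import anova_domestication_pvalues, pair_direction_signs
from tests.conftest import make_samples


def two_pair_samples():
    return make_samples(
        ["A", "A", "A", "A", "B", "B", "B", "B"],
        ["domesticated", "domesticated", "wild", "wild"] * 2,
    )


class TestJointVarianceComponents:
    def test_pure_pair_shift(self):
        samples = two_pair_samples()
        expr = pd.DataFrame([[0, 0, 0, 0, 10, 10, 10, 10]], index=["g"],
                            columns=samples.index, dtype=float)
        vc = dx.joint_variance_components(expr, samples)
        assert vc["pair_fraction"].iloc[0] >= 0.99
        assert vc["domestication_fraction"].iloc[0] <= 0.01

    def test_constant_gene_all_zero(self):
        samples = two_pair_samples()
        expr = pd.DataFrame([[5.0] * 8], index=["g"], columns=samples.index)
        vc = dx.joint_variance_components(expr, samples)
        assert (vc.iloc[0] == 0).all()

    def test_hand_type_one_decomposition(self):
        # y = 1..8, pairs A/B of 4, dom/dom/wild/wild in each:
        # TSS=42, pair SS=32, dom SS=8, residual=2
        samples = two_pair_samples()
        expr = pd.DataFrame([np.arange(1.0, 9.0)], index=["g"],
                            columns=samples.index)
        vc = dx.joint_variance_components(expr, samples)
        assert vc["pair_fraction"].iloc[0] == pytest.approx(32 / 42, abs=1e-12)
        assert vc["sex_fraction"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert vc["domestication_fraction"].iloc[0] == pytest.approx(8 / 42, abs=1e-12)
        assert vc["residual_fraction"].iloc[0] == pytest.approx(2 / 42, abs=1e-12)

    def test_fractions_sum_to_at_most_one(self, small_multi_pair):
        counts, samples, _, _ = small_multi_pair
        expr = np.log2(dx.filter_expressed(counts) + 1.0)
        vc = dx.joint_variance_components(expr, samples)
        totals = vc.sum(axis=1)
        np.testing.assert_allclose(totals.to_numpy(), 1.0, atol=1e-9)
        assert ((vc >= -1e-12) & (vc <= 1 + 1e-12)).all().all()

    def test_single_pair_rejected(self):
        samples = make_samples(["A"] * 4, ["domesticated"] * 2 + ["wild"] * 2)
        expr = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=samples.index)
        with pytest.raises(ValueError, match="pairs"):
            dx.joint_variance_components(expr, samples)

    def test_pair_fraction_invariant_under_every_flip(self, small_multi_pair):
        counts, samples, _, _ = small_multi_pair
        expr = np.log2(dx.filter_expressed(counts) + 1.0)
        base = dx.joint_variance_components(expr, samples)["pair_fraction"]
        for pattern in dx.enumerate_extreme_permutations(3):
            flipped = dx.apply_flip(samples, pattern)
            frac = dx.joint_variance_components(expr, flipped)["pair_fraction"]
            np.testing.assert_allclose(frac.to_numpy(), base.to_numpy(), atol=1e-10)


class TestStructuredPermutation:
    def test_constant_statistic_gives_p_one(self):
        samples = two_pair_samples()
        rng = np.random.default_rng(1)
        # no pair signal at all: observed median fraction is typical
        expr = pd.DataFrame(rng.normal(size=(40, 8)),
                            index=[f"g{i}" for i in range(40)],
                            columns=samples.index)
        res = dx.structured_permutation_test(expr, samples, "domestication",
                                             n_perm=60, seed=2)
        assert 0 < res.p <= 1

    def test_domestication_power_with_shared_effect(self):
        # a shared effect in 10% of genes: the mean-fraction statistic
        # responds (the median is pinned by the unaffected bulk)
        hits = 0
        for seed in range(5):
            cfg = dx.ExprSimConfig(
                n_pairs=3, samples_per_group=5, n_genes=500,
                frac_shared_de=0.10, shared_lfc_mean=1.5, seed=300 + seed,
            )
            counts, samples, _, _ = dx.simulate_counts(cfg)
            expr = np.log2(dx.filter_expressed(counts) + 1.0)
            res = dx.structured_permutation_test(expr, samples, "domestication",
                                                 n_perm=99, seed=seed,
                                                 statistic="mean")
            hits += res.p <= 0.05
        assert hits >= 4  # >= ~80% of seeds

    def test_huge_pair_effect_does_not_leak_into_domestication(self):
        # within-pair permutation keeps the domestication test calibrated
        # even when between-pair differences dominate
        rng = np.random.default_rng(4)
        samples = two_pair_samples()
        pair_shift = np.where(samples["pair"] == "A", 0.0, 100.0)
        expr = pd.DataFrame(
            rng.normal(size=(60, 8)) + pair_shift[None, :],
            index=[f"g{i}" for i in range(60)], columns=samples.index,
        )
        res = dx.structured_permutation_test(expr, samples, "domestication",
                                             n_perm=200, seed=5)
        assert res.p > 0.05

    def test_invalid_factor_rejected(self):
        samples = two_pair_samples()
        expr = pd.DataFrame([[1.0] * 8], index=["g"], columns=samples.index)
        with pytest.raises(ValueError):
            dx.structured_permutation_test(expr, samples, "batch")


def nb_loglik_scalar(y, mu, phi):
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


class TestNbGlmLrt:
    def test_flat_gene_has_p_near_one(self):
        samples = two_pair_samples()
        counts = pd.DataFrame([[20] * 8], index=["g"], columns=samples.index)
        sf = pd.Series(1.0, index=samples.index)
        res = dx.nb_glm_lrt(counts, samples, sf)
        assert res["lrt"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res["p"].iloc[0] > 0.99

    def test_single_pair_matches_grid_search_oracle(self):
        # one pair, unit size factors: the model is two-group NB regression
        # whose group-mean MLEs are the sample means for fixed dispersion
        samples = make_samples(["A"] * 6, ["domesticated"] * 3 + ["wild"] * 3)
        counts = pd.DataFrame(
            [[30, 35, 25, 10, 12, 8],
             [100, 90, 110, 105, 95, 100],
             [5, 0, 3, 9, 14, 12]],
            index=["up", "flat", "down"], columns=samples.index,
        )
        sf = pd.Series(1.0, index=samples.index)
        res = dx.nb_glm_lrt(counts, samples, sf)
        y = counts.to_numpy(dtype=float)
        for i, gene in enumerate(counts.index):
            phi = res["dispersion"].iloc[i]
            dom, wild = y[i, :3], y[i, 3:]
            ll_full = nb_loglik_scalar(dom, dom.mean(), phi) + nb_loglik_scalar(
                wild, wild.mean(), phi
            )
            ll_red = nb_loglik_scalar(y[i], y[i].mean(), phi)
            lrt_oracle = 2.0 * (ll_full - ll_red)
            assert res["lrt"].iloc[i] == pytest.approx(lrt_oracle, abs=1e-4)

    def test_null_pvalues_approximately_uniform(self):
        cfg = dx.ExprSimConfig(n_pairs=3, samples_per_group=5, n_genes=800,
                               dispersion_a0=0.1, dispersion_a1=0.0, seed=77)
        counts, samples, _, _ = dx.simulate_counts(cfg)
        counts = dx.filter_expressed(counts)
        res = dx.nb_glm_lrt(counts, samples)
        p = res["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.06

    def test_shared_effect_detected(self, small_multi_pair):
        counts, samples, _, truth = small_multi_pair
        keep = dx.filter_expressed(counts)
        res = dx.nb_glm_lrt(keep, samples)
        shared = truth.loc[keep.index, "is_shared_de"]
        assert res.loc[shared.to_numpy(), "p"].median() < 0.01


class TestExtremePermutations:
    @pytest.mark.parametrize("k,count", [(1, 0), (2, 1), (3, 3), (4, 7)])
    def test_pattern_counts(self, k, count):
        patterns = dx.enumerate_extreme_permutations(k)
        assert len(patterns) == count

    def test_closed_form_for_k_up_to_ten(self):
        for k in range(1, 11):
            patterns = dx.enumerate_extreme_permutations(k)
            assert len(patterns) == 2 ** (k - 1) - 1
            assert len(set(patterns)) == len(patterns)
            assert all(p[0] is False or p[0] == False for p in patterns)  # noqa: E712
            assert all(any(p) for p in patterns)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            dx.enumerate_extreme_permutations(0)

    def test_flip_preserves_within_pair_difference_magnitude(self, small_multi_pair):
        counts, samples, _, _ = small_multi_pair
        expr = np.log2(dx.filter_expressed(counts) + 1.0)
        base = pair_direction_signs(expr, samples)

        def median_diffs(meta):
            out = {}
            for pr in sorted(meta["pair"].unique()):
                sub = meta[meta["pair"] == pr]
                d = sub.index[sub["status"] == "domesticated"]
                w = sub.index[sub["status"] == "wild"]
                out[pr] = expr[d].median(axis=1) - expr[w].median(axis=1)
            return pd.DataFrame(out)

        observed = median_diffs(samples)
        for pattern in dx.enumerate_extreme_permutations(3):
            flipped = dx.apply_flip(samples, pattern)
            fd = median_diffs(flipped)
            np.testing.assert_allclose(fd.abs().to_numpy(),
                                       observed.abs().to_numpy(), atol=1e-12)
            signs = pair_direction_signs(expr, flipped)
            for flip, pr in zip(pattern, sorted(samples["pair"].unique())):
                expected = -base[pr] if flip else base[pr]
                np.testing.assert_array_equal(signs[pr].to_numpy(),
                                              expected.to_numpy())


class TestScreen:
    def _ps(self, rows):
        return pd.DataFrame(rows, columns=["vst", "fpkm", "nb"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_selection_logic(self):
        ps = self._ps([
            [0.01, 0.04, 0.03],   # significant everywhere
            [0.01, 0.06, 0.03],   # one model misses
            [0.01, 0.04, 0.03],   # inconsistent direction
        ])
        directions = pd.DataFrame(
            [[1, 1, 1], [1, 1, 1], [1, 1, -1]],
            columns=["A", "B", "C"], index=ps.index,
        )
        screen = dx.screen_domestication_genes(ps, directions, alpha=0.05)
        assert screen["selected"].tolist() == [True, False, False]

    def test_zero_sign_excluded_and_counted(self):
        ps = self._ps([[0.01, 0.01, 0.01]])
        directions = pd.DataFrame([[1, 0, 1]], columns=["A", "B", "C"],
                                  index=ps.index)
        screen = dx.screen_domestication_genes(ps, directions)
        assert not screen["selected"].iloc[0]
        assert screen["excluded_zero_sign"].iloc[0]


class TestSignificanceCurve:
    def test_threshold_one_counts_all_consistent(self):
        p = np.array([0.001, 0.5, 0.9, 0.2])
        consistent = np.array([True, True, False, True])
        curve = dx.significance_curve(p, consistent, [0.01, 1.0])
        assert curve.tolist() == [1, 3]

    def test_empty_input(self):
        curve = dx.significance_curve(np.array([]), np.array([], dtype=bool),
                                      [0.05, 1.0])
        assert curve.tolist() == [0, 0]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        consistent = rng.choice([True, False], 500)
        curve = dx.significance_curve(p, consistent, np.linspace(0.001, 1, 20))
        assert (np.diff(curve) >= 0).all()


class TestExtremeNullCurves:
    def test_observed_dominates_with_shared_effects(self):
        cfg = dx.ExprSimConfig(n_pairs=3, samples_per_group=5, n_genes=600,
                               frac_shared_de=0.1, shared_lfc_mean=1.5, seed=55)
        counts, samples, _, _ = dx.simulate_counts(cfg)
        counts = dx.filter_expressed(counts)
        curves = dx.extreme_null_curves(counts, samples, [0.001, 0.01, 0.05],
                                        model="vst")
        for flip_curve in curves["flips"]:
            assert (curves["observed"] >= flip_curve).all()

    def test_pair_specific_effects_fall_inside_envelope(self):
        inside = 0
        for seed in range(5):
            cfg = dx.ExprSimConfig(
                n_pairs=3, samples_per_group=5, n_genes=400,
                frac_pair_specific_de=0.1, frac_shared_de=0.0, seed=500 + seed,
            )
            counts, samples, _, _ = dx.simulate_counts(cfg)
            counts = dx.filter_expressed(counts)
            curves = dx.extreme_null_curves(counts, samples, [0.05], model="vst")
            flips = np.array([c[0] for c in curves["flips"]])
            inside += flips.min() <= curves["observed"][0] <= flips.max()
        assert inside >= 3  # ~70% of seeds


class TestHoldout:
    def _build(self, seed=123):
        cfg = dx.ExprSimConfig(n_pairs=4, samples_per_group=5, n_genes=400,
                               frac_shared_de=0.15, shared_lfc_mean=2.0,
                               seed=seed)
        counts, samples, omap, truth = dx.simulate_counts(cfg)
        counts = dx.filter_expressed(counts)
        held_pair = "pair4"
        train = samples.index[samples["pair"] != held_pair]
        held = samples.index[samples["pair"] == held_pair]
        train_counts = counts[train]
        models = dx.run_joint_models(train_counts, samples.loc[train])
        screen = dx.screen_domestication_genes(models.p, models.directions)
        held_expr = np.log2(counts[held] + 1.0)
        omap = omap.loc[counts.index]
        return models, screen, held_expr, samples.loc[held], omap, held_pair, samples, train_counts

    def test_agreement_is_enriched_and_matches_oracle(self):
        models, screen, held_expr, held_samples, omap, held_pair, *_ = self._build()
        out = dx.holdout_direction_prediction(
            screen, models, held_expr, held_samples, omap, held_pair
        )
        res = out["observed"]
        a, b, c, d = res.table
        assert res.odds_ratio > 1
        from tests.test_crosspair import hypergeom_tail_oracle
        assert res.p_one_sided == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), rel=1e-9
        )

    def test_flip_selections_have_matching_size(self):
        (models, screen, held_expr, held_samples, omap, held_pair,
         samples, train_counts) = self._build()
        train = train_counts.columns
        flip_models = []
        for pattern in dx.enumerate_extreme_permutations(3):
            flipped = dx.apply_flip(samples.loc[train], pattern)
            flip_models.append(dx.run_joint_models(train_counts, flipped))
        out = dx.holdout_direction_prediction(
            screen, models, held_expr, held_samples, omap, held_pair,
            flip_models=flip_models,
        )
        assert len(out["flip_odds_ratios"]) == 3
        assert all(np.isfinite(or_) or or_ == np.inf
                   for or_ in out["flip_odds_ratios"])

    def test_empty_selection_rejected(self):
        models, screen, held_expr, held_samples, omap, held_pair, *_ = self._build()
        screen = screen.copy()
        screen["selected"] = False
        with pytest.raises(ValueError):
            dx.holdout_direction_prediction(
                screen, models, held_expr, held_samples, omap, held_pair
            )
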