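"""Kernels, GBLUP REML, cross-validation, and the marker-set experiments."""

import numpy as np
import pandas as pd
import pytest

from genebankgp import gblup, markers
from genebankgp.gblup import (
    CVResult,
    KernelSet,
    cross_validate,
    experiment_combined,
    experiment_ld_prune,
    experiment_maf,
    experiment_subset,
    fit_gblup,
    predict,
    ssr_kernel,
    vanraden_kernel,
)
from genebankgp.markers import AlleleMatrix

from conftest import toy_genotypes


class TestVanRadenKernel:
    def test_hand_computed_two_individual_case(self):
        g = toy_genotypes([[0.0], [2.0], [0.0], [2.0]])
        g2 = g.subset_individuals([0, 1])
        g2.values = np.array([[0.0, 0.0], [2.0, 2.0]])  # two identical markers
        g2 = toy_genotypes([[0.0, 0.0], [2.0, 2.0]])
        K = vanraden_kernel(g2, stabilization=0.0)
        np.testing.assert_allclose(K, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_duplicated_individuals_have_identical_rows(self, imputed):
        g = imputed["array"]
        dup = toy_genotypes(np.vstack([g.values[:5], g.values[0]]))
        dup, _ = markers.filter_markers(dup)  # drop loci monomorphic in the toy
        K = vanraden_kernel(dup)
        np.testing.assert_allclose(K[0, 1:5], K[5, 1:5], atol=1e-10)

    def test_marker_order_and_allele_label_invariance(self, imputed, rng):
        g = imputed["array"]
        K = vanraden_kernel(g)
        perm = rng.permutation(g.n_markers)
        K_perm = vanraden_kernel(g.subset_markers(perm))
        np.testing.assert_allclose(K, K_perm, atol=1e-10)
        flipped = g.values.copy()
        swap = rng.random(g.n_markers) < 0.5
        flipped[:, swap] = 2.0 - flipped[:, swap]
        K_flip = vanraden_kernel(toy_genotypes(flipped))
        np.testing.assert_allclose(K, K_flip, atol=1e-10)

    def test_trace_reflects_inbreeding(self, platforms, imputed):
        # expected diagonal 1 + f for inbreeding coefficient f
        K = vanraden_kernel(imputed["array"])
        f = 0.95 / (2 - 0.95)
        assert np.trace(K) / K.shape[0] == pytest.approx(1 + f, abs=0.12)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_kernel(toy_genotypes([[0.0, 2.0], [0.0, 0.0]]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="imputed"):
            vanraden_kernel(toy_genotypes([[np.nan, 1.0], [0.0, 2.0]]))


class TestSsrKernel:
    def test_identical_profiles_equal_rows(self):
        a = AlleleMatrix(
            np.array([[1.0, 0.0, 1.0, 0.0]] * 2 + [[0.0, 1.0, 0.0, 1.0]]),
            ["i1", "i2", "i3"],
            ["L1", "L1", "L2", "L2"],
            ["A", "B", "A", "B"],
        )
        K = ssr_kernel(a, stabilization=0.0)
        np.testing.assert_allclose(K[0], K[1], atol=1e-12)

    def test_orthogonal_profiles_negative_off_diagonal(self):
        a = AlleleMatrix(
            np.array([[1.0, 0.0], [0.0, 1.0]]), ["i1", "i2"], ["L", "L"], ["A", "B"]
        )
        K = ssr_kernel(a, stabilization=0.0)
        assert K[0, 1] < 0

    def test_column_permutation_invariance(self, imputed, rng):
        a = imputed["ssr"]
        K = ssr_kernel(a)
        perm = rng.permutation(a.n_columns)
        K2 = ssr_kernel(a.subset_columns(perm))
        np.testing.assert_allclose(K, K2, atol=1e-10)


class TestGblupFit:
    def test_identity_kernel_fixed_ratio_equals_ridge(self, rng):
        n = 40
        y = rng.normal(size=n)
        ks = KernelSet([f"i{k}" for k in range(n)], {"I": np.eye(n)})
        fit = fit_gblup(y, ks, fix_variances={"I": 2.0, "residual": 1.0})
        lam = 0.5  # sigma2_e / sigma2_g
        np.testing.assert_allclose(
            fit.random_effects["I"], (y - y.mean()) / (1 + lam), atol=1e-10
        )

    def test_fixed_components_match_dense_mixed_model_solve(self, imputed, rng):
        g = markers.filter_markers(imputed["array"].subset_individuals(np.arange(50)))[0]
        K = vanraden_kernel(g)
        y = rng.normal(size=50)
        ks = KernelSet(list(g.individual_ids), {"K": K})
        fit = fit_gblup(y, ks, fix_variances={"K": 1.3, "residual": 0.7})
        # oracle: direct dense generalized-least-squares / BLUP solve
        V = 1.3 * K + 0.7 * np.eye(50)
        Vi = np.linalg.inv(V)
        X = np.ones((50, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 1.3 * K @ Vi @ (y - X @ beta.ravel())
        np.testing.assert_allclose(fit.random_effects["K"], u, atol=1e-8)
        assert fit.mu == pytest.approx(beta[0], abs=1e-8)

    def test_pure_noise_shrinks_to_mean(self, snp_kernelset, rng):
        sig = []
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=snp_kernelset.n)
            fit = fit_gblup(y, snp_kernelset)
            sig.append(fit.variance_by_kernel["snp"] / fit.sigma2_e)
            assert np.abs(fit.random_effects["snp"]).max() < np.abs(y - y.mean()).max()
        assert np.mean(sig) < 0.25

    def test_duplicated_kernels_split_variance_keep_predictions(self, snp_kernelset, blues):
        ids = snp_kernelset.individual_ids
        y = blues["y"].loc[ids]
        K = snp_kernelset.kernels["snp"]
        single = fit_gblup(y, snp_kernelset)
        double = fit_gblup(y, KernelSet(list(ids), {"a": K, "b": K.copy()}))
        pred_single = single.random_effects["snp"]
        pred_double = double.random_effects["a"] + double.random_effects["b"]
        np.testing.assert_allclose(pred_single, pred_double, atol=1e-6)

    def test_kernel_count_validated(self, snp_kernelset, blues):
        ids = snp_kernelset.individual_ids
        K = snp_kernelset.kernels["snp"]
        four = {f"k{i}": K for i in range(4)}
        with pytest.raises(ValueError, match="1 to 3"):
            fit_gblup(blues["y"].loc[ids], KernelSet(list(ids), four))


class TestPredict:
    def test_duplicate_of_training_individual(self, imputed, blues):
        g = imputed["array"]
        ids = list(g.individual_ids)
        y = blues["y"].loc[ids]
        K = vanraden_kernel(g)
        n = len(ids)
        train = np.arange(n - 1)
        ks_train = KernelSet(ids[:-1], {"snp": K[np.ix_(train, train)]})
        # scale genetic signal up: high-heritability regime
        fit = fit_gblup(
            y.iloc[:-1], ks_train,
            fix_variances={"snp": 10.0, "residual": 0.01},
        )
        # "test" individual identical to training individual 0
        cross = {"snp": K[np.ix_([0], train)]}
        pred = predict(fit, cross)
        fitted0 = fit.mu + fit.random_effects["snp"][0]
        assert pred[0] == pytest.approx(fitted0, abs=0.05)

    def test_zero_genetic_variance_predicts_mean(self, snp_kernelset, blues):
        ids = snp_kernelset.individual_ids
        y = blues["y"].loc[ids]
        fit = fit_gblup(
            y, snp_kernelset, fix_variances={"snp": 0.0, "residual": 1.0}
        )
        cross = {"snp": snp_kernelset.kernels["snp"][:5]}
        np.testing.assert_allclose(predict(fit, cross), fit.mu, atol=1e-12)

    def test_invariant_to_test_ordering(self, snp_kernelset, blues):
        ids = snp_kernelset.individual_ids
        y = blues["y"].loc[ids]
        fit = fit_gblup(y, snp_kernelset)
        K = snp_kernelset.kernels["snp"]
        test_idx = np.array([3, 7, 11])
        p1 = predict(fit, {"snp": K[test_idx]})
        p2 = predict(fit, {"snp": K[test_idx[::-1]]})
        np.testing.assert_allclose(p1, p2[::-1], atol=1e-12)


class TestCrossValidate:
    def test_noiseless_kernel_signal_recovered(self, snp_kernelset, rng):
        # smooth noiseless signal: dominant kernel eigenvectors (family /
        # population structure), which training sets determine almost exactly
        K = snp_kernelset.kernels["snp"]
        eigval, eigvec = np.linalg.eigh(K)
        top = eigvec[:, -6:] * np.sqrt(eigval[-6:])
        y = top @ rng.normal(size=6)
        cv = cross_validate(y, snp_kernelset, rounds=25, seed=2)
        assert cv.mean_ability >= 0.95

    def test_permuted_phenotypes_give_null_ability(self, snp_kernelset, blues):
        ids = snp_kernelset.individual_ids
        y = blues["y"].loc[ids].to_numpy()
        rng = np.random.default_rng(3)
        yperm = rng.permutation(y)
        cv = cross_validate(yperm, snp_kernelset, rounds=40, seed=3)
        assert abs(cv.mean_ability) < 2 * cv.sd_ability / np.sqrt(40) + 0.1

    def test_seeded_determinism(self, snp_kernelset, blues):
        y = blues["y"].loc[snp_kernelset.individual_ids]
        a = cross_validate(y, snp_kernelset, rounds=6, seed=9)
        b = cross_validate(y, snp_kernelset, rounds=6, seed=9)
        np.testing.assert_array_equal(
            a.per_round_correlations, b.per_round_correlations
        )

    def test_kfold_scheme_covers_every_individual(self, snp_kernelset, blues):
        y = blues["y"].loc[snp_kernelset.individual_ids]
        cv = cross_validate(y, snp_kernelset, rounds=1, seed=4, scheme="kfold")
        assert cv.per_round_correlations.size == 5

    def test_small_panels_rejected(self):
        ks = KernelSet([f"i{k}" for k in range(10)], {"I": np.eye(10)})
        with pytest.raises(ValueError, match="25"):
            cross_validate(np.arange(10.0), ks, rounds=2, seed=0)


class TestExperiments:
    def test_subset_of_all_markers_equals_full_ability(self, imputed, blues):
        g = imputed["array"]
        y = blues["y"].loc[g.individual_ids]
        full = cross_validate(
            y, KernelSet(list(g.individual_ids), {"subset": vanraden_kernel(g)}),
            rounds=6, seed=5,
        )
        res, table = experiment_subset(
            y, g, n_markers=g.n_markers, repeats=1, cv_rounds=6, seed=5
        )
        assert table["mean_ability"].iloc[0] == pytest.approx(full.mean_ability, abs=1e-9)

    def test_sparse_subsets_lose_ability(self, imputed, blues):
        g = imputed["array"]
        y = blues["y"].loc[g.individual_ids]
        full = cross_validate(
            y, KernelSet(list(g.individual_ids), {"k": vanraden_kernel(g)}),
            rounds=10, seed=6,
        )
        _, table = experiment_subset(y, g, n_markers=40, repeats=3,
                                     cv_rounds=10, seed=6)
        assert table["mean_ability"].mean() < full.mean_ability

    def test_maf_threshold_zero_equals_full_set(self, imputed, blues):
        g = imputed["gbs"]
        y = blues["y"].loc[g.individual_ids]
        table = experiment_maf(y, g, thresholds=[0.0], cv_rounds=6, seed=7)
        full = cross_validate(
            y, KernelSet(list(g.individual_ids), {"maf": vanraden_kernel(g)}),
            rounds=6, seed=7,
        )
        assert table["mean_ability"].iloc[0] == pytest.approx(full.mean_ability, abs=1e-9)
        assert table["n_markers"].iloc[0] == g.n_markers

    def test_interval_mode_counts_partition_markers(self, imputed, blues):
        g = imputed["gbs"]
        y = blues["y"].loc[g.individual_ids]
        table = experiment_maf(
            y, g, thresholds=[0.0, 0.05, 0.2, 0.5], mode="interval",
            cv_rounds=2, seed=8,
        )
        assert table["n_markers"].sum() == g.n_markers

    def test_ld_prune_removes_duplicates_keeps_independent(self, rng):
        n = 120
        a_vals = rng.choice([0.0, 2.0], size=(n, 30))
        b_vals = rng.choice([0.0, 2.0], size=(n, 30))
        b_vals[:, 0] = a_vals[:, 0]  # duplicated marker -> r2 = 1
        a = toy_genotypes(a_vals)
        b = markers.GenotypeMatrix(
            b_vals, list(a.individual_ids), [f"g{j}" for j in range(30)], "gbs"
        )
        pruned, report = experiment_ld_prune(a, b, r2_max=0.95)
        assert report["n_removed"] == 1
        assert "g0" not in pruned.marker_ids

    def test_r2_matches_bruteforce(self, rng):
        n = 10
        a_vals = rng.choice([0.0, 1.0, 2.0], size=(n, 10))
        b_vals = rng.choice([0.0, 1.0, 2.0], size=(n, 10))
        a, b = toy_genotypes(a_vals), toy_genotypes(b_vals)
        b.platform_tag = "gbs"
        from genebankgp.gblup import _standardize

        r = (_standardize(a_vals).T @ _standardize(b_vals)) / n
        for i in range(10):
            for j in range(10):
                expect = np.corrcoef(a_vals[:, i], b_vals[:, j])[0, 1]
                assert r[i, j] == pytest.approx(expect, abs=1e-10)

    def test_combined_identical_platforms_equal_single(self, imputed, blues):
        g = imputed["array"]
        y = blues["y"].loc[g.individual_ids]
        out = experiment_combined(g, g, y, cv_rounds=6, seed=9)
        single = cross_validate(
            y, KernelSet(list(g.individual_ids), {"cgs": vanraden_kernel(g)}),
            rounds=6, seed=9,
        )
        assert out["cgs"].mean_ability == pytest.approx(single.mean_ability, abs=1e-6)


def test_cv_ability_monotone_in_heritability(snp_kernelset, rng):
    """Mean ability rises with simulated heritability (paired partitions)."""
    K = snp_kernelset.kernels["snp"]
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    g_true = L @ rng.normal(size=n)
    g_true = (g_true - g_true.mean()) / g_true.std()
    noise = rng.normal(size=n)
    abilities = []
    for h2 in (0.1, 0.3, 0.5, 0.8):
        y = np.sqrt(h2) * g_true + np.sqrt(1 - h2) * noise
        cv = cross_validate(y, snp_kernelset, rounds=30, seed=12)
        abilities.append(cv.mean_ability)
    assert np.all(np.diff(abilities) > 0)
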