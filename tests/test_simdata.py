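"""Synthetic-data generator: drift, ascertainment, GBS artefacts, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from genebankgp import diversity as div
from genebankgp import simdata
from genebankgp.simdata import (
    Architecture,
    Bottleneck,
    PanelSpec,
    SimConfig,
    TrialDesign,
    VarianceSpec,
    ascertain_array_markers,
    sample_gbs_markers,
    simulate_phenotypes,
    simulate_population,
    simulate_ssr,
)

from conftest import small_config, toy_genotypes


class TestSimulatePopulation:
    def test_seeded_determinism_is_bit_identical(self):
        cfg = small_config(seed=42)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
        assert a.ssr_raw.equals(b.ssr_raw)
        assert (a.labels == b.labels).all()

    def test_no_drift_equal_lineages_have_matching_spectra(self):
        # zero drift anywhere: elite and PGR frequencies share one law and the
        # realized mean |difference| shrinks with sample size
        def mean_abs_diff(n, seed):
            cfg = SimConfig(
                n_elite=n, n_pgr=n, n_loci=400,
                elite_bottleneck=Bottleneck(100, 0),
                pgr_bottleneck=Bottleneck(100, 0),
                n_families=1, family_bottleneck=Bottleneck(100, 0),
                n_ssr_loci=2, seed=seed,
            )
            pop = simulate_population(cfg)
            el = pop.genotypes.values[pop.labels == "elite"].mean(axis=0) / 2
            pg = pop.genotypes.values[pop.labels == "pgr"].mean(axis=0) / 2
            return np.abs(el - pg).mean()

        small = np.mean([mean_abs_diff(30, s) for s in range(4)])
        large = np.mean([mean_abs_diff(300, s) for s in range(4)])
        assert large < small
        assert large < 0.05

    def test_default_profile_pgr_more_diverse(self):
        # Monte-Carlo directional check over >= 20 seeds
        wins = 0
        for seed in range(20):
            cfg = SimConfig(
                n_elite=40, n_pgr=40, n_loci=300, n_families=4,
                n_ssr_loci=2, seed=seed,
            )
            pop = simulate_population(cfg)
            el = pop.genotypes.values[pop.labels == "elite"].mean(axis=0) / 2
            pg = pop.genotypes.values[pop.labels == "pgr"].mean(axis=0) / 2
            h_el = (2 * el * (1 - el)).mean()
            h_pg = (2 * pg * (1 - pg)).mean()
            wins += h_pg > h_el
        assert wins >= 18

    def test_inbreeding_gives_mostly_homozygous_lines(self):
        pop = simulate_population(small_config(seed=5))
        het = (pop.genotypes.values == 1).mean()
        assert het < 0.08

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(small_config(selfing=1.5))
        with pytest.raises(ValueError):
            simulate_population(small_config(n_loci=0))


class TestAscertainment:
    def test_full_panel_zero_threshold_keeps_all_polymorphic(self):
        pop = simulate_population(small_config(seed=6))
        idx = ascertain_array_markers(
            pop.genotypes,
            panel_individuals=np.arange(pop.genotypes.n_individuals),
            min_panel_maf=0.0,
        )
        p = pop.genotypes.values.mean(axis=0) / 2
        expected = np.where((p > 0) & (p < 1))[0]
        np.testing.assert_array_equal(idx, expected)

    def test_locus_monomorphic_in_panel_is_excluded(self):
        # locus 0 monomorphic among panel (first 2 rows), polymorphic later
        values = np.array(
            [[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0]]
        )
        g = toy_genotypes(values)
        idx = ascertain_array_markers(
            g, panel_individuals=np.array([0, 1]), min_panel_maf=0.0
        )
        np.testing.assert_array_equal(idx, [1])

    def test_elite_panel_inflates_retained_maf(self):
        # mean full-population MAF of retained loci exceeds that of all
        # polymorphic loci (Monte-Carlo, directional)
        wins = 0
        for seed in range(10):
            pop = simulate_population(small_config(seed=100 + seed))
            p = pop.genotypes.values.mean(axis=0) / 2
            maf = np.minimum(p, 1 - p)
            poly = (p > 0) & (p < 1)
            idx = ascertain_array_markers(
                pop.genotypes, labels=pop.labels,
                panel_spec=PanelSpec(20, 1.0), min_panel_maf=0.05,
                seed=seed,
            )
            wins += maf[idx].mean() > maf[poly].mean()
        assert wins >= 9

    def test_empty_panel_rejected(self):
        pop = simulate_population(small_config(seed=6))
        with pytest.raises(ValueError, match="empty"):
            ascertain_array_markers(
                pop.genotypes, panel_individuals=np.array([], dtype=int)
            )


class TestGbsSampling:
    def test_identity_limit_is_truth_submatrix(self):
        pop = simulate_population(small_config(seed=7))
        g = sample_gbs_markers(pop.genotypes, 100, missing_rate=0.0,
                               het_undercall=0.0, seed=1)
        cols = [pop.genotypes.marker_ids.index(m) for m in g.marker_ids]
        np.testing.assert_array_equal(
            g.values, pop.genotypes.values[:, cols]
        )

    def test_missing_rate_realized(self):
        pop = simulate_population(small_config(seed=8))
        g = sample_gbs_markers(pop.genotypes, 400, missing_rate=0.2,
                               het_undercall=0.0, seed=2)
        frac = np.isnan(g.values).mean()
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_gbs_keeps_more_rare_mass_than_array(self):
        for seed in (11, 12, 13):
            pop = simulate_population(small_config(seed=seed))
            idx = ascertain_array_markers(
                pop.genotypes, labels=pop.labels, seed=seed
            )
            gbs = sample_gbs_markers(pop.genotypes, 500, seed=seed)
            from genebankgp.markers import filter_markers

            arr_sp = div.maf_spectrum(pop.genotypes.subset_markers(idx))
            gbs_f, _ = filter_markers(gbs)
            gbs_sp = div.maf_spectrum(gbs_f)
            assert gbs_sp["fraction"][0] > arr_sp["fraction"][0]

    def test_rates_validated(self):
        pop = simulate_population(small_config(seed=7))
        with pytest.raises(ValueError, match="rates"):
            sample_gbs_markers(pop.genotypes, 10, missing_rate=1.5)
        with pytest.raises(ValueError, match="exceeds"):
            sample_gbs_markers(pop.genotypes, 10**6)


class TestSsr:
    def test_fully_selfed_lines_carry_one_allele_per_locus(self):
        cfg = small_config(seed=9, selfing=1.0)
        a = simulate_ssr(cfg)
        for locus in a.loci:
            cols = a.columns_of_locus(locus)
            sums = np.nansum(a.values[:, cols], axis=1)
            assert (sums == 1).all()

    def test_total_columns_track_allele_law(self):
        cfg = SimConfig(n_elite=100, n_pgr=100, n_loci=10, n_ssr_loci=19,
                        ssr_alleles_per_locus=9.0, n_families=4, seed=10)
        a = simulate_ssr(cfg)
        # observed allele columns per locus close to the configured mean
        assert 19 * 5 <= a.n_columns <= 19 * 12
        assert len(a.loci) == 19

    def test_seeded_determinism(self):
        cfg = small_config(seed=14)
        a = simulate_ssr(cfg)
        b = simulate_ssr(cfg)
        np.testing.assert_array_equal(a.values, b.values)


class TestPhenotypes:
    def test_noiseless_limit_equals_mean_plus_genetic_value(self):
        pop = simulate_population(small_config(seed=15))
        variances = VarianceSpec(genotype=1.0, gxe=0.0, error=0.0,
                                 environment=0.0, replicate=0.0, block=0.0)
        table, truth = simulate_phenotypes(
            pop.genotypes, variances=variances,
            design=TrialDesign(n_environments=1, n_replicates=1, n_blocks=2),
            seed=3, mean=10.0,
        )
        tbv = truth.true_breeding_values
        merged = table.set_index("genotype")["value"]
        np.testing.assert_allclose(
            merged[tbv.index].to_numpy(), 10.0 + tbv.to_numpy(), atol=1e-10
        )

    def test_realized_genetic_variance_matches_configuration(self):
        pop = simulate_population(small_config(seed=16))
        _, truth = simulate_phenotypes(pop.genotypes, seed=4)
        assert truth.true_breeding_values.var(ddof=1) == pytest.approx(1.0)

    def test_rare_architecture_concentrates_causal_loci(self):
        pop = simulate_population(small_config(seed=17))
        _, truth = simulate_phenotypes(
            pop.genotypes,
            architecture=Architecture(causal_fraction=0.2, rare_enriched=True),
            seed=5,
        )
        p = pop.genotypes.values.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        causal = truth.causal_effects != 0
        assert (maf[causal] < 0.05).all()

    def test_negative_variances_rejected(self):
        pop = simulate_population(small_config(seed=15))
        with pytest.raises(ValueError, match=">= 0"):
            simulate_phenotypes(
                pop.genotypes, variances=VarianceSpec(error=-1.0), seed=0
            )

    def test_heritability_plug_in_converges_with_replicates(self):
        # empirical H2 from recovered components approaches the plug-in value
        from genebankgp import phenostat

        cfg = SimConfig(n_elite=60, n_pgr=60, n_loci=200, n_families=6,
                        n_ssr_loci=2, seed=18)
        pop = simulate_population(cfg)
        table, _ = simulate_phenotypes(
            pop.genotypes,
            design=TrialDesign(n_environments=8, n_replicates=3, n_blocks=6),
            seed=6,
        )
        b1 = phenostat.fit_stage1_all(table, "trait")
        _, vc = phenostat.fit_stage2(b1, plots=table)
        plug_in = phenostat.heritability(1.0, 0.5, 1.0, 8, 3)
        assert vc.H2 == pytest.approx(plug_in, abs=0.06)


def test_platform_set_is_deterministic():
    a = simdata.simulate_platforms(small_config(seed=19), gbs_markers=200)
    b = simdata.simulate_platforms(small_config(seed=19), gbs_markers=200)
    np.testing.assert_array_equal(a.array.values, b.array.values)
    np.testing.assert_array_equal(a.gbs.values, b.gbs.values)
    np.testing.assert_array_equal(a.ssr.values, b.ssr.values)
    assert a.array.platform_tag == "array"
    assert a.gbs.platform_tag == "gbs"
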