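"""Shared fixtures: one simulated three-platform panel reused across modules."""

import numpy as np
import pandas as pd
import pytest

from genebankgp import gblup, markers, phenostat, simdata

SEED = 1


def small_config(seed=SEED, **kw):
    base = dict(
        n_elite=60,
        n_pgr=60,
        n_loci=600,
        n_families=6,
        n_ssr_loci=6,
        seed=seed,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def platforms():
    """Default-profile panel at reduced genome size (one-time cost)."""
    return simdata.simulate_platforms(
        small_config(n_elite=90, n_pgr=90, n_loci=1200), gbs_markers=1000
    )


@pytest.fixture(scope="session")
def imputed(platforms):
    arr = markers.impute_by_frequency(
        markers.filter_markers(platforms.array)[0], seed=SEED + 1
    )
    gbs = markers.impute_by_frequency(
        markers.filter_markers(platforms.gbs)[0], seed=SEED + 2
    )
    ssr = markers.impute_allele_matrix(
        markers.filter_markers(platforms.ssr)[0], seed=SEED + 3
    )
    return {"array": arr, "gbs": gbs, "ssr": ssr}


@pytest.fixture(scope="session")
def blues(platforms):
    """Across-environment BLUEs for a default-variance trait on the panel."""
    table, truth = simdata.simulate_phenotypes(
        platforms.truth,
        design=simdata.TrialDesign(n_environments=4, n_replicates=2, n_blocks=6),
        seed=SEED + 10,
    )
    b1 = phenostat.fit_stage1_all(table, "trait")
    across, vc = phenostat.fit_stage2(b1, plots=table)
    y = pd.Series(across["value"].to_numpy(), index=across["genotype"].tolist())
    return {"y": y, "truth": truth, "vc": vc, "plots": table}


@pytest.fixture(scope="session")
def snp_kernelset(imputed):
    g = imputed["array"]
    return gblup.KernelSet(
        list(g.individual_ids), {"snp": gblup.vanraden_kernel(g)}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def toy_genotypes(values, tag="other"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return markers.GenotypeMatrix(
        values,
        [f"i{k}" for k in range(n)],
        [f"m{j}" for j in range(m)],
        tag,
    )
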