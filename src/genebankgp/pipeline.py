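"""Declarative, seeded end-to-end pipeline with a run manifest.

A single YAML (or dict) config drives the fixed stage order
simulate -> qc -> diversity + structure -> phenotypes -> prediction ->
experiments.  Every stage writes tab-separated tables into the output
directory and records them (with SHA-256 checksums) in ``manifest.json``;
rerunning the same config and seed reproduces the tables byte for byte.
Unknown config keys are rejected before any computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import gblup, markers, phenostat, simdata, structure

log = logging.getLogger("genebankgp")

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "output_dir": "results/run",
    "seed": 1,
    "stages": {
        "qc": True,
        "diversity": True,
        "structure": True,
        "phenotypes": True,
        "prediction": True,
        "experiments": True,
    },
    "simulation": {
        "n_elite": 190,
        "n_pgr": 188,
        "n_loci": 4000,
        "founder_beta": [0.2, 0.2],
        "elite_ne": 30,
        "elite_generations": 10,
        "pgr_ne": 300,
        "pgr_generations": 10,
        "n_families": 15,
        "family_ne": 10,
        "family_generations": 3,
        "n_ssr_loci": 19,
        "ssr_alleles_per_locus": 9.0,
        "selfing": 0.95,
        "linkage_block_size": 1,
        "block_copy_error": 0.02,
        "array": {"panel_n": 30, "panel_elite_fraction": 0.8, "min_panel_maf": 0.05},
        "gbs": {"n_markers": 3500, "missing_rate": 0.02, "het_undercall": 0.3},
        "traits": [
            {"name": "yield_like", "causal_fraction": 0.1, "rare_enriched": False},
            {"name": "height_like", "causal_fraction": 0.05, "rare_enriched": False},
        ],
        "variances": {
            "genotype": 1.0,
            "gxe": 0.5,
            "error": 1.0,
            "environment": 1.0,
            "replicate": 0.1,
            "block": 0.1,
        },
        "design": {"n_environments": 8, "n_replicates": 2, "n_blocks": 10},
    },
    "qc": {"max_missing": 0.05},
    "diversity": {"bootstrap_rounds": 200},
    "phenotypes": {"outlier_alpha": 0.05},
    "prediction": {"cv_rounds": 20, "folds": 5, "scheme": "resample"},
    "experiments": {
        "subset_n_markers": 158,
        "subset_repeats": 3,
        "maf_thresholds": [0.0, 0.05, 0.1, 0.2],
        "ld_r2_max": 0.95,
        "cv_rounds": 20,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    return _merge(DEFAULT_CONFIG, config or {})


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, config: dict, output_dir=None, seed=None):
        self.config = validate_config(config)
        if output_dir is not None:
            self.config["output_dir"] = str(output_dir)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.out = Path(self.config["output_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": self.config["seed"],
            "config": self.config,
            "stages": {},
        }
        self.state: dict = {}

    def write(self, stage: str, name: str, df: pd.DataFrame, index=False) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        self.manifest["stages"].setdefault(stage, {}).setdefault("files", {})[
            name
        ] = _sha256(path)
        return path

    def done(self, stage: str, **params) -> None:
        self.manifest["stages"].setdefault(stage, {})["params"] = params
        log.info("stage %s complete", stage)

    def save_manifest(self) -> Path:
        path = self.out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return path


def _sim_config(sim: dict, seed: int) -> simdata.SimConfig:
    return simdata.SimConfig(
        n_elite=sim["n_elite"],
        n_pgr=sim["n_pgr"],
        n_loci=sim["n_loci"],
        founder_maf_law=tuple(sim["founder_beta"]),
        elite_bottleneck=simdata.Bottleneck(sim["elite_ne"], sim["elite_generations"]),
        pgr_bottleneck=simdata.Bottleneck(sim["pgr_ne"], sim["pgr_generations"]),
        n_families=sim["n_families"],
        family_bottleneck=simdata.Bottleneck(
            sim["family_ne"], sim["family_generations"]
        ),
        n_ssr_loci=sim["n_ssr_loci"],
        ssr_alleles_per_locus=sim["ssr_alleles_per_locus"],
        selfing=sim["selfing"],
        linkage_block_size=sim["linkage_block_size"],
        block_copy_error=sim["block_copy_error"],
        seed=seed,
    )


def stage_simulate(run: _Run) -> None:
    cfg = run.config
    sim = cfg["simulation"]
    sc = _sim_config(sim, cfg["seed"])
    platforms = simdata.simulate_platforms(
        sc,
        gbs_markers=sim["gbs"]["n_markers"],
        gbs_missing_rate=sim["gbs"]["missing_rate"],
        gbs_het_undercall=sim["gbs"]["het_undercall"],
        panel_spec=simdata.PanelSpec(
            sim["array"]["panel_n"], sim["array"]["panel_elite_fraction"]
        ),
        min_panel_maf=sim["array"]["min_panel_maf"],
    )
    pop = platforms
    array_g, gbs_g, ssr = platforms.array, platforms.gbs, platforms.ssr

    variances = simdata.VarianceSpec(**sim["variances"])
    design = simdata.TrialDesign(**sim["design"])
    pheno_parts, truths = [], {}
    for t, trait in enumerate(sim["traits"]):
        arch = simdata.Architecture(
            causal_fraction=trait["causal_fraction"],
            rare_enriched=trait.get("rare_enriched", False),
        )
        table, truth = simdata.simulate_phenotypes(
            pop.truth,
            architecture=arch,
            variances=variances,
            design=design,
            seed=cfg["seed"] + 10 + t,
            trait=trait["name"],
        )
        pheno_parts.append(table)
        truths[trait["name"]] = truth
    phenotypes = pd.concat(pheno_parts, ignore_index=True)

    run.state.update(
        pop=pop, array_g=array_g, gbs_g=gbs_g, ssr=ssr,
        phenotypes=phenotypes, truths=truths,
    )
    run.write("simulate", "labels.tsv",
              pd.DataFrame({"individual": pop.truth.individual_ids,
                            "population": pop.labels,
                            "family": pop.families}))
    run.write("simulate", "array_dosage.tsv", array_g.to_frame(), index=True)
    run.write("simulate", "gbs_dosage.tsv", gbs_g.to_frame(), index=True)
    run.write("simulate", "ssr_calls.tsv", pop.ssr_raw)
    run.write("simulate", "phenotypes.tsv", phenotypes)
    tbv = pd.DataFrame({name: t.true_breeding_values for name, t in truths.items()})
    tbv.index.name = "individual"
    run.write("simulate", "true_breeding_values.tsv", tbv, index=True)
    markers.write_vcf(array_g, run.out / "array.vcf")
    run.manifest["stages"]["simulate"]["files"]["array.vcf"] = _sha256(
        run.out / "array.vcf"
    )
    run.done("simulate", seed=cfg["seed"], n_array_markers=array_g.n_markers,
             n_gbs_markers=gbs_g.n_markers, n_ssr_columns=ssr.n_columns)


def stage_qc(run: _Run) -> None:
    cfg = run.config
    max_missing = cfg["qc"]["max_missing"]
    filtered, reports = {}, []
    for name, g in (("array", run.state["array_g"]), ("gbs", run.state["gbs_g"]),
                    ("ssr", run.state["ssr"])):
        f, rep = markers.filter_markers(g, max_missing=max_missing)
        filtered[name] = f
        reports.append(rep.to_frame().assign(platform=name))
    run.state["filtered"] = filtered
    run.state["imputed"] = {
        "array": markers.impute_by_frequency(filtered["array"], seed=cfg["seed"] + 20),
        "gbs": markers.impute_by_frequency(filtered["gbs"], seed=cfg["seed"] + 21),
        "ssr": markers.impute_allele_matrix(filtered["ssr"], seed=cfg["seed"] + 22),
    }
    run.write("qc", "filter_report.tsv", pd.concat(reports, ignore_index=True))
    run.done("qc", max_missing=max_missing)


def stage_diversity(run: _Run) -> None:
    cfg = run.config
    rounds = cfg["diversity"]["bootstrap_rounds"]
    labels = run.state["pop"].labels
    tables, spectra = [], []
    for name, g in run.state["filtered"].items():
        t = div.diversity_summary(g, labels=labels, rounds=rounds, seed=cfg["seed"])
        tables.append(t.assign(platform=name))
        spectra.append(div.maf_spectrum(g).assign(platform=name, population="All"))
        run.state.setdefault("distances", {})[name] = div.rogers_distance(g)
    run.state["diversity_table"] = pd.concat(tables, ignore_index=True)
    run.write("diversity", "diversity_summary.tsv", run.state["diversity_table"])
    run.write("diversity", "maf_spectra.tsv", pd.concat(spectra, ignore_index=True))
    for name, d in run.state["distances"].items():
        run.write("diversity", f"rogers_{name}.tsv", d.to_frame(), index=True)
    run.done("diversity", bootstrap_rounds=rounds)


def stage_structure(run: _Run) -> None:
    distances = run.state.get("distances")
    if not distances:
        raise RuntimeError("structure stage requires the diversity stage")
    coords, eigens, mantel_rows = [], [], []
    for name, d in distances.items():
        res = structure.pcoa(d, n_axes=3)
        coords.append(res.to_frame().reset_index().assign(platform=name))
        eigens.append(res.eigen_frame().assign(platform=name))
        run.state.setdefault("pcoa", {})[name] = res
    names = list(distances)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            mantel_rows.append(
                {"pair": f"{a}-{b}",
                 "mantel_r": structure.mantel(distances[a], distances[b])}
            )
    run.write("structure", "pcoa_coordinates.tsv", pd.concat(coords, ignore_index=True))
    run.write("structure", "pcoa_eigenvalues.tsv", pd.concat(eigens, ignore_index=True))
    run.write("structure", "mantel.tsv", pd.DataFrame(mantel_rows))
    run.done("structure")


def stage_phenotypes(run: _Run) -> None:
    cfg = run.config
    phenotypes = run.state["phenotypes"]
    flagged = phenostat.detect_outliers_bh_madr(
        phenotypes, alpha=cfg["phenotypes"]["outlier_alpha"]
    )
    clean = phenostat.remove_outliers(phenotypes, flagged)
    blues1, across_parts, vc_rows = [], [], []
    for trait in dict.fromkeys(clean["trait"]):
        b1 = phenostat.fit_stage1_all(clean, trait)
        blues1.append(b1)
        across, vc = phenostat.fit_stage2(b1, plots=clean, trait=trait)
        across_parts.append(across)
        vc_rows.append(vc.to_frame().assign(trait=trait))
    run.state["blues"] = pd.concat(across_parts, ignore_index=True)
    run.write("phenotypes", "outliers.tsv", flagged)
    run.write("phenotypes", "blues_stage1.tsv", pd.concat(blues1, ignore_index=True))
    run.write("phenotypes", "blues_across.tsv", run.state["blues"])
    run.write("phenotypes", "variance_components.tsv",
              pd.concat(vc_rows, ignore_index=True))
    run.done("phenotypes", outlier_alpha=cfg["phenotypes"]["outlier_alpha"],
             n_flagged=len(flagged))


def _kernels(run: _Run) -> gblup.KernelSet:
    imp = run.state["imputed"]
    ids = list(imp["array"].individual_ids)
    return gblup.KernelSet(
        ids,
        {
            "snp": gblup.vanraden_kernel(imp["array"]),
            "gbs": gblup.vanraden_kernel(imp["gbs"]),
            "ssr": gblup.ssr_kernel(imp["ssr"]),
        },
    )


def _trait_y(run: _Run, trait: str) -> pd.Series:
    blues = run.state["blues"]
    sub = blues[blues["trait"] == trait]
    return pd.Series(sub["value"].to_numpy(), index=sub["genotype"].tolist())


def stage_prediction(run: _Run) -> None:
    cfg = run.config
    pred = cfg["prediction"]
    ks = _kernels(run)
    run.state["kernels"] = ks
    models = {
        "S": ["snp"], "G": ["gbs"], "SSR": ["ssr"],
        "S-G": ["snp", "gbs"], "S-S": ["snp", "ssr"], "G-S": ["gbs", "ssr"],
        "S-G-S": ["snp", "gbs", "ssr"],
    }
    rows = []
    for trait in dict.fromkeys(run.state["blues"]["trait"]):
        y = _trait_y(run, trait)
        common = [i for i in ks.individual_ids if i in set(y.index)]
        idx = [ks.individual_ids.index(i) for i in common]
        ksub = ks.subset(idx)
        for model, names in models.items():
            sub = gblup.KernelSet(
                list(ksub.individual_ids), {n: ksub.kernels[n] for n in names}
            )
            cv = gblup.cross_validate(
                y, sub, folds=pred["folds"], rounds=pred["cv_rounds"],
                seed=cfg["seed"], scheme=pred["scheme"],
            )
            rows.append(
                {"trait": trait, "model": model, "kernels": "+".join(names),
                 "rounds": cv.rounds, "mean_ability": cv.mean_ability,
                 "sd_ability": cv.sd_ability, "seed": cfg["seed"]}
            )
    run.state["prediction_table"] = pd.DataFrame(rows)
    run.write("prediction", "prediction_ability.tsv", run.state["prediction_table"])
    for name, K in ks.kernels.items():
        run.write(
            "prediction", f"kernel_{name}.tsv",
            pd.DataFrame(K, index=ks.individual_ids, columns=ks.individual_ids),
            index=True,
        )
    run.done("prediction", **pred)


def stage_experiments(run: _Run) -> None:
    cfg = run.config
    exp = cfg["experiments"]
    imp = run.state["imputed"]
    trait = run.state["blues"]["trait"].iloc[0]
    y = _trait_y(run, trait)

    _, subset_table = gblup.experiment_subset(
        y, imp["array"], n_markers=min(exp["subset_n_markers"], imp["array"].n_markers),
        repeats=exp["subset_repeats"], cv_rounds=exp["cv_rounds"], seed=cfg["seed"],
    )
    maf_table = gblup.experiment_maf(
        y, imp["gbs"], thresholds=exp["maf_thresholds"], mode="cumulative",
        cv_rounds=exp["cv_rounds"], seed=cfg["seed"],
    )
    pruned, report = gblup.experiment_ld_prune(
        imp["array"], imp["gbs"], r2_max=exp["ld_r2_max"]
    )
    combined = gblup.experiment_combined(
        imp["array"], pruned, y, cv_rounds=exp["cv_rounds"], seed=cfg["seed"]
    )
    run.write("experiments", "subset_158.tsv", subset_table.assign(trait=trait))
    run.write("experiments", "maf_experiment.tsv", maf_table.assign(trait=trait))
    run.write("experiments", "ld_prune_report.tsv", pd.DataFrame([report]))
    run.write(
        "experiments", "combined_vs_two_kernel.tsv",
        pd.concat(
            [combined["cgs"].to_frame().assign(model="CGS"),
             combined["two_kernel"].to_frame().assign(model="S-G.LD")],
            ignore_index=True,
        ).assign(trait=trait),
    )
    run.done("experiments", **{k: v for k, v in exp.items()})


_STAGE_FUNCS = {
    "qc": stage_qc,
    "diversity": stage_diversity,
    "structure": stage_structure,
    "phenotypes": stage_phenotypes,
    "prediction": stage_prediction,
    "experiments": stage_experiments,
}

# phenotypes must precede prediction (BLUEs are the response)
_STAGE_ORDER = ["qc", "diversity", "structure", "phenotypes", "prediction", "experiments"]


def run_pipeline(config: dict, output_dir=None, seed=None, only=None) -> dict:
    """Execute the pipeline stages in fixed order; returns the manifest.

    ``only`` restricts execution to a subset of stages (the simulate stage
    always runs — it defines the data everything else consumes).  A stage
    failure aborts the run but the manifest of completed stages is written.
    """
    run = _Run(config, output_dir=output_dir, seed=seed)
    try:
        stage_simulate(run)
        for name in _STAGE_ORDER:
            if only is not None and name not in only:
                continue
            if only is None and not run.config["stages"].get(name, True):
                continue
            deps = {"structure": ["qc", "diversity"], "prediction": ["qc", "phenotypes"],
                    "experiments": ["qc", "phenotypes"]}.get(name, [])
            for dep in deps:
                if dep not in run.manifest["stages"]:
                    _STAGE_FUNCS[dep](run)
            if name not in run.manifest["stages"]:
                _STAGE_FUNCS[name](run)
    finally:
        run.save_manifest()
    return run.manifest
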