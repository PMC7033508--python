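"""Synthetic elite/PGR panels with platform-specific marker sets and phenotypes.

The generator reproduces, with known ground truth, the statistical structure a
marker-platform comparison in genebank genomics rests on:

* two subpopulations — an elite breeding pool and a sample of plant genetic
  resources (PGR) — derived from common founder allele frequencies by
  lineage-specific genetic drift, with the elite lineage passing through a
  stronger bottleneck so its true diversity is lower;
* highly inbred lines (configurable selfing level, so genotypes are mostly
  homozygous);
* an "array" marker set obtained by ascertaining loci in a small, elite-biased
  discovery panel (this flattens the minor-allele-frequency spectrum and
  depletes rare alleles in the non-ascertained population — the classic
  ascertainment bias);
* a "GBS" marker set drawn at random from the genome (keeping the rare-allele
  excess) with missing calls and heterozygote undercalling;
* multi-allelic SSR loci (about 9 alleles per locus by default);
* multi-environment phenotypes built from additive marker effects plus
  environment, genotype-by-environment, replicate, block, and plot-error
  effects — mirroring the two-stage analysis model used downstream.

Founder allele frequencies follow a U-shaped Beta law, and drift is modelled
by generational binomial resampling of allele frequencies at the lineage's
effective size; loci are independent by default, with an optional
near-duplicate block structure to exercise LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import AlleleMatrix, GenotypeMatrix, code_ssr

__all__ = [
    "Bottleneck",
    "SimConfig",
    "PanelSpec",
    "Architecture",
    "VarianceSpec",
    "TrialDesign",
    "TruthRecord",
    "PopulationSim",
    "PlatformSet",
    "simulate_population",
    "simulate_platforms",
    "ascertain_array_markers",
    "sample_gbs_markers",
    "simulate_ssr",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class Bottleneck:
    """Effective size and duration of a lineage's drift phase."""

    effective_size: int = 100
    generations: int = 10

    def validate(self) -> None:
        if self.effective_size <= 0 or self.generations < 0:
            raise ValueError("effective size must be > 0 and generations >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults follow the panel the analysis is designed around: 190 elite lines
    and 188 PGR accessions, highly inbred (selfing 0.95), with the elite
    lineage drifting at a much smaller effective size (~30, the magnitude
    reported for European elite wheat pools) than the PGR lineage, 19 SSR loci
    averaging ~9 alleles each, and a U-shaped Beta(0.2, 0.2) founder frequency
    law so rare alleles are plentiful.  The truth genome is 4,000 loci — a
    desk-scale stand-in for array/GBS marker densities.
    """

    n_elite: int = 190
    n_pgr: int = 188
    n_loci: int = 4000
    founder_maf_law: tuple[float, float] = (0.2, 0.2)
    elite_bottleneck: Bottleneck = field(default_factory=lambda: Bottleneck(30, 10))
    pgr_bottleneck: Bottleneck = field(default_factory=lambda: Bottleneck(300, 10))
    n_families: int = 15
    family_bottleneck: Bottleneck = field(default_factory=lambda: Bottleneck(10, 3))
    n_ssr_loci: int = 19
    ssr_alleles_per_locus: float = 9.0
    selfing: float = 0.95
    linkage_block_size: int = 1
    block_copy_error: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_elite, self.n_pgr, self.n_loci, self.n_ssr_loci) <= 0:
            raise ValueError("all counts must be > 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 <= self.selfing <= 1:
            raise ValueError("selfing must lie in [0, 1]")
        a, b = self.founder_maf_law
        if a <= 0 or b <= 0:
            raise ValueError("founder Beta parameters must be > 0")
        if self.ssr_alleles_per_locus < 2:
            raise ValueError("need at least 2 alleles per SSR locus on average")
        if self.linkage_block_size < 1:
            raise ValueError("linkage_block_size must be >= 1")
        if not 0 <= self.block_copy_error <= 1:
            raise ValueError("block_copy_error must lie in [0, 1]")
        self.elite_bottleneck.validate()
        self.pgr_bottleneck.validate()
        self.family_bottleneck.validate()

    @property
    def inbreeding(self) -> float:
        """Equilibrium inbreeding coefficient F = s / (2 - s) under selfing s."""
        return self.selfing / (2.0 - self.selfing)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated phenotype set."""

    true_breeding_values: pd.Series
    causal_effects: np.ndarray
    variance_components_true: dict[str, float]

    def __post_init__(self) -> None:
        if np.any(self.causal_effects != 0):
            var = float(np.var(self.true_breeding_values.to_numpy(), ddof=1))
            if not np.isfinite(var) or var <= 0:
                raise ValueError("realized genetic variance must be finite and > 0")


@dataclass
class PopulationSim:
    """Whole-genome truth genotypes plus labels and raw SSR calls."""

    genotypes: GenotypeMatrix
    labels: np.ndarray  # 'elite' / 'pgr' per individual
    families: np.ndarray  # family label per individual (within lineage)
    ssr_raw: pd.DataFrame
    lineage_frequencies: dict[str, np.ndarray]


def _drift(p: np.ndarray, bottleneck: Bottleneck, rng: np.random.Generator) -> np.ndarray:
    two_ne = 2 * bottleneck.effective_size
    for _ in range(bottleneck.generations):
        p = rng.binomial(two_ne, p) / two_ne
    return p


def _draw_genotypes(
    p: np.ndarray, n: int, inbreeding: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype dosages under inbreeding-adjusted Hardy–Weinberg proportions."""
    p = p[None, :]
    p_het = 2 * p * (1 - p) * (1 - inbreeding)
    p_alt_hom = p**2 + inbreeding * p * (1 - p)
    u = rng.random((n, p.shape[1]))
    return ((u < p_alt_hom) * 2.0 + ((u >= p_alt_hom) & (u < p_alt_hom + p_het)) * 1.0)


def _copy_blocks(
    values: np.ndarray, block_size: int, copy_error: float, rng: np.random.Generator
) -> np.ndarray:
    """Turn each block of loci into near-duplicates of its first locus."""
    if block_size <= 1:
        return values
    n, m = values.shape
    out = values.copy()
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        for j in range(start + 1, stop):
            flip = rng.random(n) < copy_error
            out[:, j] = np.where(flip, values[:, j], values[:, start])
    return out


def _simulate_ssr_raw(
    config: SimConfig,
    labels: np.ndarray,
    families: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw multi-allelic calls: long format (individual, locus, allele)."""
    individual_ids = _individual_ids(config)
    rows: list[tuple[str, str, str]] = []
    f = config.inbreeding
    for locus_idx in range(config.n_ssr_loci):
        k = max(2, int(rng.poisson(config.ssr_alleles_per_locus)))
        founder = rng.dirichlet(np.full(k, 1.0))
        lineage = {
            "elite": _drift_multiallelic(founder, config.elite_bottleneck, rng),
            "pgr": _drift_multiallelic(founder, config.pgr_bottleneck, rng),
        }
        freqs: dict[str, np.ndarray] = {}
        for fam in dict.fromkeys(families):
            lab = "elite" if fam.startswith("elite") else "pgr"
            freqs[fam] = _drift_multiallelic(
                lineage[lab], config.family_bottleneck, rng
            )
        locus = f"SSR{locus_idx + 1:02d}"
        for ind, fam in zip(individual_ids, families):
            pvec = freqs[fam]
            if pvec.sum() <= 0:
                pvec = founder
            pvec = pvec / pvec.sum()
            a1 = rng.choice(k, p=pvec)
            a2 = a1 if rng.random() < f else rng.choice(k, p=pvec)
            alleles = {a1, a2}
            for a in sorted(alleles):
                rows.append((ind, locus, f"a{a + 1}"))
    return pd.DataFrame(rows, columns=["individual", "locus", "allele"])


def _drift_multiallelic(
    p: np.ndarray, bottleneck: Bottleneck, rng: np.random.Generator
) -> np.ndarray:
    two_ne = 2 * bottleneck.effective_size
    for _ in range(bottleneck.generations):
        p = rng.multinomial(two_ne, p) / two_ne
    return p


def _individual_ids(config: SimConfig) -> list[str]:
    return [f"E{i + 1:03d}" for i in range(config.n_elite)] + [
        f"P{i + 1:03d}" for i in range(config.n_pgr)
    ]


def _family_labels(config: SimConfig) -> np.ndarray:
    fams = []
    for lab, n in (("elite", config.n_elite), ("pgr", config.n_pgr)):
        fams.extend(f"{lab}_f{(i % config.n_families) + 1:02d}" for i in range(n))
    return np.array(fams)


def simulate_population(config: SimConfig) -> PopulationSim:
    """Simulate the whole-genome truth panel for both subpopulations.

    Founder frequencies drift independently down the elite and PGR lineages
    (binomial resampling at each lineage's effective size), then each lineage
    splits into ``n_families`` sub-families that drift further at the family
    bottleneck — giving the within-pool relatedness structure (full-sib-like
    families) that real breeding panels and genebank collections carry.
    Returns the genotype matrix over ALL simulated loci, per-individual
    subpopulation and family labels, and raw SSR calls.  Identical configs
    (including the seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b = config.founder_maf_law
    p0 = rng.beta(a, b, size=config.n_loci)
    p_elite = _drift(p0, config.elite_bottleneck, rng)
    p_pgr = _drift(p0, config.pgr_bottleneck, rng)
    lineage_p = {"elite": p_elite, "pgr": p_pgr}

    families = _family_labels(config)
    labels = np.array(["elite"] * config.n_elite + ["pgr"] * config.n_pgr)
    f = config.inbreeding
    n_total = config.n_elite + config.n_pgr
    values = np.empty((n_total, config.n_loci))
    for fam in dict.fromkeys(families):
        lab = "elite" if fam.startswith("elite") else "pgr"
        p_fam = _drift(lineage_p[lab], config.family_bottleneck, rng)
        rows = np.where(families == fam)[0]
        values[rows] = _draw_genotypes(p_fam, rows.size, f, rng)
    values = _copy_blocks(values, config.linkage_block_size, config.block_copy_error, rng)

    genotypes = GenotypeMatrix(
        values,
        _individual_ids(config),
        [f"L{j + 1:05d}" for j in range(config.n_loci)],
        platform_tag="other",
    )
    ssr_raw = _simulate_ssr_raw(config, labels, families, rng)
    return PopulationSim(
        genotypes=genotypes,
        labels=labels,
        families=families,
        ssr_raw=ssr_raw,
        lineage_frequencies={"founder": p0, "elite": p_elite, "pgr": p_pgr},
    )


@dataclass(frozen=True)
class PanelSpec:
    """Composition of the marker discovery panel (the bias mechanism).

    The default — 30 individuals, 80% of them elite — mimics an array designed
    mostly from elite material.
    """

    n: int = 30
    elite_fraction: float = 0.8

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("discovery panel must contain at least one individual")
        if not 0 <= self.elite_fraction <= 1:
            raise ValueError("elite_fraction must lie in [0, 1]")


def ascertain_array_markers(
    truth: GenotypeMatrix,
    labels=None,
    panel_spec: PanelSpec | None = None,
    min_panel_maf: float = 0.05,
    seed: int = 0,
    panel_individuals=None,
) -> np.ndarray:
    """Select "array" loci through a small discovery panel.

    A locus is retained when it is polymorphic in the panel with panel MAF of
    at least ``min_panel_maf``; loci monomorphic in the panel (however common
    elsewhere) are invisible to the array.  Returns the retained locus indices.
    ``panel_individuals`` (row indices) overrides the sampled panel.
    """
    if not 0 <= min_panel_maf <= 0.5:
        raise ValueError("min_panel_maf must lie in [0, 0.5]")
    if panel_individuals is None:
        spec = panel_spec or PanelSpec()
        spec.validate()
        if labels is None:
            raise ValueError("labels required to sample a discovery panel")
        labels = np.asarray(labels)
        rng = np.random.default_rng(seed)
        elite_idx = np.where(labels == "elite")[0]
        pgr_idx = np.where(labels != "elite")[0]
        n_elite = min(int(round(spec.n * spec.elite_fraction)), elite_idx.size)
        n_other = min(spec.n - n_elite, pgr_idx.size)
        panel_individuals = np.concatenate(
            [
                rng.choice(elite_idx, size=n_elite, replace=False),
                rng.choice(pgr_idx, size=n_other, replace=False),
            ]
        )
    panel_individuals = np.asarray(panel_individuals)
    if panel_individuals.size == 0:
        raise ValueError("empty discovery panel")
    panel = truth.values[panel_individuals]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(panel, axis=0) / 2.0
    panel_maf = np.minimum(p, 1 - p)
    keep = (p > 0) & (p < 1) & (panel_maf >= min_panel_maf)
    return np.where(keep)[0]


def sample_gbs_markers(
    truth: GenotypeMatrix,
    n_markers: int,
    missing_rate: float = 0.02,
    het_undercall: float = 0.3,
    seed: int = 0,
) -> GenotypeMatrix:
    """Random (frequency-blind) locus subset with GBS-style call artefacts.

    Unlike array ascertainment no frequency selection is applied, so the
    rare-allele excess of the truth spectrum is kept.  ``missing_rate`` of
    calls are set missing, and a fraction ``het_undercall`` of heterozygous
    calls collapse to a random homozygote, mimicking low-coverage calling.
    """
    if n_markers > truth.n_markers:
        raise ValueError("n_markers exceeds available loci")
    if not (0 <= missing_rate <= 1 and 0 <= het_undercall <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(truth.n_markers, size=n_markers, replace=False))
    g = truth.subset_markers(idx)
    values = g.values.copy()
    if het_undercall > 0:
        het = values == 1.0
        collapse = het & (rng.random(values.shape) < het_undercall)
        values[collapse] = rng.choice([0.0, 2.0], size=int(collapse.sum()))
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return GenotypeMatrix(values, list(g.individual_ids), list(g.marker_ids), "gbs")


def simulate_ssr(config: SimConfig, labels=None, seed: int | None = None) -> AlleleMatrix:
    """Simulate SSR loci and return them in binary allele-presence coding."""
    config.validate()
    if labels is None:
        labels = np.array(["elite"] * config.n_elite + ["pgr"] * config.n_pgr)
    labels = np.asarray(labels)
    if labels.size != config.n_elite + config.n_pgr:
        raise ValueError("labels length mismatch")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    raw = _simulate_ssr_raw(config, labels, _family_labels(config), rng)
    return code_ssr(raw, individual_ids=_individual_ids(config))


@dataclass
class PlatformSet:
    """The default study conditions: one truth genome, three marker platforms."""

    truth: GenotypeMatrix
    labels: np.ndarray
    families: np.ndarray
    array: GenotypeMatrix  # ascertained, platform_tag 'array'
    gbs: GenotypeMatrix  # random sample with call artefacts, tag 'gbs'
    ssr: AlleleMatrix
    array_indices: np.ndarray
    ssr_raw: pd.DataFrame


def simulate_platforms(
    config: SimConfig | None = None,
    seed: int | None = None,
    gbs_markers: int = 3500,
    gbs_missing_rate: float = 0.02,
    gbs_het_undercall: float = 0.3,
    panel_spec: PanelSpec | None = None,
    min_panel_maf: float = 0.05,
) -> PlatformSet:
    """One call producing the canonical three-platform panel.

    The GBS set samples most of the truth genome (default 3,500 of 4,000
    loci), echoing a GBS marker count roughly 2.5 times the ascertained array
    count; the array set is ascertained through the default elite-biased
    30-individual discovery panel.  Platform matrices are raw (pre-QC).
    """
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": int(seed)})
    pop = simulate_population(config)
    array_idx = ascertain_array_markers(
        pop.genotypes,
        labels=pop.labels,
        panel_spec=panel_spec or PanelSpec(),
        min_panel_maf=min_panel_maf,
        seed=config.seed + 1,
    )
    array_g = pop.genotypes.subset_markers(array_idx)
    array_g.platform_tag = "array"
    gbs_g = sample_gbs_markers(
        pop.genotypes,
        n_markers=min(gbs_markers, pop.genotypes.n_markers),
        missing_rate=gbs_missing_rate,
        het_undercall=gbs_het_undercall,
        seed=config.seed + 2,
    )
    ssr = code_ssr(pop.ssr_raw, individual_ids=pop.genotypes.individual_ids)
    return PlatformSet(
        truth=pop.genotypes,
        labels=pop.labels,
        families=pop.families,
        array=array_g,
        gbs=gbs_g,
        ssr=ssr,
        array_indices=array_idx,
        ssr_raw=pop.ssr_raw,
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class Architecture:
    """Genetic architecture of the simulated trait."""

    causal_fraction: float = 0.1
    rare_enriched: bool = False
    rare_maf_threshold: float = 0.05

    def validate(self) -> None:
        if not 0 < self.causal_fraction <= 1:
            raise ValueError("causal_fraction must lie in (0, 1]")
        if not 0 < self.rare_maf_threshold <= 0.5:
            raise ValueError("rare_maf_threshold must lie in (0, 0.5]")


@dataclass(frozen=True)
class VarianceSpec:
    """Generating variance components (trait units squared)."""

    genotype: float = 1.0
    gxe: float = 0.5
    error: float = 1.0
    environment: float = 1.0
    replicate: float = 0.1
    block: float = 0.1

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"variance component {name} must be >= 0")


@dataclass(frozen=True)
class TrialDesign:
    """Environments × replicates × incomplete blocks layout."""

    n_environments: int = 8
    n_replicates: int = 2
    n_blocks: int = 10
    presence_fraction: float = 1.0  # fraction of genotypes present per environment

    def validate(self) -> None:
        if self.n_environments < 1 or self.n_replicates < 1 or self.n_blocks < 1:
            raise ValueError("design counts must be >= 1")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must lie in (0, 1]")


def simulate_phenotypes(
    truth: GenotypeMatrix,
    architecture: Architecture | None = None,
    variances: VarianceSpec | None = None,
    design: TrialDesign | None = None,
    seed: int = 0,
    trait: str = "trait",
    mean: float = 0.0,
):
    """Simulate plot-level phenotypes from additive marker effects.

    Plot value = mean + genetic value + environment + G×E + replicate + block
    + error, exactly the generative counterpart of the two-stage analysis
    model.  True breeding values are rescaled so their realized sample
    variance equals the configured genotypic variance.  Returns
    ``(PhenotypeTable records, TruthRecord)``.
    """
    architecture = architecture or Architecture()
    variances = variances or VarianceSpec()
    design = design or TrialDesign()
    architecture.validate()
    variances.validate()
    design.validate()

    rng = np.random.default_rng(seed)
    values = truth.values
    if np.isnan(values).any():
        raise ValueError("truth genotypes must be complete")
    n_ind, n_loci = values.shape
    p = values.mean(axis=0) / 2.0
    locus_maf = np.minimum(p, 1 - p)
    n_causal = max(1, int(round(architecture.causal_fraction * n_loci)))
    if architecture.rare_enriched:
        pool = np.where((locus_maf > 0) & (locus_maf < architecture.rare_maf_threshold))[0]
        if pool.size == 0:
            raise ValueError("no loci below the rare MAF threshold")
    else:
        pool = np.where(locus_maf > 0)[0]
    causal = rng.choice(pool, size=min(n_causal, pool.size), replace=False)

    effects = np.zeros(n_loci)
    effects[causal] = rng.normal(size=causal.size)
    tbv = (values - 2 * p) @ effects
    sd = tbv.std(ddof=1)
    if variances.genotype > 0:
        if sd == 0:
            raise ValueError("degenerate genetic values (no marker variation)")
        scale = np.sqrt(variances.genotype) / sd
        tbv = tbv * scale
        effects = effects * scale
    else:
        tbv = np.zeros_like(tbv)
        effects = np.zeros_like(effects)

    env_ids = [f"E{e + 1:02d}" for e in range(design.n_environments)]
    env_eff = rng.normal(0, np.sqrt(variances.environment), design.n_environments)
    gxe = rng.normal(0, np.sqrt(variances.gxe), (n_ind, design.n_environments))

    rows = []
    for e, env in enumerate(env_ids):
        if design.presence_fraction < 1.0:
            k = max(2, int(round(design.presence_fraction * n_ind)))
            present = np.sort(rng.choice(n_ind, size=k, replace=False))
        else:
            present = np.arange(n_ind)
        for r in range(design.n_replicates):
            rep_eff = rng.normal(0, np.sqrt(variances.replicate))
            block_eff = rng.normal(0, np.sqrt(variances.block), design.n_blocks)
            order = rng.permutation(present)
            block_of = np.empty(present.size, dtype=int)
            block_of[np.argsort(order)] = (
                np.arange(present.size) * design.n_blocks // present.size
            )
            errs = rng.normal(0, np.sqrt(variances.error), present.size)
            for pos, i in enumerate(present):
                b = block_of[pos]
                rows.append(
                    {
                        "genotype": truth.individual_ids[i],
                        "environment": env,
                        "replicate": f"R{r + 1}",
                        "block": f"{env}_R{r + 1}_B{b + 1:02d}",
                        "trait": trait,
                        "value": mean
                        + tbv[i]
                        + env_eff[e]
                        + gxe[i, e]
                        + rep_eff
                        + block_eff[b]
                        + errs[pos],
                    }
                )
    table = pd.DataFrame(rows)
    record = TruthRecord(
        true_breeding_values=pd.Series(tbv, index=truth.individual_ids, name=trait),
        causal_effects=effects,
        variance_components_true={
            "genotype": variances.genotype,
            "gxe": variances.gxe,
            "error": variances.error,
            "environment": variances.environment,
            "replicate": variances.replicate,
            "block": variances.block,
        },
    )
    return table, record
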