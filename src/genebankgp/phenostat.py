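"""Two-stage analysis of multi-environment trial phenotypes.

Stage 1 fits, within each environment, a mixed model with fixed genotype
means and random replicate and incomplete-block effects, yielding
per-environment genotype BLUEs.  Stage 2 combines the per-environment BLUEs
across environments: with genotype fixed it returns across-environment BLUEs;
with genotype random it returns REML variance components (genotypic, G×E,
error) from which broad-sense heritability is computed on an entry-mean basis:

    H2 = sigma2_G / (sigma2_G + sigma2_GxE / nbar + sigma2_e / (r * nbar))

where ``nbar`` is the average number of environments per genotype and ``r``
the average number of replicates.

A caveat of any two-stage scheme with one BLUE per genotype-environment cell:
the G×E and plot-error components are exactly confounded at stage 2 (their
design matrices coincide), so from BLUEs alone only their cell-level sum is
estimable.  When the plot-level records are supplied, the all-random
plot-level model separates the two; this changes nothing in H2 because
``(s_gxe + s_e/r)/nbar == s_gxe/nbar + s_e/(r*nbar)``.

Outlier screening follows the BH-MADR recipe: stage-1 residuals standardized
by the re-scaled median absolute deviation (1.4826 × MAD), two-sided normal
p-values, and Bonferroni–Holm step-down at the chosen level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .mixedlm import FactorTerm, MixedFit, fit_factor_model, term_from_labels

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_phenotypes",
    "VarianceComponents",
    "detect_outliers_bh_madr",
    "remove_outliers",
    "fit_stage1",
    "fit_stage1_all",
    "fit_stage2",
    "heritability",
]

REQUIRED_COLUMNS = ("genotype", "environment", "replicate", "block", "trait", "value")


def validate_phenotypes(p: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(p.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    key = ["genotype", "environment", "replicate", "trait"]
    if p.duplicated(subset=key).any():
        raise ValueError("duplicate (genotype, environment, replicate, trait) records")
    values = p["value"].to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValueError("non-finite phenotype values (use NaN for missing)")
    return p


@dataclass
class VarianceComponents:
    """Stage-2 variance components and entry-mean heritability."""

    sigma2_g: float
    sigma2_gxe: float
    sigma2_e: float
    n_bar: float
    r: float
    H2: float
    gxe_confounded_with_error: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gxe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.H2 <= 1:
            raise ValueError("H2 must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _genotype_design(genotypes: pd.Series):
    """Cell-means fixed-effect design: one column per genotype level."""
    levels = list(dict.fromkeys(genotypes))
    index = {g: i for i, g in enumerate(levels)}
    codes = genotypes.map(index).to_numpy()
    X = np.zeros((len(codes), len(levels)))
    X[np.arange(len(codes)), codes] = 1.0
    return X, levels


def _stage1_fit(sub: pd.DataFrame) -> tuple[pd.Series, MixedFit]:
    """Within-environment mixed fit: genotype fixed, replicate/block random."""
    X, levels = _genotype_design(sub["genotype"].astype(str))
    terms: list[FactorTerm] = []
    for col in ("replicate", "block"):
        labels = sub[col].astype(str)
        n_levels = labels.nunique()
        if 1 < n_levels < len(sub):
            terms.append(term_from_labels(col, labels))
    if len(sub) <= X.shape[1]:
        terms = []  # saturated: BLUEs are the raw plot values
    fit = fit_factor_model(sub["value"].to_numpy(dtype=float), X, terms)
    return pd.Series(fit.beta, index=levels), fit


def fit_stage1(p: pd.DataFrame, trait: str, environment: str):
    """Per-environment genotype BLUEs; genotypes unobserved there are omitted.

    Returns ``(BlueTable rows, MixedFit)``.
    """
    validate_phenotypes(p)
    sub = p[
        (p["trait"] == trait)
        & (p["environment"] == environment)
        & p["value"].notna()
    ]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r} in {environment!r}")
    all_geno = set(p.loc[p["trait"] == trait, "genotype"].astype(str))
    seen = set(sub["genotype"].astype(str))
    if all_geno - seen:
        warnings.warn(
            f"{environment}: {len(all_geno - seen)} genotype(s) unobserved, omitted"
        )
    blues, fit = _stage1_fit(sub)
    table = pd.DataFrame(
        {
            "genotype": blues.index,
            "environment": environment,
            "trait": trait,
            "value": blues.to_numpy(),
            "stage": "within-environment",
        }
    )
    return table, fit


def fit_stage1_all(p: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Stage-1 BLUEs for every environment carrying the trait."""
    envs = list(dict.fromkeys(p.loc[p["trait"] == trait, "environment"]))
    if not envs:
        raise ValueError(f"trait {trait!r} not present")
    parts = [fit_stage1(p, trait, env)[0] for env in envs]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# outliers


def detect_outliers_bh_madr(
    p: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag outlying plot records per trait (BH-MADR).

    Residuals come from the stage-1 fit in each environment; per trait they
    are pooled, centered at their median, standardized by 1.4826 × MAD, turned
    into two-sided normal p-values and screened by Bonferroni–Holm at
    ``alpha``.  Returns the flagged records with their test statistics.
    """
    validate_phenotypes(p)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    flagged = []
    for trait in dict.fromkeys(p["trait"]):
        rows = p[(p["trait"] == trait) & p["value"].notna()]
        if len(rows) < 10:
            raise ValueError(f"trait {trait!r}: need at least 10 records")
        residuals = np.empty(len(rows))
        pos = 0
        for env in dict.fromkeys(rows["environment"]):
            sub = rows[rows["environment"] == env]
            _, fit = _stage1_fit(sub)
            residuals[pos : pos + len(sub)] = (
                sub["value"].to_numpy(dtype=float) - fit.fitted
            )
            pos += len(sub)
        med = np.median(residuals)
        mad = np.median(np.abs(residuals - med))
        if mad == 0:
            raise ValueError(f"trait {trait!r}: MAD of residuals is zero")
        z = (residuals - med) / (1.4826 * mad)
        pvals = 2.0 * sps.norm.sf(np.abs(z))
        if alpha == 0:
            continue
        reject, p_holm, *_ = multipletests(pvals, alpha=alpha, method="holm")
        if reject.any():
            out = rows.iloc[np.where(reject)[0]].copy()
            out["residual_z"] = z[reject]
            out["p_holm"] = p_holm[reject]
            flagged.append(out)
    if not flagged:
        return p.iloc[0:0].assign(residual_z=[], p_holm=[])
    return pd.concat(flagged)


def remove_outliers(p: pd.DataFrame, flagged: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged records (matched by index) from the phenotype table."""
    return p.drop(index=flagged.index)


# ---------------------------------------------------------------------------
# stage 2


def _check_connected(blues: pd.DataFrame) -> None:
    genotypes = list(dict.fromkeys(blues["genotype"]))
    envs = list(dict.fromkeys(blues["environment"]))
    gi = {g: i for i, g in enumerate(genotypes)}
    ei = {e: i + len(genotypes) for i, e in enumerate(envs)}
    n = len(genotypes) + len(envs)
    rows = [gi[g] for g in blues["genotype"]]
    cols = [ei[e] for e in blues["environment"]]
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    if n_comp > 1:
        groups = [
            [genotypes[i] for i in range(len(genotypes)) if labels[i] == c]
            for c in range(n_comp)
        ]
        raise ValueError(
            f"genotype x environment incidence is disconnected: {n_comp} groups, "
            f"e.g. sizes {[len(g) for g in groups]}"
        )


def fit_stage2(
    blues_stage1: pd.DataFrame,
    plots: pd.DataFrame | None = None,
    trait: str | None = None,
):
    """Across-environment BLUEs and REML variance components.

    ``blues_stage1`` holds the stage-1 (within-environment) genotype BLUEs.
    Two fits are performed: genotype fixed (returning across-environment
    BLUEs) and all-random for the variance components.  Supplying the
    plot-level ``plots`` records lets the all-random fit run at plot level,
    separating sigma2_GxE from sigma2_e; from BLUEs alone only their
    cell-level sum is estimable and is reported as sigma2_GxE with a flag.

    Returns ``(BlueTable across environments, VarianceComponents)``.
    """
    blues = blues_stage1
    if trait is not None:
        blues = blues[blues["trait"] == trait]
        if plots is not None:
            plots = plots[plots["trait"] == trait]
    traits = set(blues["trait"])
    if len(traits) != 1:
        raise ValueError("fit_stage2 handles one trait at a time (pass trait=...)")
    trait_name = traits.pop()
    blues = blues[blues["value"].notna()]
    envs = blues["environment"].nunique()
    if envs < 2:
        raise ValueError("need at least two environments for stage 2")
    _check_connected(blues)

    # (a) genotype fixed -> across-environment BLUEs
    y = blues["value"].to_numpy(dtype=float)
    X, levels = _genotype_design(blues["genotype"].astype(str))
    env_term = term_from_labels("environment", blues["environment"])
    fit_fixed = fit_factor_model(y, X, [env_term])
    across = pd.DataFrame(
        {
            "genotype": levels,
            "trait": trait_name,
            "value": fit_fixed.beta,
            "stage": "across-environment",
        }
    )

    # (b) all-random -> variance components
    n_bar = float(blues.groupby("genotype")["environment"].nunique().mean())
    if plots is not None:
        plots = validate_phenotypes(plots)
        plots = plots[plots["value"].notna()]
        cell = plots.groupby(["genotype", "environment"])["replicate"].nunique()
        r = float(cell.mean())
        yp = plots["value"].to_numpy(dtype=float)
        Xp = np.ones((len(yp), 1))
        gxe_labels = (
            plots["genotype"].astype(str) + "\x1f" + plots["environment"].astype(str)
        )
        rep_labels = (
            plots["environment"].astype(str) + "\x1f" + plots["replicate"].astype(str)
        )
        terms = [
            term_from_labels("genotype", plots["genotype"]),
            term_from_labels("environment", plots["environment"]),
            term_from_labels("gxe", gxe_labels),
            term_from_labels("replicate", rep_labels),
        ]
        if plots["block"].nunique() > plots["environment"].nunique() and plots[
            "block"
        ].nunique() < len(plots):
            terms.append(term_from_labels("block", plots["block"]))
        fit_rand = fit_factor_model(yp, Xp, terms)
        s_g = fit_rand.sigma2["genotype"]
        s_gxe = fit_rand.sigma2["gxe"]
        s_e = fit_rand.sigma2["residual"]
        confounded = False
    else:
        r = 1.0
        Xr = np.ones((len(y), 1))
        terms = [
            term_from_labels("genotype", blues["genotype"]),
            env_term,
        ]
        fit_rand = fit_factor_model(y, Xr, terms)
        s_g = fit_rand.sigma2["genotype"]
        s_gxe = fit_rand.sigma2["residual"]  # G×E + mean plot error, confounded
        s_e = 0.0
        confounded = True

    h2 = heritability(s_g, s_gxe, s_e, n_bar, r)
    vc = VarianceComponents(
        sigma2_g=s_g,
        sigma2_gxe=s_gxe,
        sigma2_e=s_e,
        n_bar=n_bar,
        r=r,
        H2=h2,
        gxe_confounded_with_error=confounded,
        converged=fit_rand.converged,
    )
    return across, vc


def heritability(
    sigma2_g: float, sigma2_gxe: float, sigma2_e: float, n_bar: float, r: float
) -> float:
    """Entry-mean broad-sense heritability.

    H2 = s2_G / (s2_G + s2_GxE / nbar + s2_e / (r * nbar)).
    """
    if n_bar <= 0 or r <= 0:
        raise ValueError("n_bar and r must be > 0")
    if min(sigma2_g, sigma2_gxe, sigma2_e) < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma2_g + sigma2_gxe / n_bar + sigma2_e / (r * n_bar)
    if denom == 0:
        return 0.0
    return float(sigma2_g / denom)
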