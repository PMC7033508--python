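"""Allele-frequency diversity statistics with bootstrap uncertainty.

Implements the classic genebank-fingerprinting indices on both bi-allelic
dosage data and multi-allelic SSR-style allele-presence data:

* minor allele frequency (MAF), ``min(p, 1-p)`` per bi-allelic marker, or the
  rarest-allele frequency per multi-allelic locus,
* gene diversity / expected heterozygosity ``H = 1 - sum_i p_i^2``,
* polymorphism information content (Botstein form)
  ``PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``,
* Rogers' distance between individuals: per locus the Euclidean-type distance
  ``sqrt(0.5 * sum_a (f1a - f2a)^2)`` between the two individuals' within-locus
  allele-frequency vectors (entries 0, 1/2, 1 from the genotype), averaged over
  the loci scored in both individuals.

Bootstrap SDs resample markers/loci with replacement (indices) or subsample
genotypes without replacement (distances), matching standard practice for
these statistics.  Diversity is intended to be computed on filtered but
UNIMPUTED data so imputation noise cannot leak into the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import AlleleMatrix, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "allele_frequencies",
    "maf",
    "maf_per_column",
    "heterozygosity",
    "pic",
    "per_marker_stats",
    "rogers_distance",
    "bootstrap_summary",
    "rd_uncertainty",
    "maf_spectrum",
    "diversity_summary",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise ValueError("Rogers' distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def subset(self, idx) -> "DistanceMatrix":
        idx = np.asarray(idx)
        return DistanceMatrix(
            self.values[np.ix_(idx, idx)], [self.individual_ids[i] for i in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, ind in enumerate(self.individual_ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{ind} {row}\n")


# ---------------------------------------------------------------------------
# frequencies


def _locus_frequency_vectors(a: AlleleMatrix) -> dict[str, np.ndarray]:
    """Per-locus allele-frequency vectors from individual contributions.

    Each scored individual contributes its within-locus allele frequencies
    (presence row normalised to sum 1: homozygote -> 1, heterozygote -> 1/2
    each); the locus frequency vector is the mean contribution.
    """
    out: dict[str, np.ndarray] = {}
    for locus in a.loci:
        cols = a.columns_of_locus(locus)
        sub = a.values[:, cols]
        scored = ~np.isnan(sub).any(axis=1)
        obs = sub[scored]
        if obs.shape[0] == 0:
            raise ValueError(f"locus {locus} has no observed calls")
        totals = obs.sum(axis=1)
        if (totals == 0).any():
            raise ValueError(f"locus {locus}: scored individual with no allele present")
        out[locus] = (obs / totals[:, None]).mean(axis=0)
    return out


def allele_frequencies(g):
    """Observed allele frequencies.

    For a GenotypeMatrix: alternate-allele frequency per marker (dosages count
    0/1/2 alternate copies, missing excluded).  For an AlleleMatrix: a dict
    locus -> allele-frequency vector.
    """
    if isinstance(g, GenotypeMatrix):
        n_obs = (~np.isnan(g.values)).sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("marker with zero observed calls")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g.values, axis=0) / 2.0
    if isinstance(g, AlleleMatrix):
        return _locus_frequency_vectors(g)
    raise TypeError("expected GenotypeMatrix or AlleleMatrix")


def _as_freq_list(freqs) -> list[np.ndarray]:
    """Normalise input to a list of per-locus allele-frequency vectors."""
    if isinstance(freqs, dict):
        return [np.asarray(v, dtype=float) for v in freqs.values()]
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim == 1:  # bi-allelic p's
        return [np.array([p, 1 - p]) for p in arr]
    raise TypeError("freqs must be a 1-D array of p's or a dict of allele vectors")


def maf(freqs) -> np.ndarray:
    """Minor allele frequency: min(p, 1-p) bi-allelic, rarest allele multi-allelic."""
    return np.array([v.min() for v in _as_freq_list(freqs)])


def maf_per_column(a: AlleleMatrix) -> np.ndarray:
    """MAF treating every binary allele column as a marker in its own right.

    The column "allele frequency" is each individual's within-locus frequency
    of that allele (0, 1/2 or 1), averaged over scored individuals.
    """
    out = np.empty(a.n_columns)
    for locus in a.loci:
        cols = a.columns_of_locus(locus)
        sub = a.values[:, cols]
        scored = ~np.isnan(sub).any(axis=1)
        obs = sub[scored]
        contrib = obs / obs.sum(axis=1)[:, None]
        q = contrib.mean(axis=0)
        out[cols] = np.minimum(q, 1 - q)
    return out


def heterozygosity(freqs) -> np.ndarray:
    """Gene diversity (expected heterozygosity) 1 - sum_i p_i^2 per locus."""
    return np.array([1.0 - float((v**2).sum()) for v in _as_freq_list(freqs)])


def pic(freqs) -> np.ndarray:
    """Polymorphism information content, 1 - Σp_i² - Σ_{i<j} 2 p_i² p_j²."""
    out = []
    for v in _as_freq_list(freqs):
        s2 = float((v**2).sum())
        # sum_{i<j} p_i^2 p_j^2 = ((Σp²)² − Σp⁴) / 2
        cross = (s2**2 - float((v**4).sum())) / 2.0
        out.append(1.0 - s2 - 2.0 * cross)
    return np.array(out)


def per_marker_stats(g) -> pd.DataFrame:
    """Tidy per-marker (bi-allelic) or per-locus (SSR) MAF/H/PIC table."""
    freqs = allele_frequencies(g)
    if isinstance(g, GenotypeMatrix):
        labels = list(g.marker_ids)
    else:
        labels = list(freqs.keys())
    return pd.DataFrame(
        {
            "marker": labels,
            "maf": maf(freqs),
            "het": heterozygosity(freqs),
            "pic": pic(freqs),
        }
    )


# ---------------------------------------------------------------------------
# Rogers' distance


def _rogers_genotype(values: np.ndarray) -> np.ndarray:
    """Pairwise Rogers' distances for dosage data, pairwise-complete loci.

    For a bi-allelic locus the per-locus distance between individuals with
    dosages x1, x2 reduces to |x1 - x2| / 2.
    """
    n = values.shape[0]
    half_diff_ready = values / 2.0
    valid = ~np.isnan(values)
    filled = np.where(valid, half_diff_ready, 0.0)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        denom = both.sum(axis=1)
        if (denom == 0).any():
            j = int(np.where(denom == 0)[0][0])
            if j != i:
                raise ValueError(
                    f"individuals {i} and {j} share no scored loci"
                )
        num = np.where(both, np.abs(filled[i] - filled), 0.0).sum(axis=1)
        d[i] = num / np.maximum(denom, 1)
    np.fill_diagonal(d, 0.0)
    return d


def _rogers_allele(a: AlleleMatrix) -> np.ndarray:
    n = a.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for locus in a.loci:
        cols = a.columns_of_locus(locus)
        sub = a.values[:, cols]
        scored = ~np.isnan(sub).any(axis=1)
        contrib = np.full_like(sub, np.nan)
        totals = np.where(scored, np.nansum(sub, axis=1), np.nan)
        contrib[scored] = sub[scored] / totals[scored, None]
        f = np.where(scored[:, None], contrib, 0.0)
        # squared Euclidean between frequency vectors of every pair
        sq = ((f[:, None, :] - f[None, :, :]) ** 2).sum(axis=2)
        d_locus = np.sqrt(0.5 * sq)
        both = scored[:, None] & scored[None, :]
        num += np.where(both, d_locus, 0.0)
        den += both
    if (den[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("some pair shares no scored loci")
    d = num / np.maximum(den, 1)
    np.fill_diagonal(d, 0.0)
    return d


def rogers_distance(g) -> DistanceMatrix:
    """Rogers' distance matrix among individuals (dosage or allele-presence data)."""
    if isinstance(g, GenotypeMatrix):
        if g.n_individuals < 2:
            raise ValueError("need at least two individuals")
        return DistanceMatrix(_rogers_genotype(g.values), list(g.individual_ids))
    if isinstance(g, AlleleMatrix):
        if g.n_individuals < 2:
            raise ValueError("need at least two individuals")
        return DistanceMatrix(_rogers_allele(g), list(g.individual_ids))
    raise TypeError("expected GenotypeMatrix or AlleleMatrix")


# ---------------------------------------------------------------------------
# resampling uncertainty


_INDEX_FUNCS = {"maf": maf, "H": heterozygosity, "pic": pic}


def bootstrap_summary(g, index: str, rounds: int = 1000, seed: int = 0):
    """Mean and bootstrap SD of a diversity index, resampling markers/loci.

    Returns ``(mean, sd)`` where ``mean`` is the plain mean over markers (or
    loci) and ``sd`` is the standard deviation of the resampled means over
    ``rounds`` bootstrap draws with replacement.
    """
    if index not in _INDEX_FUNCS:
        raise ValueError(f"index must be one of {sorted(_INDEX_FUNCS)}")
    per_locus = _INDEX_FUNCS[index](allele_frequencies(g))
    rng = np.random.default_rng(seed)
    m = per_locus.size
    draws = rng.integers(0, m, size=(rounds, m))
    means = per_locus[draws].mean(axis=1)
    return float(per_locus.mean()), float(means.std(ddof=1))


def rd_uncertainty(
    g, rounds: int = 1000, seed: int = 0, subsample_fraction: float = 0.8
):
    """Mean pairwise Rogers' distance and its genotype-resampling SD.

    Each round draws ``subsample_fraction`` of the genotypes WITHOUT
    replacement and records the mean pairwise distance among them; the SD over
    rounds is reported.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    d = g if isinstance(g, DistanceMatrix) else rogers_distance(g)
    rng = np.random.default_rng(seed)
    n = d.n
    k = max(2, int(round(subsample_fraction * n)))
    means = np.empty(rounds)
    tri = np.tril_indices(k, k=-1)
    for r in range(rounds):
        idx = rng.choice(n, size=k, replace=False)
        means[r] = d.values[np.ix_(idx, idx)][tri].mean()
    return float(d.lower_triangle().mean()), float(means.std(ddof=1))


def maf_spectrum(g, bin_edges=None, per_column_ssr: bool = True) -> pd.DataFrame:
    """Binned MAF histogram (counts and fractions) over [0, 0.5]."""
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.501, 0.05)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if isinstance(g, AlleleMatrix) and per_column_ssr:
        values = maf_per_column(g)
    else:
        values = maf(allele_frequencies(g))
    counts, edges = np.histogram(values, bins=bin_edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "fraction": counts / max(values.size, 1),
        }
    )


def diversity_summary(
    g, labels=None, rounds: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Tidy diversity table (population × index, mean and bootstrap SD).

    ``labels`` maps individuals to subpopulations; the table always contains
    the pooled "All" population plus one row set per label value, with the
    mean pairwise Rogers' distance alongside MAF/H/PIC.
    """
    groups: dict[str, np.ndarray] = {"All": np.arange(_n_ind(g))}
    if labels is not None:
        labels = np.asarray(labels)
        if labels.size != _n_ind(g):
            raise ValueError("labels length mismatch")
        for lab in dict.fromkeys(labels):
            groups[str(lab)] = np.where(labels == lab)[0]
    rows = []
    for pop, idx in groups.items():
        sub = _subset_individuals(g, idx)
        for index in ("maf", "H", "pic"):
            mean, sd = bootstrap_summary(sub, index, rounds=rounds, seed=seed)
            rows.append(
                {"population": pop, "index": index, "mean": mean, "sd": sd,
                 "n": int(idx.size)}
            )
        rd_mean, rd_sd = rd_uncertainty(sub, rounds=rounds, seed=seed)
        rows.append(
            {"population": pop, "index": "RD", "mean": rd_mean, "sd": rd_sd,
             "n": int(idx.size)}
        )
    return pd.DataFrame(rows)


def _n_ind(g) -> int:
    return g.n_individuals


def _subset_individuals(g, idx):
    if isinstance(g, GenotypeMatrix):
        return g.subset_individuals(idx)
    return AlleleMatrix(
        g.values[np.asarray(idx)],
        [g.individual_ids[i] for i in idx],
        list(g.column_loci),
        list(g.column_alleles),
    )
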