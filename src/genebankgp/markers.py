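"""Marker-data containers, coding, quality filtering, and imputation.

Bi-allelic markers (SNP-array-like or GBS-like) live in a :class:`GenotypeMatrix`
with dosage coding 0/1/2 (copies of the alternate allele) and NaN for missing
calls.  Multi-allelic SSR-like loci live in an :class:`AlleleMatrix` with one
binary presence column per (locus, allele) pair — the "each allele is a marker"
coding used throughout genebank fingerprinting studies.

Quality control is the two-pass rule standard in this literature: drop markers
with more than ``max_missing`` missing calls, then drop monomorphic markers
(allele frequency 0 or 1 among the remaining calls).  Missing values can then
be imputed by seeded random draws from Hardy–Weinberg proportions at the
observed allele frequency, which preserves the marker's frequency spectrum in
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleMatrix",
    "FilterReport",
    "read_genotypes",
    "write_vcf",
    "write_dosage_table",
    "read_ssr_table",
    "code_ssr",
    "filter_markers",
    "impute_by_frequency",
    "impute_allele_matrix",
]

_ALLOWED_DOSAGES = (0.0, 1.0, 2.0)


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class GenotypeMatrix:
    """Individuals × bi-allelic markers, dosage coded with NaN for missing."""

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    platform_tag: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x markers)")
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("dimension mismatch between values and id lists")
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.marker_ids, "marker")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, _ALLOWED_DOSAGES).all():
            raise ValueError("genotype entries must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            list(self.individual_ids),
            [self.marker_ids[i] for i in idx],
            self.platform_tag,
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx, :],
            [self.individual_ids[i] for i in idx],
            list(self.marker_ids),
            self.platform_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.marker_ids
        )


@dataclass
class AlleleMatrix:
    """Individuals × (locus, allele) binary presence matrix for SSR-like loci.

    ``column_loci[j]``/``column_alleles[j]`` name the locus and allele behind
    column ``j``; an individual with no call at a locus carries NaN across all
    of that locus's columns.
    """

    values: np.ndarray
    individual_ids: list[str]
    column_loci: list[str]
    column_alleles: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.column_loci = [str(c) for c in self.column_loci]
        self.column_alleles = [str(c) for c in self.column_alleles]
        if self.values.shape != (len(self.individual_ids), len(self.column_loci)):
            raise ValueError("dimension mismatch")
        if len(self.column_alleles) != len(self.column_loci):
            raise ValueError("column annotation length mismatch")
        _check_unique(self.individual_ids, "individual")
        _check_unique(list(zip(self.column_loci, self.column_alleles)), "allele-column")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("allele-presence entries must be 0, 1 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.column_loci:
            seen.setdefault(l, None)
        return list(seen)

    @property
    def locus_of_column(self) -> dict[int, str]:
        return dict(enumerate(self.column_loci))

    def columns_of_locus(self, locus: str) -> np.ndarray:
        return np.array([j for j, l in enumerate(self.column_loci) if l == locus])

    def marker_labels(self) -> list[str]:
        return [f"{l}:{a}" for l, a in zip(self.column_loci, self.column_alleles)]

    def subset_columns(self, idx) -> "AlleleMatrix":
        idx = np.asarray(idx)
        return AlleleMatrix(
            self.values[:, idx],
            list(self.individual_ids),
            [self.column_loci[i] for i in idx],
            [self.column_alleles[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.marker_labels()
        )


@dataclass
class FilterReport:
    """Bookkeeping of the two-pass marker quality filter."""

    n_input: int
    n_failed_missing: int
    n_monomorphic: int
    retained_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_input != self.n_failed_missing + self.n_monomorphic + len(
            self.retained_ids
        ):
            raise ValueError("filter report counts do not reconcile")

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": [self.n_input],
                "n_failed_missing": [self.n_failed_missing],
                "n_monomorphic": [self.n_monomorphic],
                "n_retained": [self.n_retained],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path, format: str = "vcf", platform_tag: str = "other") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (GT field) or a dosage table.

    Only bi-allelic VCF records are kept; multi-allelic records are skipped
    and counted in a warning.  Missing genotypes map to NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, platform_tag)
    if format == "dosage":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return GenotypeMatrix(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            platform_tag,
        )
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path, platform_tag: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lookup = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            n_skipped += 1
            continue
        cols.append(lookup[var.gt_types])
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no bi-allelic records found")
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-bi-allelic record(s)")
    g = GenotypeMatrix(np.column_stack(cols), individuals, ids, platform_tag)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only, synthetic chrom/pos)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, mid in enumerate(g.marker_ids):
            calls = [
                "./." if np.isnan(v) else _GT_CODE[v] for v in g.values[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_dosage_table(g: GenotypeMatrix, path) -> None:
    g.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_ssr_table(path) -> pd.DataFrame:
    """Read long-format SSR calls (columns: individual, locus, allele)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "locus", "allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"SSR table must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Coding and QC


def code_ssr(raw_ssr_calls: pd.DataFrame, individual_ids=None) -> AlleleMatrix:
    """Binary allele-presence coding of multi-allelic SSR calls.

    ``raw_ssr_calls`` is long format with one row per observed allele per
    individual per locus (a heterozygote contributes two rows).  Every allele
    observed anywhere at a locus becomes a column; individuals with no call at
    a locus get NaN across that locus's columns.
    """
    df = raw_ssr_calls
    required = {"individual", "locus", "allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"SSR calls must have columns {sorted(required)}")
    df = df.astype({"individual": str, "locus": str, "allele": str})
    if individual_ids is None:
        individual_ids = list(dict.fromkeys(df["individual"]))
    else:
        individual_ids = [str(i) for i in individual_ids]
    ind_index = {ind: i for i, ind in enumerate(individual_ids)}
    unknown = set(df["individual"]) - set(individual_ids)
    if unknown:
        raise ValueError(f"SSR calls for unknown individuals: {sorted(unknown)[:5]}")

    columns = sorted(
        set(zip(df["locus"], df["allele"])), key=lambda la: (la[0], la[1])
    )
    col_index = {la: j for j, la in enumerate(columns)}
    loci = sorted(set(df["locus"]))
    locus_cols = {
        l: [j for j, (cl, _) in enumerate(columns) if cl == l] for l in loci
    }

    values = np.full((len(individual_ids), len(columns)), np.nan)
    scored = set(zip(df["individual"], df["locus"]))
    for ind, locus in scored:
        values[ind_index[ind], locus_cols[locus]] = 0.0
    for ind, locus, allele in zip(df["individual"], df["locus"], df["allele"]):
        values[ind_index[ind], col_index[(locus, allele)]] = 1.0
    return AlleleMatrix(
        values,
        individual_ids,
        [l for l, _ in columns],
        [a for _, a in columns],
    )


def _column_frequencies(values: np.ndarray, dosage: bool) -> np.ndarray:
    """Alternate-allele (or presence) frequency per column from observed calls."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
    return mean / 2.0 if dosage else mean


def filter_markers(g, max_missing: float = 0.05):
    """Two-pass QC: missingness strictly above ``max_missing``, then monomorphic.

    Returns ``(filtered, FilterReport)``.  Applies to both GenotypeMatrix
    (markers) and AlleleMatrix (allele columns).  Raises if nothing survives.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    is_dosage = isinstance(g, GenotypeMatrix)
    values = g.values
    if values.size == 0:
        raise ValueError("empty matrix")
    labels = g.marker_ids if is_dosage else g.marker_labels()

    miss = np.isnan(values).mean(axis=0)
    pass1 = miss <= max_missing  # "more than max_missing" removed: strict
    n_failed_missing = int((~pass1).sum())

    freq = np.full(values.shape[1], np.nan)
    cols = np.where(pass1)[0]
    freq[cols] = _column_frequencies(values[:, cols], dosage=is_dosage)
    poly = pass1 & (freq > 0) & (freq < 1)
    n_monomorphic = int(pass1.sum() - poly.sum())

    keep = np.where(poly)[0]
    if keep.size == 0:
        raise ValueError("no markers retained after filtering")
    report = FilterReport(
        n_input=values.shape[1],
        n_failed_missing=n_failed_missing,
        n_monomorphic=n_monomorphic,
        retained_ids=[labels[i] for i in keep],
    )
    if is_dosage:
        return g.subset_markers(keep), report
    return g.subset_columns(keep), report


def impute_by_frequency(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace missing dosages by Hardy–Weinberg draws at the observed frequency.

    Observed entries are untouched; the draw is seeded.  Markers with zero
    observed calls cannot be imputed and raise.
    """
    values = g.values.copy()
    n_obs = (~np.isnan(values)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.marker_ids[j] for j in np.where(n_obs == 0)[0][:5]]
        raise ValueError(f"markers with zero observed calls: {bad}")
    p = _column_frequencies(values, dosage=True)
    rng = np.random.default_rng(seed)
    miss_i, miss_j = np.where(np.isnan(values))
    if miss_i.size:
        pm = p[miss_j]
        probs = np.column_stack(((1 - pm) ** 2, 2 * pm * (1 - pm), pm**2))
        u = rng.random(miss_i.size)
        draws = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1).astype(float)
        values[miss_i, miss_j] = draws
    return GenotypeMatrix(values, list(g.individual_ids), list(g.marker_ids), g.platform_tag)


def impute_allele_matrix(a: AlleleMatrix, seed: int) -> AlleleMatrix:
    """Impute missing SSR loci by drawing two alleles from the locus frequencies.

    An individual's missing locus is filled with a seeded draw of an unordered
    allele pair (two iid draws from the locus's observed allele-frequency
    vector); the drawn allele(s) get presence 1, the rest 0.
    """
    values = a.values.copy()
    rng = np.random.default_rng(seed)
    for locus in a.loci:
        cols = a.columns_of_locus(locus)
        sub = values[:, cols]
        missing_rows = np.where(np.isnan(sub).any(axis=1))[0]
        if missing_rows.size == 0:
            continue
        obs = sub[~np.isnan(sub).any(axis=1)]
        if obs.size == 0:
            raise ValueError(f"locus {locus} has no observed calls")
        contrib = obs / np.maximum(obs.sum(axis=1, keepdims=True), 1)
        freqs = contrib.mean(axis=0)
        freqs = freqs / freqs.sum()
        for i in missing_rows:
            pair = rng.choice(cols.size, size=2, p=freqs)
            row = np.zeros(cols.size)
            row[pair[0]] = 1.0
            row[pair[1]] = 1.0
            values[i, cols] = row
    return AlleleMatrix(
        values, list(a.individual_ids), list(a.column_loci), list(a.column_alleles)
    )
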