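"""Genomic relationship kernels, single-/multi-kernel GBLUP, and CV experiments.

The relationship matrix is VanRaden's numerator relationship: center dosages
by twice the allele frequency and scale by ``2 * sum p(1-p)``; for binary SSR
allele columns the same construction applies with the column frequency.  The
GBLUP model

    y = 1 mu + sum_k g_k + e,    g_k ~ N(0, A_k sigma2_k),  e ~ N(0, I sigma2_e)

is fitted by REML on the profiled criterion over variance ratios
``gamma_k = sigma2_k / sigma2_e``: with ``H = I + sum_k gamma_k A_k`` the
restricted deviance needs only a Cholesky of H per evaluation (or, for a
single kernel, one eigendecomposition up front and O(n) per evaluation).
BLUPs are ``g_k = gamma_k A_k H^{-1} (y - X beta)`` and out-of-sample genetic
values follow from the train/test kernel cross-blocks.

Prediction ability is the Pearson correlation between predicted genetic
values and the observed values (across-environment BLUEs) in the test set,
estimated by repeated random 80/20 partitions (one partition per round, the
usual "fivefold" resampling scheme; a strict disjoint-fold mode is available).
Partitions depend only on (seed, round, n), so models compared under the same
seed see identical partitions — a paired design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .markers import AlleleMatrix, GenotypeMatrix

__all__ = [
    "KernelSet",
    "GblupFit",
    "CVResult",
    "vanraden_kernel",
    "ssr_kernel",
    "fit_gblup",
    "predict",
    "cross_validate",
    "experiment_subset",
    "experiment_maf",
    "experiment_ld_prune",
    "experiment_combined",
]

_LOG2PI = np.log(2.0 * np.pi)


def vanraden_kernel(g: GenotypeMatrix, stabilization: float = 1e-6) -> np.ndarray:
    """VanRaden numerator relationship matrix from imputed dosages.

    ``K = W W' / (2 sum p(1-p))`` with ``W`` the dosages centered by ``2p``.
    A small diagonal inflation (``stabilization``) keeps the matrix positive
    definite.  Monomorphic markers must have been filtered out.
    """
    values = g.values
    if np.isnan(values).any():
        raise ValueError("kernel requires imputed (complete) genotypes")
    p = values.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic marker present; filter before building kernels")
    if values.shape[1] < 2:
        raise ValueError("need at least two polymorphic markers")
    W = values - 2.0 * p
    denom = 2.0 * float((p * (1 - p)).sum())
    K = (W @ W.T) / denom
    K[np.diag_indices_from(K)] += stabilization
    return K


def ssr_kernel(a: AlleleMatrix, stabilization: float = 1e-6) -> np.ndarray:
    """VanRaden-type relationship from binary allele-presence columns.

    Columns are centered by their presence frequency q and the matrix scaled
    by ``sum q(1-q)`` over columns.
    """
    values = a.values
    if np.isnan(values).any():
        raise ValueError("kernel requires imputed (complete) allele matrix")
    q = values.mean(axis=0)
    denom = float((q * (1 - q)).sum())
    if denom <= 0:
        raise ValueError("all allele columns monomorphic")
    W = values - q
    K = (W @ W.T) / denom
    K[np.diag_indices_from(K)] += stabilization
    return K


@dataclass
class KernelSet:
    """Named relationship matrices over a shared individual ordering."""

    individual_ids: list[str]
    kernels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        n = len(self.individual_ids)
        for name, K in self.kernels.items():
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name}: shape mismatch")
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"kernel {name}: not symmetric")
            try:
                np.linalg.cholesky(K + 1e-8 * np.eye(n))
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"kernel {name}: not PSD after stabilization") from exc
            self.kernels[name] = K

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def names(self) -> list[str]:
        return list(self.kernels)

    def subset(self, idx) -> "KernelSet":
        idx = np.asarray(idx)
        return KernelSet(
            [self.individual_ids[i] for i in idx],
            {k: K[np.ix_(idx, idx)] for k, K in self.kernels.items()},
        )

    def cross(self, test_idx, train_idx) -> dict[str, np.ndarray]:
        test_idx, train_idx = np.asarray(test_idx), np.asarray(train_idx)
        return {k: K[np.ix_(test_idx, train_idx)] for k, K in self.kernels.items()}


@dataclass
class GblupFit:
    """REML GBLUP fit: variance components, BLUPs and prediction state."""

    mu: float
    variance_by_kernel: dict[str, float]
    sigma2_e: float
    gamma: dict[str, float]
    random_effects: dict[str, np.ndarray]
    alpha: np.ndarray  # H^{-1} (y - mu)
    train_ids: list[str]
    deviance: float
    converged: bool
    n_iter: int


def _align_y(y, ids: list[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [i for i in ids if i not in y.index]
        if missing:
            raise ValueError(f"phenotypes missing for {len(missing)} individual(s)")
        return y.loc[ids].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size != len(ids):
        raise ValueError("y length does not match kernel individuals")
    return y


def _reml_deviance_chol(gammas, y, Ks):
    n = y.size
    H = np.eye(n)
    for g, K in zip(gammas, Ks):
        H += g * K
    c, low = cho_factor(H, lower=True)
    logdet_H = 2.0 * float(np.log(np.diag(c)).sum())
    Hi_y = cho_solve((c, low), y)
    ones = np.ones(n)
    Hi_1 = cho_solve((c, low), ones)
    xhx = float(ones @ Hi_1)
    mu = float(ones @ Hi_y) / xhx
    r = y - mu
    ypy = float(r @ cho_solve((c, low), r))
    df = n - 1
    sigma2 = max(ypy / df, 1e-300)
    dev = df * (_LOG2PI + np.log(sigma2) + 1.0) + logdet_H + np.log(xhx)
    return dev, mu, sigma2, (c, low)


def fit_gblup(
    y,
    kernels: KernelSet,
    fix_variances: dict[str, float] | None = None,
) -> GblupFit:
    """Fit single- or multi-kernel GBLUP by REML.

    ``y`` is an array aligned to ``kernels.individual_ids`` or a Series
    indexed by individual id.  ``fix_variances`` (kernel name -> variance,
    plus ``"residual"``) skips estimation and computes BLUPs at the given
    components.  Non-convergence is flagged on the result, never silent.
    """
    if not 1 <= len(kernels.kernels) <= 3:
        raise ValueError("expected 1 to 3 kernels")
    yv = _align_y(y, kernels.individual_ids)
    names = kernels.names
    Ks = [kernels.kernels[k] for k in names]
    n = yv.size

    if fix_variances is not None:
        s_e = float(fix_variances["residual"])
        if s_e <= 0:
            raise ValueError("fixed residual variance must be > 0")
        gammas = np.array([float(fix_variances[k]) / s_e for k in names])
        converged, n_iter = True, 0
        dev, mu, sigma2, cf = _reml_deviance_chol(gammas, yv, Ks)
        sigma2 = s_e  # honour the fixed scale
    elif len(Ks) == 1:
        eigval, eigvec = np.linalg.eigh(Ks[0])
        yt = eigvec.T @ yv
        ot = eigvec.T @ np.ones(n)

        def dev1(theta):
            g = theta * theta
            w = 1.0 / (1.0 + g * eigval)
            xhx = float((ot * ot * w).sum())
            mu_ = float((ot * yt * w).sum()) / xhx
            rt = yt - mu_ * ot
            ypy = float((rt * rt * w).sum())
            df = n - 1
            s2 = max(ypy / df, 1e-300)
            return (
                df * (_LOG2PI + np.log(s2) + 1.0)
                - float(np.log(w).sum())
                + np.log(xhx)
            )

        res = optimize.minimize_scalar(
            dev1, bounds=(0.0, 1e3), method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        theta = float(res.x)
        converged = bool(res.status == 0) if hasattr(res, "status") else True
        n_iter = int(getattr(res, "nfev", 0))
        gammas = np.array([theta * theta])
        dev, mu, sigma2, cf = _reml_deviance_chol(gammas, yv, Ks)
    else:
        def devk(theta):
            return _reml_deviance_chol(theta * theta, yv, Ks)[0]

        res = optimize.minimize(
            devk,
            np.ones(len(Ks)),
            method="L-BFGS-B",
            bounds=[(0.0, 1e3)] * len(Ks),
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if not res.success:
            # line searches can fail on the flat ridges of near-duplicate
            # kernels; the theta^2 parametrization lets Nelder-Mead polish
            polish = optimize.minimize(
                devk, res.x, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if polish.fun <= res.fun:
                res = polish
        gammas = res.x * res.x
        converged, n_iter = bool(res.success), int(res.nit)
        dev, mu, sigma2, cf = _reml_deviance_chol(gammas, yv, Ks)

    if not converged:
        warnings.warn("GBLUP REML did not report convergence; result flagged")
    alpha = cho_solve(cf, yv - mu)
    random_effects = {
        k: g * (K @ alpha) for k, g, K in zip(names, gammas, Ks)
    }
    return GblupFit(
        mu=float(mu),
        variance_by_kernel={k: float(g * sigma2) for k, g in zip(names, gammas)},
        sigma2_e=float(sigma2),
        gamma={k: float(g) for k, g in zip(names, gammas)},
        random_effects=random_effects,
        alpha=alpha,
        train_ids=list(kernels.individual_ids),
        deviance=float(dev),
        converged=converged,
        n_iter=n_iter,
    )


def predict(fit: GblupFit, kernel_cross: dict[str, np.ndarray]) -> np.ndarray:
    """Predicted genetic values for test individuals.

    ``kernel_cross`` maps each kernel name to its test × train block.  The
    prediction is ``mu + sum_k gamma_k K_k[test, train] H^{-1} (y - mu)``.
    """
    missing = set(fit.gamma) - set(kernel_cross)
    if missing:
        raise ValueError(f"missing cross blocks for kernels {sorted(missing)}")
    n_train = fit.alpha.size
    out = None
    for name, g in fit.gamma.items():
        Kc = np.asarray(kernel_cross[name], dtype=float)
        if Kc.shape[1] != n_train:
            raise ValueError(f"cross block {name}: train dimension mismatch")
        term = g * (Kc @ fit.alpha)
        out = term if out is None else out + term
    return fit.mu + out


@dataclass
class CVResult:
    """Cross-validated prediction ability over resampling rounds."""

    per_round_correlations: np.ndarray
    mean_ability: float
    sd_ability: float
    folds: int
    rounds: int
    scheme: str
    seed: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.per_round_correlations, dtype=float)
        if r.size and (np.abs(r) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if r.size:
            if not np.isclose(self.mean_ability, r.mean()):
                raise ValueError("mean inconsistent with correlation list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rounds": [self.rounds],
                "folds": [self.folds],
                "scheme": [self.scheme],
                "seed": [self.seed],
                "mean_ability": [self.mean_ability],
                "sd_ability": [self.sd_ability],
                "n_dropped": [self.n_dropped],
            }
        )


def _round_partitions(n: int, folds: int, rounds: int, seed: int, scheme: str):
    """Yield (train_idx, test_idx) pairs; depends only on (n, folds, rounds, seed)."""
    for rnd in range(rounds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rnd]))
        perm = rng.permutation(n)
        if scheme == "resample":
            n_test = n // folds
            yield perm[n_test:], perm[:n_test]
        elif scheme == "kfold":
            splits = np.array_split(perm, folds)
            for f in range(folds):
                test = splits[f]
                train = np.concatenate([splits[j] for j in range(folds) if j != f])
                yield train, test
        else:
            raise ValueError("scheme must be 'resample' or 'kfold'")


def cross_validate(
    y,
    kernels: KernelSet,
    folds: int = 5,
    rounds: int = 1000,
    seed: int = 0,
    scheme: str = "resample",
) -> CVResult:
    """Cross-validated prediction ability (Pearson r in the test set).

    Default scheme draws ONE random 80/20 train/test partition per round;
    ``scheme="kfold"`` instead evaluates all ``folds`` disjoint folds per
    round.  Variance components are re-estimated on every training set.
    Rounds whose test phenotypes are constant have no defined correlation and
    are dropped (counted).
    """
    yv = _align_y(y, kernels.individual_ids)
    n = yv.size
    if n < 25:
        raise ValueError("need at least 25 individuals for cross-validation")
    correlations = []
    n_dropped = 0
    for train, test in _round_partitions(n, folds, rounds, seed, scheme):
        if np.std(yv[test]) == 0:
            n_dropped += 1
            continue
        ktrain = kernels.subset(train)
        fit = fit_gblup(yv[train], ktrain)
        pred = predict(fit, kernels.cross(test, train))
        if np.std(pred) == 0:
            n_dropped += 1
            continue
        correlations.append(float(np.corrcoef(pred, yv[test])[0, 1]))
    correlations = np.array(correlations)
    return CVResult(
        per_round_correlations=correlations,
        mean_ability=float(correlations.mean()) if correlations.size else np.nan,
        sd_ability=float(correlations.std(ddof=1)) if correlations.size > 1 else np.nan,
        folds=folds,
        rounds=rounds,
        scheme=scheme,
        seed=seed,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# marker-set experiments


def experiment_subset(
    y,
    g: GenotypeMatrix,
    n_markers: int = 158,
    repeats: int = 5,
    cv_rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
):
    """Prediction ability of random sparse marker subsets.

    Per repeat, ``n_markers`` markers are drawn, a VanRaden kernel is built,
    and CV is run with partitions shared across repeats (paired design).
    Returns ``(list of CVResult, tidy summary DataFrame)``.
    """
    if n_markers > g.n_markers:
        raise ValueError("n_markers exceeds available markers")
    rng = np.random.default_rng(seed)
    results, rows = [], []
    for rep in range(repeats):
        idx = rng.choice(g.n_markers, size=n_markers, replace=False)
        K = vanraden_kernel(g.subset_markers(np.sort(idx)))
        ks = KernelSet(list(g.individual_ids), {"subset": K})
        cv = cross_validate(y, ks, folds=folds, rounds=cv_rounds, seed=seed)
        results.append(cv)
        rows.append(
            {"repeat": rep, "n_markers": n_markers,
             "mean_ability": cv.mean_ability, "sd_ability": cv.sd_ability}
        )
    return results, pd.DataFrame(rows)


def experiment_maf(
    y,
    g: GenotypeMatrix,
    thresholds=None,
    mode: str = "cumulative",
    cv_rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Prediction ability as a function of marker MAF.

    ``cumulative`` drops markers with MAF below each threshold in turn;
    ``interval`` uses disjoint MAF windows.  Returns a table of (window,
    marker count, mean ability, SD); windows leaving < 2 markers get NaN
    ability.
    """
    if np.isnan(g.values).any():
        raise ValueError("imputed genotypes required")
    p = g.values.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    if thresholds is None:
        thresholds = [0.0, 0.05, 0.1, 0.2] if mode == "cumulative" else [
            0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
        ]
    rows = []
    if mode == "cumulative":
        windows = [(float(t), 0.5, maf >= t) for t in thresholds]
    elif mode == "interval":
        edges = list(thresholds)
        windows = [
            (float(lo), float(hi), (maf >= lo) & (maf < hi if hi < 0.5 else maf <= hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
    else:
        raise ValueError("mode must be 'cumulative' or 'interval'")
    for lo, hi, mask in windows:
        n_markers = int(mask.sum())
        if n_markers < 2:
            rows.append(
                {"maf_low": lo, "maf_high": hi, "n_markers": n_markers,
                 "mean_ability": np.nan, "sd_ability": np.nan}
            )
            continue
        K = vanraden_kernel(g.subset_markers(np.where(mask)[0]))
        ks = KernelSet(list(g.individual_ids), {"maf": K})
        cv = cross_validate(y, ks, folds=folds, rounds=cv_rounds, seed=seed)
        rows.append(
            {"maf_low": lo, "maf_high": hi, "n_markers": n_markers,
             "mean_ability": cv.mean_ability, "sd_ability": cv.sd_ability}
        )
    return pd.DataFrame(rows)


def experiment_ld_prune(
    snp_g: GenotypeMatrix,
    gbs_g: GenotypeMatrix,
    r2_max: float = 0.95,
    chunk: int = 512,
):
    """Remove GBS markers in tight LD (r² > r2_max) with ANY array marker.

    r² is the squared Pearson correlation of imputed dosage vectors across the
    shared individuals.  Returns ``(pruned GBS matrix, report dict)``.
    """
    if snp_g.individual_ids != gbs_g.individual_ids:
        raise ValueError("matrices must cover the same individuals in the same order")
    if np.isnan(snp_g.values).any() or np.isnan(gbs_g.values).any():
        raise ValueError("both matrices must be imputed")
    A = _standardize(snp_g.values)
    B = _standardize(gbs_g.values)
    n = A.shape[0]
    max_r2 = np.zeros(B.shape[1])
    for start in range(0, B.shape[1], chunk):
        r = (A.T @ B[:, start : start + chunk]) / n
        max_r2[start : start + chunk] = (r * r).max(axis=0)
    remove = max_r2 > r2_max
    keep = np.where(~remove)[0]
    report = {
        "n_gbs_input": gbs_g.n_markers,
        "n_removed": int(remove.sum()),
        "fraction_removed": float(remove.mean()),
        "r2_max": r2_max,
    }
    return gbs_g.subset_markers(keep), report


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant marker column; filter monomorphic markers first")
    return (values - mean) / sd


def experiment_combined(
    snp_g: GenotypeMatrix,
    pruned_gbs_g: GenotypeMatrix,
    y,
    cv_rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
):
    """Merged single-kernel set (CGS) versus the two-kernel model.

    Column-concatenates the array and pruned GBS dosages into one VanRaden
    kernel and compares its CV ability (paired partitions) with the
    two-kernel fit on the separate matrices.  Returns a dict with both
    CVResults and the merged matrix.
    """
    if snp_g.individual_ids != pruned_gbs_g.individual_ids:
        raise ValueError("matrices must cover the same individuals in the same order")
    merged = GenotypeMatrix(
        np.hstack([snp_g.values, pruned_gbs_g.values]),
        list(snp_g.individual_ids),
        [f"snp:{m}" for m in snp_g.marker_ids]
        + [f"gbs:{m}" for m in pruned_gbs_g.marker_ids],
        platform_tag="other",
    )
    ids = list(snp_g.individual_ids)
    cgs = KernelSet(ids, {"cgs": vanraden_kernel(merged)})
    two = KernelSet(
        ids,
        {"snp": vanraden_kernel(snp_g), "gbs": vanraden_kernel(pruned_gbs_g)},
    )
    cv_cgs = cross_validate(y, cgs, folds=folds, rounds=cv_rounds, seed=seed)
    cv_two = cross_validate(y, two, folds=folds, rounds=cv_rounds, seed=seed)
    return {"cgs": cv_cgs, "two_kernel": cv_two, "merged": merged}
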