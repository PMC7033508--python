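"""Variance-component estimation for models with independent random factors.

Fits y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k I) and
e ~ N(0, sigma2_e I) by restricted maximum likelihood.  The criterion is the
profiled REML deviance of the penalized-least-squares formulation (the same
criterion lme4 optimises): with variance ratios gamma_k = sigma2_k / sigma2_e
and the scaled coefficients u_k = sqrt(gamma_k) * u~_k, the mixed-model
equations become an ordinary penalized system whose Cholesky factor yields the
two log-determinants and the penalized residual sum of squares; sigma2_e is
profiled out in closed form.  The deviance is minimised over
theta_k = sqrt(gamma_k) >= 0 with a bounded quasi-Newton method, which reaches
the REML optimum deterministically and handles boundary estimates
(sigma2_k = 0) cleanly.

For speed the random factor with the most levels is absorbed (Schur
complement) before the dense Cholesky — its diagonal block in the system is
itself diagonal, so crossed designs with one large factor (e.g. a
genotype-by-environment interaction) cost only the small remaining system per
function evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize

__all__ = ["FactorTerm", "MixedFit", "fit_factor_model", "term_from_labels"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FactorTerm:
    """A random grouping factor: one level index per observation."""

    name: str
    codes: np.ndarray
    level_names: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=-1) >= len(
            self.level_names
        ):
            raise ValueError(f"term {self.name}: codes out of range")

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    def Z(self) -> sp.csr_matrix:
        n = self.codes.size
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.codes)), shape=(n, self.n_levels)
        )


def term_from_labels(name: str, labels) -> FactorTerm:
    labels = pd.Series(labels).astype(str)
    levels = list(dict.fromkeys(labels))
    index = {l: i for i, l in enumerate(levels)}
    return FactorTerm(name, labels.map(index).to_numpy(), levels)


@dataclass
class MixedFit:
    """REML fit of a factor mixed model."""

    beta: np.ndarray
    u: dict[str, np.ndarray]
    sigma2: dict[str, float]  # per random term plus 'residual'
    gamma: dict[str, float]
    deviance: float  # -2 * restricted log-likelihood
    converged: bool
    n_iter: int
    n_obs: int
    p: int
    fitted: np.ndarray


class _PLS:
    """Precomputed cross-products and per-theta deviance evaluation."""

    def __init__(self, y, X, terms):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if y.size != n:
            raise ValueError("y/X length mismatch")
        if n <= p:
            raise ValueError("model is saturated: no residual degrees of freedom")
        self.y, self.X, self.terms = y, X, terms
        self.n, self.p = n, p
        self.yty = float(y @ y)

        Zs = [t.Z() for t in terms]
        qs = [t.n_levels for t in terms]
        # absorb the largest factor when it dominates the system
        self.absorb = None
        if terms:
            a = int(np.argmax(qs))
            if qs[a] > 150 and qs[a] > 2 * (sum(qs) - qs[a] + p):
                self.absorb = a
        self.rest = [k for k in range(len(terms)) if k != self.absorb]

        self.counts = None
        self.A_a = None
        if self.absorb is not None:
            Za = Zs[self.absorb]
            self.counts = np.asarray((Za.multiply(Za)).sum(axis=0)).ravel()
            blocks = [Za.T @ Zs[j] for j in self.rest] + [sp.csr_matrix(Za.T @ X)]
            self.A_a = blocks  # list of sparse (q_a x q_j / p)
            self.r_a = Za.T @ y

        self.q_rest = [qs[j] for j in self.rest]
        self.m_z = int(sum(self.q_rest))
        self.m = self.m_z + p
        # dense cross products of the small part
        self.ZtZ = {}
        for ii, i in enumerate(self.rest):
            for jj, j in enumerate(self.rest):
                if jj < ii:
                    continue
                self.ZtZ[(ii, jj)] = (Zs[i].T @ Zs[j]).toarray()
        self.ZtX = [(Zs[j].T @ X) for j in self.rest]
        self.ZtX = [np.asarray(zx.todense()) if sp.issparse(zx) else zx for zx in self.ZtX]
        self.Zty = [Zs[j].T @ y for j in self.rest]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.offsets = np.concatenate([[0], np.cumsum(self.q_rest)]).astype(int)

    def _assemble(self, theta):
        sl = np.abs(np.asarray(theta, dtype=float))
        m, m_z, p = self.m, self.m_z, self.p
        C = np.zeros((m, m))
        rhs = np.zeros(m)
        for ii, i in enumerate(self.rest):
            o_i = self.offsets[ii]
            q_i = self.q_rest[ii]
            for jj, j in enumerate(self.rest):
                if jj < ii:
                    continue
                o_j = self.offsets[jj]
                block = sl[i] * sl[j] * self.ZtZ[(ii, jj)]
                C[o_i : o_i + q_i, o_j : o_j + self.q_rest[jj]] = block
                if ii != jj:
                    C[o_j : o_j + self.q_rest[jj], o_i : o_i + q_i] = block.T
            C[o_i : o_i + q_i, o_i : o_i + q_i] += np.eye(q_i)
            xb = sl[i] * self.ZtX[ii]
            C[o_i : o_i + q_i, m_z:] = xb
            C[m_z:, o_i : o_i + q_i] = xb.T
            rhs[o_i : o_i + q_i] = sl[i] * self.Zty[ii]
        C[m_z:, m_z:] = self.XtX
        rhs[m_z:] = self.Xty
        return C, rhs, sl

    def deviance(self, theta, want_solution=False):
        C, rhs, sl = self._assemble(theta)
        logdet_absorbed = 0.0
        u_a = None
        r_a_s = None
        d = None
        B = None
        if self.absorb is not None:
            a = self.absorb
            g_a = sl[a] ** 2
            d = g_a * self.counts + 1.0
            logdet_absorbed = float(np.log(d).sum())
            scaled = []
            for jj, j in enumerate(self.rest):
                scaled.append(sl[a] * sl[j] * self.A_a[jj])
            scaled.append(sl[a] * self.A_a[-1])
            B = sp.hstack(scaled, format="csr") if scaled else None
            r_a_s = sl[a] * self.r_a
            if B is not None and B.nnz:
                Bd = B.multiply((1.0 / d)[:, None]).tocsr()
                C -= (B.T @ Bd).toarray()
                rhs_schur = rhs - B.T @ (r_a_s / d)
            else:
                rhs_schur = rhs
        else:
            rhs_schur = rhs

        L = _chol(C)
        sol = _chol_solve(L, rhs_schur)
        diag = np.diag(L)
        logdet_zz = logdet_absorbed + 2.0 * float(np.log(diag[: self.m_z]).sum())
        logdet_x = 2.0 * float(np.log(diag[self.m_z :]).sum())

        r2 = self.yty - float(sol @ rhs)
        if self.absorb is not None:
            u_a = (r_a_s - (B @ sol if B is not None else 0.0)) / d
            r2 -= float(u_a @ r_a_s)
        r2 = max(r2, 1e-300)
        df = self.n - self.p
        sigma2 = r2 / df
        dev = df * (_LOG2PI + np.log(sigma2) + 1.0) + logdet_zz + logdet_x
        if not want_solution:
            return dev
        return dev, sol, u_a, sigma2, sl


def _chol(C):
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(1.0, float(np.trace(C)) / max(C.shape[0], 1))
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


def _chol_solve(L, b):
    from scipy.linalg import solve_triangular

    z = solve_triangular(L, b, lower=True)
    return solve_triangular(L.T, z, lower=False)


def fit_factor_model(
    y,
    X,
    terms: list[FactorTerm],
    fix_gammas: dict[str, float] | None = None,
    theta_max: float = 1e3,
) -> MixedFit:
    """REML fit; ``fix_gammas`` skips estimation (variance ratios held fixed)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not terms:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = max(y.size - X.shape[1], 1)
        s2 = float(resid @ resid) / df
        return MixedFit(
            beta=beta,
            u={},
            sigma2={"residual": s2},
            gamma={},
            deviance=float(df * (_LOG2PI + np.log(max(s2, 1e-300)) + 1.0)),
            converged=True,
            n_iter=0,
            n_obs=y.size,
            p=X.shape[1],
            fitted=X @ beta,
        )

    pls = _PLS(y, X, terms)
    names = [t.name for t in terms]
    if fix_gammas is not None:
        theta = np.sqrt([max(fix_gammas[n], 0.0) for n in names])
        converged, n_iter = True, 0
    else:
        theta0 = np.ones(len(terms))
        res = optimize.minimize(
            pls.deviance,
            theta0,
            method="L-BFGS-B",
            bounds=[(0.0, theta_max)] * len(terms),
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success:
            polish = optimize.minimize(
                lambda t: pls.deviance(np.abs(t)), res.x, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if polish.fun <= res.fun:
                res = polish
                res.x = np.abs(res.x)
        theta, converged, n_iter = res.x, bool(res.success), int(res.nit)

    dev, sol, u_a, sigma2_e, sl = pls.deviance(theta, want_solution=True)
    u: dict[str, np.ndarray] = {}
    for jj, j in enumerate(pls.rest):
        o = pls.offsets[jj]
        u[names[j]] = sl[j] * sol[o : o + pls.q_rest[jj]]
    if pls.absorb is not None:
        u[names[pls.absorb]] = sl[pls.absorb] * u_a
    beta = sol[pls.m_z :]

    gamma = {n: float(sl[k] ** 2) for k, n in enumerate(names)}
    sigma2 = {n: gamma[n] * sigma2_e for n in names}
    sigma2["residual"] = float(sigma2_e)
    fitted = X @ beta
    for t in terms:
        fitted = fitted + u[t.name][t.codes]
    return MixedFit(
        beta=beta,
        u=u,
        sigma2=sigma2,
        gamma=gamma,
        deviance=float(dev),
        converged=converged,
        n_iter=n_iter,
        n_obs=pls.n,
        p=pls.p,
        fitted=fitted,
    )
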