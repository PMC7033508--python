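"""Population structure: classical PCoA and Mantel matrix correlation.

Principal coordinates analysis is classical (Torgerson/Gower) scaling: square
the distances, double-center, eigendecompose; coordinates are eigenvectors
scaled by the square root of their (positive) eigenvalues.  Negative
eigenvalues — which arise because an averaged Rogers' distance matrix need not
be Euclidean — are dropped from coordinates and from the explained-variance
denominator, and their count is reported.

The Mantel statistic is the Pearson correlation of the strictly-lower-triangle
entries of two aligned distance matrices, optionally with a permutation null
obtained by relabelling the individuals of the second matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix

__all__ = ["PCoAResult", "pcoa", "mantel"]


@dataclass
class PCoAResult:
    """Coordinates and spectrum of a classical-scaling ordination."""

    coordinates: np.ndarray  # individuals x retained axes
    eigenvalues: np.ndarray  # positive, non-increasing (retained axes)
    explained_fraction: np.ndarray
    n_negative_eigenvalues: int
    individual_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.individual_ids,
            columns=[f"PC{k + 1}" for k in range(self.coordinates.shape[1])],
        )
        df.index.name = "individual"
        return df

    def eigen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, self.eigenvalues.size + 1),
                "eigenvalue": self.eigenvalues,
                "explained_fraction": self.explained_fraction,
            }
        )


def pcoa(d: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Classical multidimensional scaling of a distance matrix.

    Axis signs are fixed by forcing the largest-magnitude loading on each axis
    to be positive, so results are reproducible despite eigenvector sign
    ambiguity.
    """
    D = np.asarray(d.values, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-10, 1e-10 * abs(eigval[0])) if n else 0.0
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    pos_vals = eigval[positive]
    pos_vecs = eigvec[:, positive]
    total = pos_vals.sum()

    k = min(n_axes, pos_vals.size)
    coords = pos_vecs[:, :k] * np.sqrt(pos_vals[:k])
    for j in range(k):
        lead = np.argmax(np.abs(coords[:, j]))
        if coords[lead, j] < 0:
            coords[:, j] = -coords[:, j]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=pos_vals[:k],
        explained_fraction=pos_vals[:k] / total if total > 0 else np.zeros(k),
        n_negative_eigenvalues=n_negative,
        individual_ids=list(d.individual_ids),
    )


def _align(d1: DistanceMatrix, d2: DistanceMatrix):
    if set(d1.individual_ids) != set(d2.individual_ids):
        raise ValueError("distance matrices cover different individuals")
    if d1.individual_ids == d2.individual_ids:
        return d1.values, d2.values
    pos = {ind: i for i, ind in enumerate(d2.individual_ids)}
    order = np.array([pos[ind] for ind in d1.individual_ids])
    return d1.values, d2.values[np.ix_(order, order)]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 0,
    seed: int = 0,
):
    """Mantel correlation between two distance matrices (aligned by id).

    Returns the correlation, or ``(correlation, p_value)`` when
    ``permutations > 0``.  The permutation p-value is one-sided ("greater"):
    the fraction of label permutations of the second matrix whose correlation
    is at least the observed one (observed included in the numerator).
    """
    a, b = _align(d1, d2)
    n = a.shape[0]
    i, j = np.tril_indices(n, k=-1)
    x, y = a[i, j], b[i, j]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) distance matrix")
    r = float(np.corrcoef(x, y)[0, 1])
    if permutations <= 0:
        return r
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        rp = np.corrcoef(x, bp[i, j])[0, 1]
        if rp >= r:
            count += 1
    return r, count / (permutations + 1)
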