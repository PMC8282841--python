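"""PCA of the band matrix and the per-accession Shannon index.

Covariance PCA on the centered 0/1 locus columns (divisor n-1): eigenvalues
on binary data are then bounded by the locus count times 1/4 and match the
scale conventions of the classical numerical-taxonomy programs.  Missing
cells are mean-imputed per locus before centering.

The per-accession Shannon index H' treats an individual's presence profile
as an equal-weight composition: with b bands present, H' = log10(b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix

__all__ = ["PCAResult", "pca", "accession_shannon"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray       # descending, >= 0
    pct_variation: np.ndarray     # percent per axis, sums to 100
    cumulative_pct: np.ndarray
    scores: pd.DataFrame          # individuals x axes
    loadings: pd.DataFrame        # loci x axes

    def summary(self, n_axes: int = 9) -> pd.DataFrame:
        k = min(n_axes, len(self.eigenvalues))
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues[:k],
                "pct_variation": self.pct_variation[:k],
                "cumulative_pct": self.cumulative_pct[:k],
            },
            index=[f"PC{i + 1}" for i in range(k)],
        )


def _impute_center(m: BandMatrix) -> np.ndarray:
    X = m.data.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    return X - X.mean(axis=0)


def pca(m: BandMatrix, n_axes: int | None = None) -> PCAResult:
    """Eigen-decomposition of the covariance of the centered band matrix.

    Sign convention: on each axis the loading of largest magnitude is made
    positive, so results are deterministic across platforms.
    """
    if m.n_individuals < 2 or m.n_loci < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 loci")
    Xc = _impute_center(m)
    if np.allclose(Xc, 0.0):
        raise ValueError("constant matrix: all eigenvalues are zero")
    n = Xc.shape[0]
    # SVD of the centered matrix == eigen-decomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s * s / (n - 1)
    k = min(n_axes or len(lam), len(lam))
    lam = lam[:k]
    V = Vt[:k].T                      # loci x axes
    scores = U[:, :k] * s[:k]         # individuals x axes
    for j in range(k):
        i_max = np.argmax(np.abs(V[:, j]))
        if V[i_max, j] < 0:
            V[:, j] = -V[:, j]
            scores[:, j] = -scores[:, j]
    total = (s * s / (n - 1)).sum()
    pct = 100.0 * lam / total
    axes = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        eigenvalues=lam,
        pct_variation=pct,
        cumulative_pct=np.cumsum(pct),
        scores=pd.DataFrame(scores, index=m.individual_ids, columns=axes),
        loadings=pd.DataFrame(V, index=m.locus_ids, columns=axes),
    )


def accession_shannon(m: BandMatrix, individual: str | None = None):
    """Shannon diversity H' of an individual's presence profile (log base 10).

    With equal weight on each present band, H' = -sum p_j log10 p_j reduces
    to log10 of the number of bands present.  Returns a float for one
    individual, or a Series over all individuals when none is named.
    """
    def one(idx: int, name: str) -> float:
        row = m.data[idx]
        b = np.nansum(row)
        if b < 1:
            raise ValueError(f"individual {name!r} shows no band")
        return float(np.log10(b))

    if individual is not None:
        return one(m.individual_ids.index(individual), individual)
    return pd.Series(
        {name: one(i, name) for i, name in enumerate(m.individual_ids)},
        name="H_prime",
    )
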