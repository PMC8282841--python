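"""Nei identity/distance matrices and agglomerative trees (UPGMA, Ward).

Nei's normalized gene identity between units x and y over bi-allelic loci is
I = Jxy / sqrt(Jx Jy) with Jxy the mean over loci of p_x p_y + q_x q_y and
Jx, Jy the within-unit analogues; the distance is GD = -ln I.  At the
population level the frequencies come from the HWE dominant estimator; at
the individual level the 0/1 band states are used directly as frequencies
(the GenAlEx convention for dominant data).

UPGMA merges the closest pair, averaging distances with cluster-size
weights; heights are half the merge distance, so the tree is ultrametric.
Ward linkage applies the Lance-Williams update on unsquared distances (the
``ward.D`` variant used for binary-data heatmap ordering).  Merge ties are
broken by the lexicographically smallest label pair so trees are
reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix
from .diversity import estimate_allele_freq
from .trees import Tree, TreeNode

__all__ = [
    "DistanceMatrix",
    "nei_identity",
    "nei_distance",
    "pairwise_matrix",
    "euclidean_matrix",
    "upgma",
    "ward_linkage",
    "identity_distance_report",
]

DEFAULT_DISTANCE_CAP = 10.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "nei"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def capped(self, cap: float = DEFAULT_DISTANCE_CAP) -> "DistanceMatrix":
        v = np.where(np.isfinite(self.values), self.values, cap)
        return DistanceMatrix(self.labels, v, self.kind)


def nei_identity(freq_x: np.ndarray, freq_y: np.ndarray) -> float:
    """Nei's normalized identity over a shared set of bi-allelic loci."""
    px = np.asarray(freq_x, dtype=float)
    py = np.asarray(freq_y, dtype=float)
    if px.shape != py.shape:
        raise ValueError("frequency vectors must share the locus set")
    qx, qy = 1.0 - px, 1.0 - py
    jxy = float(np.mean(px * py + qx * qy))
    jx = float(np.mean(px * px + qx * qx))
    jy = float(np.mean(py * py + qy * qy))
    return jxy / np.sqrt(jx * jy)


def nei_distance(identity: float) -> float:
    """GD = -ln I; identity 0 gives +inf."""
    if identity > 1.0 + 1e-9 or identity < -1e-12:
        raise ValueError("identity must lie in [0, 1]")
    identity = min(max(identity, 0.0), 1.0)
    if identity == 0.0:
        return float("inf")
    return -float(np.log(identity))


def _unit_frequencies(m: BandMatrix, level: str, lynch_milligan: bool = False):
    """(labels, frequency matrix) for the requested aggregation level."""
    if level == "individual":
        labels, rows = [], []
        for i, ind in enumerate(m.individual_ids):
            row = m.data[i]
            if not np.isfinite(row).any():
                warnings.warn(f"individual {ind!r} has no scored locus; excluded")
                continue
            labels.append(ind)
            rows.append(np.nan_to_num(row, nan=np.nan))
        return labels, np.array(rows)
    if level == "population":
        labels, rows = [], []
        for pop in m.populations:
            sub = m.data[m.individuals_of_population(pop)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                b = np.nanmean(sub, axis=0)
            n_obs = np.isfinite(sub).sum(axis=0)
            p, _ = estimate_allele_freq(np.nan_to_num(b), np.maximum(n_obs, 1), lynch_milligan)
            labels.append(pop)
            rows.append(p)
        return labels, np.array(rows)
    raise ValueError(f"unknown level {level!r}")


def pairwise_matrix(
    m: BandMatrix,
    level: str = "individual",
    lynch_milligan: bool = False,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Full Nei distance matrix plus the identity matrix for all unit pairs.

    Pairwise comparisons use only loci scored in both units (pairwise
    deletion of missing cells).
    """
    labels, F = _unit_frequencies(m, level, lynch_milligan)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two units")
    ident = np.ones((n, n))
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = np.isfinite(F[a]) & np.isfinite(F[b])
            I = nei_identity(F[a][ok], F[b][ok])
            ident[a, b] = ident[b, a] = I
            gd = nei_distance(I)
            dist[a, b] = dist[b, a] = gd
    return DistanceMatrix(labels, dist, "nei"), ident


def euclidean_matrix(m: BandMatrix, axis: str = "individuals") -> DistanceMatrix:
    """Plain Euclidean distances between 0/1 rows (individuals) or columns
    (loci), for heatmap ordering; missing cells are mean-imputed per locus."""
    X = m.data.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.nan_to_num(col_mean, nan=0.0)[inds[1]]
    if axis == "loci":
        X = X.T
        labels = list(m.locus_ids)
    elif axis == "individuals":
        labels = list(m.individual_ids)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(labels, np.sqrt(sq), "euclidean")


# -- agglomeration ---------------------------------------------------------


def _agglomerate(d: DistanceMatrix, update: str, ultrametric: bool) -> Tree:
    v = d.values.copy()
    if not np.isfinite(v).all():
        raise ValueError(
            "distance matrix contains infinite entries; cap them first "
            "(DistanceMatrix.capped) before tree building"
        )
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two units")
    nodes = {i: TreeNode(d.labels[i], 0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    # a cluster's label for tie-breaking = smallest member label
    tags = {i: d.labels[i] for i in range(n)}
    active = list(range(n))
    dist = {(min(a, b), max(a, b)): v[a, b] for ai, a in enumerate(active) for b in active[ai + 1:]}
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                key = (min(a, b), max(a, b))
                dd = dist[key]
                pair_tag = tuple(sorted((tags[a], tags[b])))
                cand = (dd, pair_tag, key)
                if best is None or cand < best:
                    best = cand
        dd, _, (a, b) = best
        height = dd / 2.0 if ultrametric else dd
        merged = TreeNode(None, height, [nodes[a], nodes[b]])
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            if update == "upgma":
                dnew = (na * dac + nb * dbc) / (na + nb)
            elif update == "ward":
                nc = sizes[c]
                dnew = ((na + nc) * dac + (nb + nc) * dbc - nc * dd) / (na + nb + nc)
            else:  # pragma: no cover
                raise ValueError(update)
            dist[(min(next_id, c), max(next_id, c))] = dnew
        active = [c for c in active if c not in (a, b)] + [next_id]
        nodes[next_id] = merged
        sizes[next_id] = na + nb
        tags[next_id] = min(tags[a], tags[b])
        next_id += 1
    return Tree(nodes[active[0]])


def upgma(d: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage (UPGMA) ultrametric tree; node height is
    half the merge distance."""
    return _agglomerate(d, "upgma", ultrametric=True)


def ward_linkage(d: DistanceMatrix) -> Tree:
    """Ward linkage via the Lance-Williams update on unsquared distances
    (the ward.D variant); node height is the merge cost."""
    return _agglomerate(d, "ward", ultrametric=False)


def identity_distance_report(dist: DistanceMatrix, identity: np.ndarray) -> pd.DataFrame:
    """Combined square table: distances below the diagonal, identities above."""
    n = len(dist.labels)
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    il = np.tril_indices(n, -1)
    out[iu] = identity[iu]
    out[il] = dist.values[il]
    return pd.DataFrame(out, index=dist.labels, columns=dist.labels)
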