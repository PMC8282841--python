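"""Synthetic dominant-marker band matrices with known population structure.

The generator follows the standard admixture model with correlated allele
frequencies.  An ancestral band-allele frequency is drawn per locus; each of
K latent clusters receives its own frequency from the Balding-Nichols
distribution Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the ancestral p and
whose dispersion is governed by the cluster-specific differentiation F_k.
Each individual carries admixture proportions Q_i (Dirichlet draws, or
one-hot vectors when populations map deterministically to clusters) and, at
every locus, two allele copies sampled under Hardy-Weinberg equilibrium:
each copy's cluster of origin is Categorical(Q_i) and its allelic state
Bernoulli(p_cluster).  A band is scored iff at least one copy carries the
presence allele, so P(band absent) = (sum_k Q_ik (1 - p_kl))^2 -- the
dominant phenotype a gel actually shows.

The default configuration mirrors the study design this package targets:
11 labelled populations of 4 individuals, a 32-primer panel with 11-22 loci
per primer, K = 3 latent clusters with F = (0.19, 0.37, 0.40).

Randomness: one ``numpy.random.SeedSequence`` per run, split into named
sub-streams in a fixed, documented order (frequencies, admixture, bands,
missingness), so identical config + seed gives bit-identical output
regardless of what else the caller does with NumPy's global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandmatrix import BandMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cluster_freqs",
    "simulate_admixture",
    "simulate_dominant_bands",
    "simulate_dataset",
]


def _default_pop_to_cluster() -> tuple[int, ...]:
    # 11 populations split contiguously over 3 clusters (4 + 3 + 4)
    return (0, 0, 0, 0, 1, 1, 1, 2, 2, 2, 2)


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the desk-scale stand-in
    for the unpublished 44 x ~510 Bambara groundnut panel."""

    K: int = 3
    n_pops: int = 11
    n_per_pop: int = 4
    pop_to_cluster: tuple[int, ...] | None = field(default_factory=_default_pop_to_cluster)
    alpha: float | None = None  # Dirichlet admixture parameter; None = pure assignment
    n_primers: int = 32
    loci_per_primer: tuple[int, int] = (11, 22)
    F_k: tuple[float, ...] = (0.19, 0.37, 0.40)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.F_k) != self.K:
            raise ValueError("need one F value per cluster")
        for f in self.F_k:
            if not 0.0 <= f < 1.0:
                raise ValueError("F must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.loci_per_primer
        if lo < 1 or hi < lo:
            raise ValueError("invalid loci_per_primer range")
        if self.alpha is None and self.pop_to_cluster is None:
            raise ValueError("need either alpha (admixed) or pop_to_cluster (pure)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.pop_to_cluster is not None:
            if len(self.pop_to_cluster) != self.n_pops:
                raise ValueError("pop_to_cluster must map every population")
            if any(not 0 <= c < self.K for c in self.pop_to_cluster):
                raise ValueError("cluster index out of range")


@dataclass
class SimulationTruth:
    """Latent quantities behind a simulated matrix, for recovery tests."""

    Q_true: np.ndarray          # (n, K) admixture proportions
    p_ancestral: np.ndarray     # (L,) ancestral band-allele frequencies
    p_cluster: np.ndarray       # (K, L) cluster band-allele frequencies
    F_k: np.ndarray             # (K,)
    cluster_of_pop: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q_true.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q_true rows must sum to 1")
        for arr in (self.p_ancestral, self.p_cluster):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("frequencies must lie in [0, 1]")


def simulate_cluster_freqs(
    p_ancestral: np.ndarray,
    F_k: np.ndarray | tuple[float, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols cluster frequencies around an ancestral vector.

    p_cluster[k, l] ~ Beta(p_l (1-F_k)/F_k, (1-p_l)(1-F_k)/F_k), i.e. mean
    p_l and variance F_k p_l (1-p_l).  F_k = 0 copies the ancestral vector
    exactly; F_k = 1 is rejected (degenerate two-point distribution).
    """
    p = np.asarray(p_ancestral, dtype=float)
    F = np.atleast_1d(np.asarray(F_k, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if np.any((F < 0) | (F >= 1)):
        raise ValueError("F must lie in [0, 1)")
    out = np.empty((F.size, p.size))
    for k, f in enumerate(F):
        if f == 0.0:
            out[k] = p
        else:
            ratio = (1.0 - f) / f
            out[k] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return out


def simulate_admixture(
    n: int,
    K: int,
    rng: np.random.Generator,
    alpha: float | None = None,
    pop_of: np.ndarray | None = None,
    pop_to_cluster: np.ndarray | tuple[int, ...] | None = None,
) -> np.ndarray:
    """Admixture proportions: symmetric Dirichlet rows, or one-hot rows when a
    hard population -> cluster assignment is supplied."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha is not None:
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        return rng.dirichlet(np.full(K, alpha), size=n)
    if pop_of is None or pop_to_cluster is None:
        raise ValueError("pure mode needs pop_of and pop_to_cluster")
    mapping = np.asarray(pop_to_cluster, dtype=int)
    Q = np.zeros((n, K))
    Q[np.arange(n), mapping[np.asarray(pop_of, dtype=int)]] = 1.0
    return Q


def simulate_dominant_bands(
    Q_true: np.ndarray,
    p_cluster: np.ndarray,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    missing_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Diploid dominant phenotypes: band = 1 iff either allele copy is a
    presence allele.  Returns an (n, L) float array with nan for masked cells."""
    Q = np.asarray(Q_true, dtype=float)
    P = np.asarray(p_cluster, dtype=float)
    n, K = Q.shape
    if P.shape[0] != K:
        raise ValueError("Q and p_cluster disagree on K")
    L = P.shape[1]
    # P(copy is null | i, l) = sum_k Q_ik (1 - P_kl); two independent copies
    null_prob = Q @ (1.0 - P)                       # (n, L)
    u = rng.random((2, n, L))
    band = ((u[0] >= null_prob) | (u[1] >= null_prob)).astype(float)
    if missing_rate > 0.0:
        mrng = missing_rng if missing_rng is not None else rng
        band[mrng.random((n, L)) < missing_rate] = np.nan
    return band


def simulate_dataset(config: SimulationConfig | None = None) -> tuple[BandMatrix, SimulationTruth]:
    """Draw a complete synthetic panel under *config* (defaults = study scale)."""
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_admix, rng_bands, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    loci_counts = rng_freq.integers(
        cfg.loci_per_primer[0], cfg.loci_per_primer[1] + 1, size=cfg.n_primers
    )
    L = int(loci_counts.sum())
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng_freq.uniform(lo, hi, size=L)
    p_cluster = simulate_cluster_freqs(p_anc, np.asarray(cfg.F_k), rng_freq)

    n = cfg.n_pops * cfg.n_per_pop
    pop_of = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    Q = simulate_admixture(
        n,
        cfg.K,
        rng_admix,
        alpha=cfg.alpha,
        pop_of=None if cfg.alpha is not None else pop_of,
        pop_to_cluster=None if cfg.alpha is not None else cfg.pop_to_cluster,
    )
    data = simulate_dominant_bands(
        Q, p_cluster, rng_bands, missing_rate=cfg.missing_rate, missing_rng=rng_miss
    )

    individual_ids = [f"G{i + 1}" for i in range(n)]
    population_of = {
        f"G{i + 1}": f"Pop{pop_of[i] + 1}" for i in range(n)
    }
    locus_ids: list[str] = []
    primer_of: dict[str, str] = {}
    for pi, cnt in enumerate(loci_counts):
        primer = f"P{pi + 1:02d}"
        for j in range(cnt):
            lid = f"{primer}:{j + 1}"
            locus_ids.append(lid)
            primer_of[lid] = primer

    m = BandMatrix(data, individual_ids, locus_ids, primer_of, population_of)
    truth = SimulationTruth(
        Q_true=Q,
        p_ancestral=p_anc,
        p_cluster=p_cluster,
        F_k=np.asarray(cfg.F_k, dtype=float),
        cluster_of_pop=None if cfg.pop_to_cluster is None else np.asarray(cfg.pop_to_cluster),
    )
    return m, truth
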