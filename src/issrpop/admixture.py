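"""Bayesian admixture inference for dominant markers.

The model is the classic K-cluster admixture model with correlated allele
frequencies, adapted to dominant diploid phenotypes.  Each individual i has
admixture proportions Q_i on the K-simplex (symmetric Dirichlet(alpha)
prior) and carries, at each locus l, two latent allele copies; a copy's
cluster of origin is Categorical(Q_i) and its allelic state is
Bernoulli(P_kl), the cluster band-allele frequency.  A band is observed iff
at least one copy carries the presence allele, so

    P(band absent | Q_i, P) = (sum_k Q_ik (1 - P_kl))^2.

Under the correlated-frequencies model P_kl has a Balding-Nichols prior
Beta(p_l (1-F_k)/F_k, (1-p_l)(1-F_k)/F_k) around an ancestral frequency
p_l, with a per-cluster differentiation parameter F_k — the fixation index
the report prints.  The independent model uses Beta(1, 1).

Inference is by Gibbs sampling: (a) each copy's (cluster, allelic state)
from its exact joint full conditional given the observed band, (b) P from
its conjugate Beta conditional, (c) Q from its Dirichlet conditional,
(d) F_k and the ancestral p_l by random-walk Metropolis on the logit scale,
(e) the observed-data log-likelihood is accumulated each sweep.  Posterior
means over post-burn-in sweeps are reported.  A haploid phenotype mode
(band = single allele copy) is available for panels coded that way.

Model selection uses the model's estimated ln P(D) = mean(lnL) - var(lnL)/2
per run and the Evanno second-difference statistic
DeltaK = |L''(K)| / sd(L(K)) across independent runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import betaln, expit, logit

from .bandmatrix import BandMatrix

__all__ = [
    "AdmixtureConfig",
    "AdmixtureModel",
    "AdmixtureResults",
    "EvannoTable",
    "lnpd",
    "evanno",
    "cluster_divergence",
    "classify_membership",
    "align_runs",
    "fit_k_range",
    "fst_interpretation",
]

_EPS = 1e-9
_PCLIP = 1e-6


@dataclass
class AdmixtureConfig:
    """Sampler settings.  Desk-scale defaults: 2,000 burn-in and 10,000
    recorded sweeps; scale up for publication-grade runs."""

    burnin: int = 2000
    sweeps: int = 10000
    alpha: float = 1.0
    infer_alpha: bool = True
    alpha_bounds: tuple[float, float] = (0.02, 10.0)
    alpha_step: float = 0.3               # log-scale random walk
    freq_model: str = "correlated"        # or "independent"
    genotype_model: str = "dominant-diploid"  # or "haploid"
    f_bounds: tuple[float, float] = (0.001, 0.999)
    f_step: float = 0.4
    anc_step: float = 0.8

    def __post_init__(self) -> None:
        if self.burnin < 1 or self.sweeps < 1:
            raise ValueError("burnin and sweeps must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.freq_model not in {"correlated", "independent"}:
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        if self.genotype_model not in {"dominant-diploid", "haploid"}:
            raise ValueError(f"unknown genotype_model {self.genotype_model!r}")


@dataclass
class AdmixtureResults:
    """Posterior summaries of one fitted chain."""

    K: int
    individual_ids: list[str]
    Q: np.ndarray               # (n, K) posterior mean membership
    P: np.ndarray               # (K, L) posterior mean band-allele frequencies
    F: np.ndarray               # (K,) posterior mean fixation index per cluster
    lnl_trace: np.ndarray       # post-burn-in log-likelihood trace
    config: AdmixtureConfig
    alpha: float = 1.0          # posterior mean Dirichlet concentration
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")

    @property
    def lnpd(self) -> float:
        return lnpd(self.lnl_trace)

    @property
    def lnl_mean(self) -> float:
        return float(np.mean(self.lnl_trace))

    @property
    def lnl_var(self) -> float:
        return float(np.var(self.lnl_trace, ddof=1)) if len(self.lnl_trace) > 1 else 0.0

    def cluster_heterozygosity(self) -> np.ndarray:
        return cluster_divergence(self.P)[1]

    def net_distance(self) -> np.ndarray:
        return cluster_divergence(self.P)[0]

    def classify(self, threshold: float = 0.60) -> pd.DataFrame:
        return classify_membership(self.Q, threshold, self.individual_ids)

    def summary(self) -> str:
        net, het = cluster_divergence(self.P)
        lines = [
            f"Admixture model, K = {self.K} "
            f"({self.config.genotype_model}, {self.config.freq_model} frequencies)",
            f"sweeps: {self.config.burnin} burn-in + {len(self.lnl_trace)} recorded",
            f"ln P(D) = {self.lnpd:.1f}   mean lnL = {self.lnl_mean:.1f}   "
            f"var lnL = {self.lnl_var:.1f}",
            "",
            "cluster   Fst      interpretation          exp. het.",
        ]
        for k in range(self.K):
            lines.append(
                f"  {k + 1:<6}  {self.F[k]:<7.4f}  {fst_interpretation(self.F[k]):<22}  "
                f"{het[k]:.4f}"
            )
        counts = self.classify()["label"].value_counts()
        lines.append("")
        lines.append(
            "membership at Q > 0.60: "
            + ", ".join(f"{lab}: {cnt}" for lab, cnt in counts.items())
        )
        return "\n".join(lines)


class AdmixtureModel:
    """STRUCTURE-style admixture model bound to a band matrix.

    Parameters
    ----------
    m : BandMatrix
    K : number of ancestral clusters (>= 1, <= individuals).
    config : AdmixtureConfig, optional.

    ``fit(seed)`` runs one Gibbs chain and returns :class:`AdmixtureResults`;
    ``fit_runs`` runs several independent chains (for Evanno input).
    """

    def __init__(self, m: BandMatrix, K: int, config: AdmixtureConfig | None = None):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > m.n_individuals:
            raise ValueError("K cannot exceed the number of individuals")
        self.m = m
        self.K = K
        self.config = config or AdmixtureConfig()
        self._X = m.data
        self._obs = np.isfinite(self._X)
        self._x1 = (self._X == 1) & self._obs
        self._x0 = (self._X == 0) & self._obs

    # -- likelihood --------------------------------------------------------

    def _loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        d = np.clip(Q @ (1.0 - P), _EPS, 1.0 - _EPS)   # P(copy null)
        if self.config.genotype_model == "dominant-diploid":
            ll = np.where(self._x1, np.log1p(-d * d), 0.0)
            ll += np.where(self._x0, 2.0 * np.log(d), 0.0)
        else:
            ll = np.where(self._x1, np.log1p(-d), 0.0)
            ll += np.where(self._x0, np.log(d), 0.0)
        if not np.isfinite(ll[self._obs]).all():  # pragma: no cover
            raise FloatingPointError("non-finite likelihood; check input scores")
        return float(ll[self._obs].sum())

    # -- one Gibbs chain ---------------------------------------------------

    def fit(self, seed: int | None = None) -> AdmixtureResults:
        cfg = self.config
        rng = np.random.default_rng(seed)
        n, L, K = self.m.n_individuals, self.m.n_loci, self.K
        diploid = cfg.genotype_model == "dominant-diploid"

        # ancestral frequency init: pooled HWE dominant estimate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            band = np.nanmean(self._X, axis=0)
        band = np.nan_to_num(band, nan=0.5)
        p_anc = np.clip(1.0 - np.sqrt(1.0 - np.clip(band, 0.0, 1.0)), 0.02, 0.98)
        F = np.full(K, 0.1)
        P = np.clip(
            p_anc[None, :] + rng.normal(0.0, 0.02, size=(K, L)), _PCLIP, 1.0 - _PCLIP
        )
        Q = np.full((n, K), 1.0 / K)
        alpha = cfg.alpha

        Q_sum = np.zeros_like(Q)
        P_sum = np.zeros_like(P)
        F_sum = np.zeros_like(F)
        alpha_sum = 0.0
        trace = np.empty(cfg.sweeps)
        ks = np.arange(K)[None, :, None]

        for sweep in range(cfg.burnin + cfg.sweeps):
            # (a) latent copies: joint (cluster, allelic state) per copy
            m0 = Q[:, :, None] * (1.0 - P)[None, :, :]
            m1 = Q[:, :, None] * P[None, :, :]
            s0 = m0.sum(axis=1)
            s1 = m1.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                c0 = np.cumsum(m0, axis=1) / np.where(s0 > 0, s0, 1.0)[:, None, :]
                c1 = np.cumsum(m1, axis=1) / np.where(s1 > 0, s1, 1.0)[:, None, :]

            if diploid:
                # allelic-state pattern of the two copies given band present:
                # (1,1) : (1,0) : (0,1) proportional to s1^2 : s1 s0 : s0 s1
                Z = s1 * s1 + 2.0 * s1 * s0
                with np.errstate(divide="ignore", invalid="ignore"):
                    p11 = np.where(Z > 0, s1 * s1 / Z, 1.0)
                    p10 = np.where(Z > 0, s1 * s0 / Z, 0.0)
                u = rng.random((n, L))
                a1 = self._x1 & (u < p11 + p10)
                a2 = self._x1 & ((u < p11) | (u >= p11 + p10))
                copies = ((a1,), (a2,))
            else:
                copies = ((self._x1,),)

            n_ik = np.zeros((n, K))
            y_kl = np.zeros((K, L))
            t_kl = np.zeros((K, L))
            for (a_c,) in copies:
                u_c = rng.random((n, L))[:, None, :]
                z0 = (u_c > c0).sum(axis=1)
                z1 = (u_c > c1).sum(axis=1)
                z = np.where(a_c, z1, z0)
                hit = (z[:, None, :] == ks) & self._obs[:, None, :]
                n_ik += hit.sum(axis=2)
                t_kl += hit.sum(axis=0)
                y_kl += (hit & a_c[:, None, :]).sum(axis=0)

            # (b) cluster frequencies from the conjugate Beta conditional
            if cfg.freq_model == "correlated":
                ratio = (1.0 - F) / F
                a0 = p_anc[None, :] * ratio[:, None]
                b0 = (1.0 - p_anc)[None, :] * ratio[:, None]
            else:
                a0 = np.ones((K, L))
                b0 = np.ones((K, L))
            P = rng.beta(a0 + y_kl, b0 + (t_kl - y_kl))
            P = np.clip(P, _PCLIP, 1.0 - _PCLIP)

            # (c) admixture proportions
            g = rng.gamma(alpha + n_ik)
            Q = g / np.maximum(g.sum(axis=1, keepdims=True), _EPS)
            Q = np.clip(Q, 1e-12, 1.0)
            Q /= Q.sum(axis=1, keepdims=True)

            # (d) hyper-parameters: Dirichlet concentration and the
            # correlated-frequency prior
            if cfg.infer_alpha and K >= 2:
                alpha = self._update_alpha(alpha, Q, rng)
            if cfg.freq_model == "correlated" and K >= 1:
                F = self._update_F(F, P, p_anc, rng)
                if K >= 2:
                    p_anc = self._update_anc(F, P, p_anc, rng)

            ll = self._loglik(Q, P)
            if sweep >= cfg.burnin:
                i = sweep - cfg.burnin
                trace[i] = ll
                Q_sum += Q
                P_sum += P
                F_sum += F
                alpha_sum += alpha

        Q_mean = Q_sum / cfg.sweeps
        Q_mean /= Q_mean.sum(axis=1, keepdims=True)
        return AdmixtureResults(
            K=K,
            individual_ids=list(self.m.individual_ids),
            Q=Q_mean,
            P=P_sum / cfg.sweeps,
            F=F_sum / cfg.sweeps,
            lnl_trace=trace,
            config=cfg,
            alpha=alpha_sum / cfg.sweeps,
            seed=seed,
        )

    def _update_alpha(
        self, alpha: float, Q: np.ndarray, rng: np.random.Generator
    ) -> float:
        """Metropolis step for the Dirichlet concentration (log-scale walk,
        uniform prior on a bounded interval).  Small posterior alpha means the
        data favour near-pure ancestry."""
        from scipy.special import gammaln

        lo, hi = self.config.alpha_bounds
        n, K = Q.shape
        lnq_sum = float(np.log(Q).sum())

        def ll(a: float) -> float:
            return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * lnq_sum

        prop = float(np.exp(np.log(alpha) + rng.normal(0.0, self.config.alpha_step)))
        if not lo <= prop <= hi:
            return alpha
        log_acc = ll(prop) - ll(alpha) + np.log(prop) - np.log(alpha)
        return prop if np.log(rng.random()) < log_acc else alpha

    def _bn_loglik(self, F: np.ndarray, P: np.ndarray, p_anc: np.ndarray) -> np.ndarray:
        """Per-cluster Balding-Nichols log density of P given (p_anc, F)."""
        ratio = (1.0 - F) / F
        a = p_anc[None, :] * ratio[:, None]
        b = (1.0 - p_anc)[None, :] * ratio[:, None]
        return (
            (a - 1.0) * np.log(P) + (b - 1.0) * np.log1p(-P) - betaln(a, b)
        ).sum(axis=1)

    def _update_F(
        self, F: np.ndarray, P: np.ndarray, p_anc: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        lo, hi = self.config.f_bounds
        prop = expit(logit(F) + rng.normal(0.0, self.config.f_step, size=F.shape))
        prop = np.clip(prop, lo, hi)
        ll_old = self._bn_loglik(F, P, p_anc)
        ll_new = self._bn_loglik(prop, P, p_anc)
        # symmetric walk on the logit scale: Jacobian F(1-F) enters the ratio
        log_acc = (
            ll_new - ll_old
            + np.log(prop * (1.0 - prop))
            - np.log(F * (1.0 - F))
        )
        accept = np.log(rng.random(F.shape)) < log_acc
        return np.where(accept, prop, F)

    def _update_anc(
        self, F: np.ndarray, P: np.ndarray, p_anc: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        ratio = (1.0 - F) / F

        def ll(p: np.ndarray) -> np.ndarray:
            a = p[None, :] * ratio[:, None]
            b = (1.0 - p)[None, :] * ratio[:, None]
            return (
                (a - 1.0) * np.log(P) + (b - 1.0) * np.log1p(-P) - betaln(a, b)
            ).sum(axis=0)

        prop = expit(logit(p_anc) + rng.normal(0.0, self.config.anc_step, size=p_anc.shape))
        prop = np.clip(prop, _PCLIP, 1.0 - _PCLIP)
        log_acc = (
            ll(prop) - ll(p_anc)
            + np.log(prop * (1.0 - prop))
            - np.log(p_anc * (1.0 - p_anc))
        )
        accept = np.log(rng.random(p_anc.shape)) < log_acc
        return np.where(accept, prop, p_anc)

    def fit_runs(self, n_runs: int, seed: int | None = None) -> list[AdmixtureResults]:
        """Independent chains with seeds spawned from *seed*."""
        ss = np.random.SeedSequence(seed)
        return [self.fit(int(s.generate_state(1)[0] % (2**31))) for s in ss.spawn(n_runs)]


# -- run-level statistics --------------------------------------------------


def lnpd(lnl_trace: np.ndarray) -> float:
    """Estimated ln P(D) = mean(lnL) - var(lnL)/2 (sample variance, n-1)."""
    t = np.asarray(lnl_trace, dtype=float)
    if t.size < 1:
        raise ValueError("empty trace")
    var = float(np.var(t, ddof=1)) if t.size > 1 else 0.0
    return float(np.mean(t)) - var / 2.0


@dataclass
class EvannoTable:
    table: pd.DataFrame     # index K; columns mean_lnpd, sd_lnpd, Lp, Lpp_abs, deltaK
    best_k: int

    def __str__(self) -> str:
        return self.table.to_string() + f"\nbest K by DeltaK: {self.best_k}"


def evanno(runs: dict[int, list[float]]) -> EvannoTable:
    """Evanno DeltaK over a contiguous K range with >= 2 runs per K.

    L(K) is the mean ln P(D) over runs; L'(K) = L(K) - L(K-1);
    |L''(K)| = |L'(K+1) - L'(K)|; DeltaK = |L''(K)| / sd(L(K)).  DeltaK is
    defined only for interior K; best K is its argmax.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("Evanno needs at least three K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"K = {k}: Evanno needs >= 2 runs")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (
            abs((mean[k + 1] - mean[k]) - (mean[k] - mean[k - 1]))
            if (k - 1 in mean and k + 1 in mean)
            else np.nan
        )
        if np.isfinite(lpp) and sd[k] == 0.0:
            warnings.warn(f"K = {k}: zero sd across runs; DeltaK undefined")
            dk = np.nan
        else:
            dk = lpp / sd[k] if np.isfinite(lpp) else np.nan
        rows.append(
            {"K": k, "mean_lnpd": mean[k], "sd_lnpd": sd[k], "Lp": lp,
             "Lpp_abs": lpp, "deltaK": dk}
        )
    table = pd.DataFrame(rows).set_index("K")
    dk = table["deltaK"]
    if not dk.notna().any():
        raise ValueError("DeltaK undefined everywhere")
    return EvannoTable(table=table, best_k=int(dk.idxmax()))


def cluster_divergence(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(net nucleotide distance K x K, within-cluster expected heterozygosity).

    het_k = mean_l (1 - P_kl^2 - (1-P_kl)^2); pi_AB = mean_l (1 - P_Al P_Bl
    - (1-P_Al)(1-P_Bl)); net d_AB = pi_AB - (het_A + het_B)/2.
    """
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    het = (1.0 - P * P - (1.0 - P) ** 2).mean(axis=1)
    net = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            pi_ab = float(
                (1.0 - P[a] * P[b] - (1.0 - P[a]) * (1.0 - P[b])).mean()
            )
            net[a, b] = net[b, a] = pi_ab - (het[a] + het[b]) / 2.0
    return net, het


def classify_membership(
    Q: np.ndarray,
    threshold: float = 0.60,
    individual_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Pure/admixed call per individual: pure in cluster k iff Q_ik > threshold
    (strict, so a row exactly at the threshold is admixed)."""
    Q = np.asarray(Q, dtype=float)
    best = Q.argmax(axis=1)
    labels = [
        f"pure({k + 1})" if Q[i, k] > threshold else "admixed"
        for i, k in enumerate(best)
    ]
    idx = individual_ids or [f"ind{i + 1}" for i in range(len(labels))]
    return pd.DataFrame(
        {"max_Q": Q.max(axis=1), "cluster": best + 1, "label": labels}, index=idx
    )


def align_runs(Qs: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Resolve label switching across runs: Hungarian assignment of each run's
    columns onto the first run (maximizing summed column agreement), then the
    element-wise mean of the aligned Q matrices."""
    if not Qs:
        raise ValueError("no runs")
    ref = np.asarray(Qs[0], dtype=float)
    aligned = [ref]
    for Q in Qs[1:]:
        Q = np.asarray(Q, dtype=float)
        if Q.shape != ref.shape:
            raise ValueError("runs disagree on K or individuals")
        # match columns minimizing summed squared disagreement with the reference
        cost = ((ref[:, :, None] - Q[:, None, :]) ** 2).sum(axis=0)
        _, cols = linear_sum_assignment(cost)
        aligned.append(Q[:, cols])
    return aligned, np.mean(aligned, axis=0)


def fit_k_range(
    m: BandMatrix,
    k_values: range | list[int],
    runs: int = 2,
    config: AdmixtureConfig | None = None,
    seed: int | None = None,
) -> dict[int, list[AdmixtureResults]]:
    """Independent chains for every K in *k_values* (Evanno input)."""
    ss = np.random.SeedSequence(seed)
    out: dict[int, list[AdmixtureResults]] = {}
    for k, sub in zip(k_values, ss.spawn(len(list(k_values)))):
        model = AdmixtureModel(m, k, config)
        out[k] = [
            model.fit(int(s.generate_state(1)[0] % (2**31))) for s in sub.spawn(runs)
        ]
    return out


def fst_interpretation(fst: float) -> str:
    """Hartl & Clark verbal scale at the 0.05 / 0.15 / 0.25 cut-points."""
    if fst < 0.05:
        return "little differentiation"
    if fst < 0.15:
        return "moderate differentiation"
    if fst < 0.25:
        return "great differentiation"
    return "very great differentiation"
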