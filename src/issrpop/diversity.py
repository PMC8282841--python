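"""Dominant-marker diversity statistics in the POPGENE tradition.

Band-allele frequencies are estimated from dominant phenotypes under
Hardy-Weinberg equilibrium: the null (band-absent) allele frequency is the
square root of the band-absent phenotype frequency, q_hat = sqrt(1 - b).
The Lynch-Milligan small-sample correction is available as an option.

Per locus the statistics are the observed allele count Na, the effective
allele count Ne = 1/(p^2 + q^2), Nei's gene diversity h = 1 - p^2 - q^2,
and Shannon's information index I = -p ln p - q ln q (natural log).  For a
population partition, Hs is the (equally weighted) mean within-population
gene diversity, Ht the gene diversity of the mean frequencies, and
Gst = (Ht - Hs)/Ht, from which gene flow Nm = 0.5 (1 - Gst)/Gst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix

__all__ = [
    "estimate_allele_freq",
    "locus_diversity",
    "per_locus_table",
    "per_primer_diversity",
    "partition_diversity",
    "gene_flow",
    "PartitionDiversity",
]


def estimate_allele_freq(
    band_freq: float | np.ndarray,
    n: int | np.ndarray | None = None,
    lynch_milligan: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(p_hat, q_hat) from the band-present phenotype frequency.

    Plain estimator: q_hat = sqrt(1 - band_freq).  With ``lynch_milligan``
    the Taylor-corrected estimator q_hat = sqrt(1-b) / (1 - var(b)/(8(1-b)^2))
    is used, with var(b) = b(1-b)/n; it requires the per-locus sample size.
    """
    b = np.asarray(band_freq, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("band frequency must lie in [0, 1]")
    absent = 1.0 - b
    q = np.sqrt(absent)
    if lynch_milligan:
        if n is None:
            raise ValueError("Lynch-Milligan correction needs sample sizes")
        nn = np.asarray(n, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_b = b * absent / nn
            denom = 1.0 - var_b / (8.0 * absent * absent)
            q = np.where(absent > 0, q / denom, 0.0)
        q = np.clip(q, 0.0, 1.0)
    return 1.0 - q, q


def locus_diversity(p_hat: float | np.ndarray) -> pd.DataFrame:
    """Na, Ne, h, I per locus from the band-allele frequency."""
    p = np.atleast_1d(np.asarray(p_hat, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    homo = p * p + q * q
    na = np.where((p > 0) & (p < 1), 2.0, 1.0)
    ne = 1.0 / homo
    h = 1.0 - homo
    with np.errstate(divide="ignore", invalid="ignore"):
        I = -np.where(p > 0, p * np.log(p), 0.0) - np.where(q > 0, q * np.log(q), 0.0)
    return pd.DataFrame({"Na": na, "Ne": ne, "h": h, "I": I})


def per_locus_table(m: BandMatrix, lynch_milligan: bool = False) -> pd.DataFrame:
    """Band frequency, estimated allele frequencies and diversity per locus."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        b = np.nanmean(m.data, axis=0)
    n_obs = np.isfinite(m.data).sum(axis=0)
    p, q = estimate_allele_freq(np.nan_to_num(b), n_obs, lynch_milligan)
    div = locus_diversity(p)
    div.insert(0, "locus", m.locus_ids)
    div.insert(1, "primer", [m.primer_of[l] for l in m.locus_ids])
    div.insert(2, "band_freq", b)
    div.insert(3, "p_hat", p)
    div.insert(4, "n", n_obs)
    return div.set_index("locus")


def per_primer_diversity(m: BandMatrix, lynch_milligan: bool = False) -> pd.DataFrame:
    """Mean Na, Ne, h, I per primer plus TSB/PB/PPB bookkeeping — the layout
    of a POPGENE per-primer diversity report."""
    per_locus = per_locus_table(m, lynch_milligan)
    rows = []
    for primer in m.primers:
        sub = per_locus[per_locus["primer"] == primer]
        poly = int(((sub["band_freq"] > 0) & (sub["band_freq"] < 1)).sum())
        rows.append(
            {
                "primer": primer,
                "na": sub["Na"].mean(),
                "ne": sub["Ne"].mean(),
                "h": sub["h"].mean(),
                "I": sub["I"].mean(),
                "TSB": len(sub),
                "PB": poly,
                "PPB": 100.0 * poly / len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("primer")


@dataclass
class PartitionDiversity:
    """Ht/Hs/Gst/Nm for a population partition.

    ``per_locus`` holds the locus-wise components; the headline ``Gst`` is
    the ratio of means (Ht_bar - Hs_bar)/Ht_bar (Nei's definition), with the
    mean of per-locus ratios also reported for transparency.
    """

    per_locus: pd.DataFrame
    Ht: float
    Hs: float
    Gst: float
    Gst_locus_mean: float
    Nm: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "Ht": self.Ht,
                "Hs": self.Hs,
                "Gst": self.Gst,
                "Gst_locus_mean": self.Gst_locus_mean,
                "Nm": self.Nm,
            }
        )


def partition_diversity(
    m: BandMatrix,
    partition: dict[str, str] | None = None,
    lynch_milligan: bool = False,
    weight_by_size: bool = False,
) -> PartitionDiversity:
    """Total/within diversity and differentiation over a grouping of
    individuals (default: the matrix's own population labels).

    Per locus, allele frequencies are estimated within each group; Hs is the
    mean of the within-group 2 p q (equal weights by default, matching the
    POPGENE convention for equal-sized populations), Ht = 2 p_bar q_bar with
    p_bar the mean of group frequencies.  Loci monomorphic overall (Ht = 0)
    are excluded from Gst but retained in the table.
    """
    partition = partition or m.population_of
    groups = sorted(set(partition.values()))
    if len(groups) < 2:
        raise ValueError("Gst needs at least two groups")
    idx_of = {
        g: [i for i, ind in enumerate(m.individual_ids) if partition[ind] == g]
        for g in groups
    }
    L = m.n_loci
    p_g = np.empty((len(groups), L))
    n_g = np.empty((len(groups), L))
    for gi, g in enumerate(groups):
        sub = m.data[idx_of[g]]
        n_obs = np.isfinite(sub).sum(axis=0)
        if np.any(n_obs == 0):
            raise ValueError(f"group {g!r} has loci with no non-missing observation")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            b = np.nanmean(sub, axis=0)
        p_g[gi], _ = estimate_allele_freq(b, n_obs, lynch_milligan)
        n_g[gi] = n_obs

    w = n_g / n_g.sum(axis=0) if weight_by_size else np.full_like(p_g, 1.0 / len(groups))
    hs = (w * 2.0 * p_g * (1.0 - p_g)).sum(axis=0)
    p_bar = (w * p_g).sum(axis=0)
    ht = 2.0 * p_bar * (1.0 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        gst_l = np.where(ht > 0, (ht - hs) / ht, np.nan)

    per_locus = pd.DataFrame(
        {"locus": m.locus_ids, "Ht": ht, "Hs": hs, "Gst": gst_l}
    ).set_index("locus")
    Ht_bar = float(ht.mean())
    Hs_bar = float(hs.mean())
    Gst = (Ht_bar - Hs_bar) / Ht_bar if Ht_bar > 0 else float("nan")
    Gst_locus_mean = float(np.nanmean(gst_l)) if np.isfinite(gst_l).any() else float("nan")
    return PartitionDiversity(
        per_locus=per_locus,
        Ht=Ht_bar,
        Hs=Hs_bar,
        Gst=Gst,
        Gst_locus_mean=Gst_locus_mean,
        Nm=gene_flow(Gst) if np.isfinite(Gst) and Gst > 0 else float("inf"),
    )


def gene_flow(gst: float) -> float:
    """Effective migrants per generation, Nm = 0.5 (1 - Gst)/Gst."""
    if gst < 0:
        raise ValueError("Gst must be nonnegative")
    if gst == 0:
        warnings.warn("Gst = 0: gene flow is unbounded")
        return float("inf")
    if gst > 1:
        raise ValueError("Gst must be <= 1")
    return 0.5 * (1.0 - gst) / gst
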