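"""Per-primer marker-efficiency indices for dominant band data.

For each primer the panel report carries: total scored bands (TSB), the
polymorphic count (PB) and percentage (PPB), expected heterozygosity H,
polymorphic information content PIC, effective multiplex ratio EMR, mean
heterozygosity of the polymorphic fraction Havp, marker index MI = PIC*EMR,
Tessier's discriminating power D, and Prevost-Wilkinson resolving power RP.

H and PIC are computed from a single pooled band frequency per primer
(1-entries over non-missing entries across the primer's polymorphic loci).
With a pooled bi-allelic frequency p, H = 2p(1-p) and the Botstein PIC
reduces to H - H^2/2 — an identity the per-locus averaging convention would
not satisfy, and the convention used by the online marker-efficiency
calculators this report format mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix

__all__ = [
    "PrimerMetrics",
    "count_bands",
    "pooled_band_frequency",
    "expected_heterozygosity",
    "pic",
    "pic_multiallelic",
    "emr",
    "resolving_power",
    "discriminating_power",
    "havp",
    "marker_index",
    "primer_metrics",
    "panel_metrics",
    "aggregate_metrics",
]


@dataclass
class PrimerMetrics:
    """One row of the marker-efficiency report."""

    primer: str
    TSB: int
    PB: int
    PPB: float
    p_bar: float
    H: float
    PIC: float
    EMR: float
    Havp: float
    MI: float
    D: float
    RP: float


def _primer_block(m: BandMatrix, primer: str) -> np.ndarray:
    return m.data[:, m.loci_of_primer(primer)]


def _polymorphic_mask(block: np.ndarray, min_freq: float = 0.0) -> np.ndarray:
    """A locus is polymorphic iff both states occur among non-missing entries.

    ``min_freq`` optionally imposes a minor-state frequency threshold (e.g.
    0.05 for the 95% criterion); the default 0 counts any second state.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        freq = np.nanmean(block, axis=0)
    freq = np.nan_to_num(freq, nan=0.0)
    return (freq > min_freq) & (freq < 1.0 - min_freq)


def count_bands(m: BandMatrix, primer: str, min_freq: float = 0.0) -> tuple[int, int, float]:
    """(TSB, PB, PPB%) for one primer."""
    block = _primer_block(m, primer)
    TSB = block.shape[1]
    PB = int(_polymorphic_mask(block, min_freq).sum())
    return TSB, PB, 100.0 * PB / TSB


def pooled_band_frequency(m: BandMatrix, primer: str) -> float:
    """Fraction of 1-entries over all non-missing cells of the primer's
    polymorphic loci (the single frequency behind H and PIC)."""
    block = _primer_block(m, primer)
    poly = _polymorphic_mask(block)
    if not poly.any():
        raise ValueError(f"primer {primer!r} has no polymorphic locus")
    sub = block[:, poly]
    n_obs = np.isfinite(sub).sum()
    if n_obs == 0:
        raise ValueError(f"primer {primer!r} has no non-missing entries")
    return float(np.nansum(sub) / n_obs)


def expected_heterozygosity(p_bar: float) -> float:
    """Bi-allelic expected heterozygosity H = 1 - p^2 - q^2 = 2p(1-p)."""
    if not 0.0 <= p_bar <= 1.0:
        raise ValueError("p_bar must lie in [0, 1]")
    return 2.0 * p_bar * (1.0 - p_bar)


def pic(p_bar: float) -> float:
    """Botstein PIC in its bi-allelic closed form, 1 - p^2 - q^2 - 2 p^2 q^2
    (equivalently H - H^2/2)."""
    h = expected_heterozygosity(p_bar)
    return h - h * h / 2.0


def pic_multiallelic(freqs: np.ndarray) -> float:
    """General Botstein PIC, 1 - sum p_i^2 - sum_{i != j} p_i^2 p_j^2, for
    completeness on co-dominant multi-allele frequency vectors."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    p2 = p * p
    return float(1.0 - p2.sum() - (p2.sum() ** 2 - (p2 * p2).sum()))


def emr(m: BandMatrix, primer: str) -> float:
    """Effective multiplex ratio n * beta: n = mean bands amplified per
    individual at this primer's loci (missing cells excluded per individual),
    beta = PB/TSB."""
    block = _primer_block(m, primer)
    TSB, PB, _ = count_bands(m, primer)
    obs = np.isfinite(block)
    per_ind = np.where(
        obs.any(axis=1),
        np.nansum(block, axis=1) / np.maximum(obs.sum(axis=1), 1) * block.shape[1],
        np.nan,
    )
    # per-individual band count rescaled to the full locus set, so individuals
    # with a few missing cells are not undercounted
    n_mean = float(np.nanmean(per_ind))
    return n_mean * PB / TSB


def resolving_power(m: BandMatrix, primer: str) -> float:
    """RP = sum over bands of Ib = 1 - 2|0.5 - p|, p = fraction of
    individuals showing the band."""
    block = _primer_block(m, primer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(block, axis=0)
    p = np.nan_to_num(p, nan=0.0)
    return float(np.sum(1.0 - 2.0 * np.abs(0.5 - p)))


def discriminating_power(m: BandMatrix, primer: str) -> float:
    """Tessier's D = 1 - C, where C sums c_i = p_i (N p_i - 1)/(N - 1) over
    the distinct multi-locus banding patterns at this primer's loci."""
    block = _primer_block(m, primer)
    N = block.shape[0]
    if N < 2:
        raise ValueError("discriminating power needs >= 2 individuals")
    patterns: dict[tuple, int] = {}
    for row in block:
        key = tuple("N" if np.isnan(v) else int(v) for v in row)
        patterns[key] = patterns.get(key, 0) + 1
    C = 0.0
    for cnt in patterns.values():
        p_i = cnt / N
        C += p_i * (N * p_i - 1.0) / (N - 1.0)
    return 1.0 - C


def havp(m: BandMatrix, primer: str) -> float:
    """Mean heterozygosity over the polymorphic fraction: the average of the
    per-locus 2 p_l (1 - p_l) across polymorphic loci."""
    block = _primer_block(m, primer)
    poly = _polymorphic_mask(block)
    if not poly.any():
        warnings.warn(f"primer {primer!r} has no polymorphic locus; Havp = 0")
        return 0.0
    p = np.nanmean(block[:, poly], axis=0)
    return float(np.mean(2.0 * p * (1.0 - p)))


def marker_index(pic_value: float, emr_value: float) -> float:
    """MI = PIC * EMR."""
    if not (np.isfinite(pic_value) and np.isfinite(emr_value)):
        raise ValueError("PIC and EMR must be finite")
    if pic_value < 0 or emr_value < 0:
        raise ValueError("PIC and EMR must be nonnegative")
    return pic_value * emr_value


def primer_metrics(m: BandMatrix, primer: str) -> PrimerMetrics:
    TSB, PB, PPB = count_bands(m, primer)
    if PB > 0:
        p_bar = pooled_band_frequency(m, primer)
        H = expected_heterozygosity(p_bar)
        PIC = pic(p_bar)
        Havp = havp(m, primer)
    else:
        p_bar, H, PIC, Havp = 0.0, 0.0, 0.0, 0.0
    EMR = emr(m, primer)
    return PrimerMetrics(
        primer=primer,
        TSB=TSB,
        PB=PB,
        PPB=PPB,
        p_bar=p_bar,
        H=H,
        PIC=PIC,
        EMR=EMR,
        Havp=Havp,
        MI=marker_index(PIC, EMR),
        D=discriminating_power(m, primer),
        RP=resolving_power(m, primer),
    )


def panel_metrics(m: BandMatrix) -> pd.DataFrame:
    """Marker-efficiency report: one row per primer, in panel order."""
    rows = [primer_metrics(m, p) for p in m.primers]
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(PrimerMetrics)} for r in rows]
    ).set_index("primer")


def aggregate_metrics(table: pd.DataFrame, with_std: bool = False) -> pd.DataFrame:
    """Column-wise arithmetic means (and optionally standard deviations) over
    the per-primer rows — the panel's summary row."""
    if len(table) < 1:
        raise ValueError("need at least one primer")
    num = table.select_dtypes("number")
    out = pd.DataFrame([num.mean()], index=["mean"])
    if with_std:
        out = pd.concat([out, pd.DataFrame([num.std(ddof=1)], index=["std"])])
    return out
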