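"""Quantitative clonality statistics.

Each retained somatic mutation is treated as one molecular species whose
abundance is ``VAF * DP * CN`` (allelic frequency times read depth times
local copy number, diploid when no copy-number call covers the locus).
Clonal heterogeneity is summarized two ways:

* the Shannon diversity index ``SDI = -sum_i p(i) ln p(i)`` over the
  normalized abundances, in nats — it grows both with the number of
  distinct mutations and with the evenness of their abundances; and
* a Gaussian kernel density estimate of the VAF distribution,
  ``f(x) = sum_i w_i K((x_i - x)/h) / (h sum_i w_i)``, with per-mutation
  copy-number weights ``w_i`` and a data-derived two-stage direct plug-in
  bandwidth ``h``.  Peaks of the density suggest clonal clusters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClonalityMetrics",
    "KdeCurve",
    "compute_vaf",
    "abundance",
    "shannon_diversity",
    "simpson_diversity",
    "berger_parker_dominance",
    "plugin_bandwidth",
    "silverman_bandwidth",
    "weighted_kde",
    "default_grid",
    "kde_modes",
    "calculate_metrics",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Smallest bandwidth returned by any selector, in VAF percent points.
#: Engaged only by degenerate inputs (near-zero spread).
MIN_BANDWIDTH = 0.5


def compute_vaf(trv: int, trr: int) -> float:
    """Variant allele frequency in percent: ``100 * TRV / (TRV + TRR)``.

    ``trv`` and ``trr`` are the read counts supporting the variant and the
    reference allele respectively.
    """
    if trv < 0 or trr < 0:
        raise ValueError("read counts must be non-negative")
    total = trv + trr
    if total == 0:
        raise ValueError("VAF undefined: no supporting reads (TRV + TRR = 0)")
    return 100.0 * trv / total


def abundance(vaf: float, dp: int, cn: int | None) -> float:
    """Per-mutation abundance ``VAF * DP * CN``.

    A missing copy-number call (``cn`` null) is interpreted as the neutral
    diploid state, CN = 2.
    """
    if dp <= 0:
        raise ValueError("depth must be positive")
    cn_eff = 2 if cn is None or (isinstance(cn, float) and math.isnan(cn)) else cn
    return float(vaf) * float(dp) * float(cn_eff)


def shannon_diversity(abundances) -> float:
    """Shannon diversity index ``-sum p(i) ln p(i)`` in nats.

    ``p(i)`` is each species' share of the total abundance; zero-abundance
    entries contribute nothing.  Raises on empty, all-zero or negative
    input.
    """
    a = np.asarray(list(abundances), dtype=float)
    if a.size == 0:
        raise ValueError("no abundances given")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all abundances are zero")
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def simpson_diversity(abundances) -> float:
    """Simpson's index ``1 - sum p(i)^2`` (probability two draws differ)."""
    a = np.asarray(list(abundances), dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all abundances are zero")
    p = a / a.sum()
    return float(1.0 - (p**2).sum())


def berger_parker_dominance(abundances) -> float:
    """Berger-Parker dominance: the largest single abundance share."""
    a = np.asarray(list(abundances), dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all abundances are zero")
    return float(a.max() / a.sum())


# ---------------------------------------------------------------------------
# Bandwidth selection
# ---------------------------------------------------------------------------


def _phi4(u: np.ndarray) -> np.ndarray:
    # 4th derivative of the standard normal density
    return (u**4 - 6.0 * u**2 + 3.0) * np.exp(-0.5 * u**2) / _SQRT_2PI


def _phi6(u: np.ndarray) -> np.ndarray:
    # 6th derivative of the standard normal density
    return (u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0) * np.exp(-0.5 * u**2) / _SQRT_2PI


def silverman_bandwidth(values, weights=None) -> float:
    """Silverman's rule of thumb on a (optionally weighted) sample.

    ``0.9 * min(sd, IQR/1.34) * n_eff**(-1/5)``, floored at
    :data:`MIN_BANDWIDTH`.  Used as the fallback when the plug-in selector
    is infeasible (fewer than 5 distinct values, or zero spread).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("no values given")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(list(weights), dtype=float)
    w = w / w.sum()
    mu = float((w * x).sum())
    var = float((w * (x - mu) ** 2).sum())
    n_eff = 1.0 / float((w**2).sum())
    sd = math.sqrt(var * n_eff / max(n_eff - 1.0, 1.0)) if n_eff > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * scale * n_eff ** (-0.2) if scale > 0 else 0.0
    return max(h, MIN_BANDWIDTH)


def plugin_bandwidth(values, weights=None) -> float:
    """Two-stage direct plug-in bandwidth for the Gaussian kernel.

    The Sheather-Jones / Wand-Jones "direct plug-in" selector, level 2,
    computed exactly (no binning):

    1. scale estimate ``sigma = min(sd, IQR/1.349)``;
    2. normal-reference 8th-moment functional
       ``psi8 = 105 / (32 sqrt(pi) sigma^9)``;
    3. ``g1 = (-2 K6(0) / (psi8 n))**(1/9)`` and the kernel estimate
       ``psi6 = n^-2 g1^-7 sum_ij K6((Xi-Xj)/g1)``;
    4. ``g2 = (-2 K4(0) / (psi6 n))**(1/7)`` and
       ``psi4 = n^-2 g2^-5 sum_ij K4((Xi-Xj)/g2)``;
    5. ``h = (1 / (2 sqrt(pi) psi4 n))**(1/5)``.

    The selector runs on the raw values; copy-number weights enter the
    density itself, not the bandwidth (``weights`` is accepted only to
    parameterize the fallback).  With fewer than 5 distinct values or zero
    spread the Silverman fallback is returned instead of raising.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("no values given")
    n = x.size
    if np.unique(x).size < 5:
        return silverman_bandwidth(x, weights)
    sd = float(x.std(ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    candidates = [s for s in (sd, iqr / 1.349) if s > 0]
    if not candidates:
        return silverman_bandwidth(x, weights)
    sigma = min(candidates)

    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sigma**9)
    g1 = (2.0 * (15.0 / _SQRT_2PI) / (psi8 * n)) ** (1.0 / 9.0)
    diffs = np.subtract.outer(x, x)
    psi6 = float(_phi6(diffs / g1).sum()) / (n**2 * g1**7)
    if psi6 >= 0:  # numerically degenerate; psi6 must be negative
        return silverman_bandwidth(x, weights)
    g2 = (-2.0 * (3.0 / _SQRT_2PI) / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = float(_phi4(diffs / g2).sum()) / (n**2 * g2**5)
    if psi4 <= 0:
        return silverman_bandwidth(x, weights)
    return (1.0 / (2.0 * math.sqrt(math.pi) * psi4 * n)) ** 0.2


# ---------------------------------------------------------------------------
# Weighted KDE
# ---------------------------------------------------------------------------


@dataclass
class KdeCurve:
    """A kernel density estimate of the VAF distribution.

    ``density[j]`` estimates the density at ``grid[j]`` (VAF percent);
    ``bandwidth`` is the Gaussian kernel bandwidth in the same units;
    ``weights_used`` records whether non-uniform copy-number weights
    entered the estimate.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    weights_used: bool = False

    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def default_grid(lo: float = 0.0, hi: float = 100.0, size: int = 512) -> np.ndarray:
    """Evaluation grid for VAF densities: 512 equispaced points on [0, 100]."""
    return np.linspace(lo, hi, size)


def weighted_kde(values, weights=None, h: float | None = None, grid=None) -> KdeCurve:
    """Copy-number-weighted Gaussian KDE of VAF values.

    ``f(x) = sum_i w_i K((x_i - x)/h) / (h sum_i w_i)`` with ``K`` the
    standard normal density.  With equal weights this reduces exactly to
    the unweighted estimator ``(nh)^-1 sum_i K((x_i-x)/h)``.  When ``h``
    is omitted the plug-in selector is used (on the unweighted values).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("no values given")
    if weights is None:
        w = np.ones_like(x)
        weights_used = False
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != x.shape:
            raise ValueError(f"{w.size} weights for {x.size} values")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        weights_used = bool(np.ptp(w) > 0)
    if h is None:
        h = plugin_bandwidth(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    u = (x[:, None] - g[None, :]) / h  # (n, grid)
    kern = np.exp(-0.5 * u**2) / _SQRT_2PI
    dens = (w[:, None] * kern).sum(axis=0) / (h * w.sum())
    return KdeCurve(grid=g, density=dens, bandwidth=float(h), n=int(x.size), weights_used=weights_used)


def kde_modes(curve: KdeCurve, min_density: float = 1e-8) -> np.ndarray:
    """Grid locations of the strict local maxima of a density curve."""
    d = curve.density
    idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] > min_density)) + 1
    return curve.grid[idx]


# ---------------------------------------------------------------------------
# Per-sample metrics
# ---------------------------------------------------------------------------


@dataclass
class ClonalityMetrics:
    """Headline per-sample metrics: mutation count, key-gene count, SDI."""

    n_mutations: int
    n_key_genes: int
    sdi: float
    experiment_id: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "experiment": self.experiment_id,
                "N": self.n_mutations,
                "KG": self.n_key_genes,
                "SDI": self.sdi,
            }
        )


def calculate_metrics(w_hat: pd.DataFrame, key_genes: pd.DataFrame | None = None) -> ClonalityMetrics:
    """Compute :class:`ClonalityMetrics` from a distinct-mutation relation.

    ``w_hat`` must carry ``dna_allelic_freq``, ``dna_depth`` and
    ``copy_number`` (nullable) columns, one row per mutation.  The
    key-gene count is the number of distinct ``gene_symbol`` values also
    present in ``key_genes``.
    """
    if len(w_hat) == 0:
        raise ValueError("empty mutation relation: metrics undefined")
    ab = [
        abundance(row.dna_allelic_freq, row.dna_depth,
                  None if pd.isna(row.copy_number) else int(row.copy_number))
        for row in w_hat.itertuples(index=False)
    ]
    n_kg = 0
    if key_genes is not None and len(key_genes) and "gene_symbol" in key_genes.columns:
        kg_symbols = set(key_genes["gene_symbol"].dropna())
        n_kg = len(set(w_hat["gene_symbol"].dropna()) & kg_symbols)
    exp_id = None
    if "experiment_id" in w_hat.columns and len(w_hat["experiment_id"].dropna()):
        exp_id = str(w_hat["experiment_id"].dropna().iloc[0])
    return ClonalityMetrics(
        n_mutations=int(len(w_hat)),
        n_key_genes=n_kg,
        sdi=shannon_diversity(ab),
        experiment_id=exp_id,
    )
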