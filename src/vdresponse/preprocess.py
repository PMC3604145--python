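"""RMA-style normalization and PCA quality control.

The classical robust multi-array average (RMA) pipeline has three
stages: normexp background correction of linear-scale probe intensities,
quantile normalization across arrays (applied here on the log2 scale),
and Tukey median-polish summarization of probes into gene-level values.
Gene-level matrices that were already summarized elsewhere can skip the
first and last stages and go straight through :func:`quantile_normalize`
(see :func:`normalize_gene_level`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .matrix import ExpressionMatrix


# ---------------------------------------------------------------------------
# normexp background correction
# ---------------------------------------------------------------------------

def _normexp_loglik(params: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood of the normal+exponential convolution.

    The observed intensity is modelled as B + S with background
    B ~ N(mu, sigma^2) and signal S ~ Exp(mean alpha).
    """
    mu, log_sigma, log_alpha = params
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = (
        -log_alpha
        + (mu - x) / alpha
        + sigma**2 / (2 * alpha**2)
        + special.log_ndtr(z)
    )
    return -float(np.sum(ll))


def _normexp_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Estimate (mu, sigma, alpha) by maximum likelihood.

    Initialized from the method of moments; falls back to a quantile
    split when the third central moment is non-positive.
    """
    m1 = float(np.mean(x))
    m2 = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    if m3 > 0:
        alpha0 = (m3 / 2.0) ** (1.0 / 3.0)
    else:
        alpha0 = max(float(np.mean(x) - np.quantile(x, 0.25)), 1e-2)
    sigma2_0 = max(m2 - alpha0**2, (0.1 * alpha0) ** 2, 1e-6)
    mu0 = m1 - alpha0
    start = np.array([mu0, 0.5 * np.log(sigma2_0), np.log(alpha0)])
    res = optimize.minimize(
        _normexp_loglik, start, args=(x,), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000},
    )
    mu, log_sigma, log_alpha = res.x
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))


def _normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior mean of the signal given the observed intensity.

    E[S | X=x] = m + sigma * phi(m/sigma) / Phi(m/sigma) with
    m = x - mu - sigma^2/alpha; strictly positive and monotone in x.
    """
    m = x - mu - sigma**2 / alpha
    z = m / sigma
    # phi(z)/Phi(z) computed in log space for stability in the left tail
    log_ratio = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - special.log_ndtr(z)
    return m + sigma * np.exp(log_ratio)


def normexp_background_correct(raw: pd.DataFrame) -> pd.DataFrame:
    """Background-correct linear-scale intensities column by column.

    Fits the normal+exponential convolution per array by maximum
    likelihood and replaces each intensity with the posterior mean of
    its signal component.  All outputs are strictly positive.
    """
    arr = raw.to_numpy(dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("raw intensities must be positive and finite")
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        mu, sigma, alpha = _normexp_fit(arr[:, j])
        out[:, j] = _normexp_signal(arr[:, j], mu, sigma, alpha)
    out = np.maximum(out, np.finfo(float).tiny)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the mean empirical distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; tied input values receive the mean of their
    tied quantiles, which makes the transform idempotent.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return values.copy()
    arr = values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = mean_sorted
        # average over ties so equal inputs map to equal outputs
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if uniq.size < col.size:
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# median polish summarization
# ---------------------------------------------------------------------------

def _median_polish(block: np.ndarray, max_iter: int, tol: float):
    """Tukey median polish; returns (overall, row_eff, col_eff, residuals)."""
    resid = block.astype(float).copy()
    overall = 0.0
    row_eff = np.zeros(block.shape[0])
    col_eff = np.zeros(block.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_row = np.median(row_eff)
        overall += cmed_of_row
        row_eff -= cmed_of_row
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_col = np.median(col_eff)
        overall += rmed_of_col
        col_eff -= rmed_of_col
        if max(np.abs(rmed).max(), np.abs(cmed).max()) <= tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(
    probe_values: pd.DataFrame,
    probe_to_gene: dict[str, str],
    meta: pd.DataFrame,
    max_iter: int = 20,
    tol: float = 1e-9,
) -> ExpressionMatrix:
    """Summarize probe-level log2 values into gene-level values.

    Probes mapping to the same gene form a (probes x samples) block; a
    median polish decomposes it into overall + probe + sample effects
    and the gene-level value for each sample is overall + sample effect.
    """
    unmapped = [p for p in probe_values.index if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"probes without a gene mapping: {unmapped[:5]}")
    genes: dict[str, list[str]] = {}
    for probe in probe_values.index:
        genes.setdefault(probe_to_gene[probe], []).append(probe)
    rows = {}
    for gene in sorted(genes):
        block = probe_values.loc[genes[gene]].to_numpy(dtype=float)
        overall, _, col_eff, _ = _median_polish(block, max_iter, tol)
        rows[gene] = overall + col_eff
    values = pd.DataFrame.from_dict(rows, orient="index", columns=probe_values.columns)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# PCA quality control
# ---------------------------------------------------------------------------

@dataclass
class PcaSummary:
    """Per-sample component scores and percent variance per component."""

    scores: pd.DataFrame
    percent_variance: np.ndarray


def pca_qc(matrix: ExpressionMatrix) -> PcaSummary:
    """Principal components of the samples on gene-centered log2 values.

    Values are centered per gene across samples (no scaling) and the
    samples are projected onto the orthonormal right singular axes.
    Percent variance is reported over all components and sums to 100
    unless the matrix is constant, in which case all components carry
    zero variance and a warning is issued.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    arr = matrix.values.to_numpy(dtype=float)
    centered = (arr - arr.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    total = float(np.sum(s**2))
    if total == 0:
        warnings.warn("constant expression matrix: all PCA variance is zero")
        percent = np.zeros(len(s))
    else:
        percent = 100.0 * s**2 / total
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaSummary(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        percent_variance=percent,
    )


# ---------------------------------------------------------------------------
# convenience pipelines
# ---------------------------------------------------------------------------

def normalize_gene_level(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an already summarized gene-level log2 matrix."""
    return ExpressionMatrix(quantile_normalize(matrix.values), matrix.meta.copy())


def rma(
    raw_probe_values: pd.DataFrame,
    probe_to_gene: dict[str, str],
    meta: pd.DataFrame,
) -> ExpressionMatrix:
    """Full RMA: background correct, log2, quantile normalize, polish."""
    corrected = normexp_background_correct(raw_probe_values)
    logged = np.log2(corrected)
    normalized = quantile_normalize(logged)
    return median_polish_summarize(normalized, probe_to_gene, meta)
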