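"""Normalization: median-of-ratios size factors + VST for counts, quantile
normalization for intensities, and empirical-Bayes batch adjustment.

The count branch follows the median-of-ratios / variance-stabilizing
transformation recipe standard for RNA-seq: per-sample size factors are the
median across zero-free reference genes of the ratio to the gene's geometric
mean, and counts are mapped through the exact variance-stabilizing integral
for a negative-binomial mean-variance trend Var(X) = mu + b*mu^2,

    vst(x) = 2 * asinh(sqrt(b * x)) / ln 2,

which is strictly increasing, vst(0) = 0, and asymptotically spaced like
log2 (vst(2x) - vst(x) -> 1 as x -> infinity).  The microarray branch uses
quantile normalization; residual batch structure is removed by a one-step
parametric empirical-Bayes location/scale adjustment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from metaregnet.dataio import ExpressionMatrix


class NormalizeError(ValueError):
    pass


@dataclass
class NormalizationModel:
    """Fitted size factors and (optionally) a dispersion trend alpha(mu) = a/mu + b."""

    size_factors: pd.Series
    dispersion_trend: tuple[float, float] | None = None
    method: str = "median-of-ratios"

    def __post_init__(self) -> None:
        sf = self.size_factors.to_numpy(dtype=float)
        if (sf <= 0).any():
            raise NormalizeError("size factors must be positive")
        if self.dispersion_trend is not None and self.dispersion_trend[1] < 0:
            raise NormalizeError("dispersion trend intercept b must be >= 0")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "size_factors": self.size_factors.to_dict(),
                    "dispersion_trend": self.dispersion_trend,
                },
                indent=2,
                sort_keys=True,
            )
        )


def size_factors_mor(counts: ExpressionMatrix, pseudo_reference: bool = False) -> NormalizationModel:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are rows with no zero count.  If none exists, pass
    ``pseudo_reference=True`` to fall back to genes with positive counts in at
    least half of the samples (geometric mean over the positive entries).
    """
    if counts.platform != "counts":
        raise NormalizeError("size_factors_mor requires the counts platform")
    x = counts.values.to_numpy(dtype=float)
    zero_free = (x > 0).all(axis=1)
    if zero_free.any():
        ref = x[zero_free]
        log_gmean = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_gmean[:, None]
    elif pseudo_reference:
        mostly = (x > 0).mean(axis=1) >= 0.5
        if not mostly.any():
            raise NormalizeError("no usable reference genes even with pseudo-reference")
        ref = x[mostly]
        logs = np.full(ref.shape, np.nan)
        np.log(ref, out=logs, where=ref > 0)
        log_gmean = np.nanmean(logs, axis=1)
        ratios = logs - log_gmean[:, None]
    else:
        raise NormalizeError(
            "no gene has all-positive counts; rerun with pseudo_reference=True"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # rescale: geometric mean of s_j = 1
    sf = pd.Series(np.exp(log_sf), index=counts.samples, name="size_factor")
    return NormalizationModel(sf)


def normalized_counts(counts: ExpressionMatrix, model: NormalizationModel) -> pd.DataFrame:
    return counts.values / model.size_factors


def fit_dispersion_trend(
    counts: ExpressionMatrix, model: NormalizationModel
) -> tuple[float, float]:
    """Fit alpha(mu) = a/mu + b by OLS on gene-wise method-of-moments dispersions.

    On size-factor-normalized counts: alpha_hat_i = max(0, (var_i - mu_i)/mu_i^2);
    (a, b) minimize the squared residuals of alpha_hat against 1/mu, with the
    intercept b clamped to >= 1e-8.  The fitted trend is stored on the model.
    """
    k = normalized_counts(counts, model).to_numpy(dtype=float)
    if k.shape[0] < 50:
        raise NormalizeError("dispersion trend fit requires at least 50 genes")
    mu = k.mean(axis=1)
    var = k.var(axis=1, ddof=1)
    keep = mu > 0
    mu, var = mu[keep], var[keep]
    alpha_hat = np.maximum(0.0, (var - mu) / mu**2)
    if not (alpha_hat > 0).any():
        warnings.warn("all moment dispersions are zero; returning (0, 1e-8)")
        trend = (0.0, 1e-8)
    else:
        X = np.column_stack([1.0 / mu, np.ones_like(mu)])
        coef, *_ = np.linalg.lstsq(X, alpha_hat, rcond=None)
        a = float(coef[0])
        b = float(max(coef[1], 1e-8))
        trend = (a, b)
    model.dispersion_trend = trend
    return trend


def vst_transform(counts: ExpressionMatrix, model: NormalizationModel) -> ExpressionMatrix:
    """Variance-stabilizing transform of size-factor-normalized counts.

    Uses vst(x) = 2*asinh(sqrt(b*x))/ln 2 with b from the fitted dispersion
    trend.  Output platform is ``intensity`` (continuous scale).
    """
    if model.dispersion_trend is None:
        raise NormalizeError("fit_dispersion_trend must run before vst_transform")
    k = normalized_counts(counts, model).to_numpy(dtype=float)
    if (k < 0).any():
        raise NormalizeError("negative input to vst_transform")
    b = max(model.dispersion_trend[1], 1e-8)
    v = 2.0 * np.arcsinh(np.sqrt(b * k)) / np.log(2.0)
    out = pd.DataFrame(v, index=counts.genes, columns=counts.samples)
    return ExpressionMatrix(out, "intensity", counts.annotations)


def quantile_normalize(intensities: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of row-wise sorted means.

    Ties within a sample share the mean of the values they would have
    received.  Idempotent; a single-sample input is returned unchanged with a
    warning.
    """
    if intensities.platform != "intensity":
        raise NormalizeError("quantile_normalize requires the intensity platform")
    x = intensities.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples == 1:
        warnings.warn("single sample: quantile normalization is the identity")
        return intensities
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(n_genes)
        col[order] = ref
        # ties share the mean of their would-be values
        vals = x[:, j]
        uniq, inv, cnt = np.unique(vals, return_inverse=True, return_counts=True)
        if (cnt > 1).any():
            sums = np.bincount(inv, weights=col)
            col = (sums / cnt)[inv]
        out[:, j] = col
    df = pd.DataFrame(out, index=intensities.genes, columns=intensities.samples)
    return ExpressionMatrix(df, "intensity", intensities.annotations)


def eb_batch_adjust(matrix: ExpressionMatrix, batches: pd.Series | None = None) -> ExpressionMatrix:
    """One-step parametric empirical-Bayes location/scale batch adjustment.

    Per gene the data are standardized (grand mean, pooled sd); per batch the
    location gamma_hat and scale delta_hat^2 are estimated, shrunk toward
    cross-gene moment priors (normal for locations, inverse-gamma for scales),
    removed, and the gene scale restored.  A single batch is an identity map.
    """
    if batches is None:
        if matrix.annotations is None or "batch" not in matrix.annotations.columns:
            raise NormalizeError("batch labels required")
        batches = matrix.annotations["batch"]
    batches = pd.Series(batches).loc[matrix.samples]
    labels = pd.unique(batches)
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise NormalizeError(f"batches with a single sample: {list(small.index)}")

    x = matrix.values.to_numpy(dtype=float)
    grand = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - grand) / sd

    z_adj = np.empty_like(z)
    col_batch = batches.to_numpy()
    for b in labels:
        cols = np.flatnonzero(col_batch == b)
        zb = z[:, cols]
        n_b = len(cols)
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1)
        # normal prior on locations
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if len(gamma_hat) > 1 else 0.0
        if tau2 > 0:
            gamma_star = (n_b * tau2 * gamma_hat + delta2_hat * gamma_bar) / (
                n_b * tau2 + delta2_hat
            )
        else:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        # inverse-gamma prior on scales (method of moments)
        m = delta2_hat.mean()
        v = delta2_hat.var(ddof=1) if len(delta2_hat) > 1 else 0.0
        if v > 0:
            lam = (2.0 * v + m**2) / v
            theta = (m * v + m**3) / v
            delta2_star = (theta + 0.5 * ((zb - gamma_star[:, None]) ** 2).sum(axis=1)) / (
                n_b / 2.0 + lam - 1.0
            )
        else:
            delta2_star = delta2_hat.copy()
        delta2_star = np.maximum(delta2_star, 1e-12)
        z_adj[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta2_star)[:, None]

    if len(labels) == 1:
        # single batch: gamma_hat == 0 and delta2_hat == 1 by construction,
        # so return the input untouched instead of accumulating rounding error
        return matrix

    out = pd.DataFrame(
        z_adj * sd + grand, index=matrix.genes, columns=matrix.samples
    )
    return ExpressionMatrix(out, matrix.platform, matrix.annotations)
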