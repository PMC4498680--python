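"""Normalization and count transformations feeding the dissimilarity measures.

Covers median-of-ratios size factors, log(count+1), a closed-form
variance-stabilizing transform (VST) for the negative-binomial mean–variance
relationship v(mu) = mu + (a0 + a1/mu) * mu^2, a regularized-log transform with
dispersion-dependent shrinkage toward the gene mean, and the power transform
selected by a Pearson goodness-of-fit criterion that deflates overdispersed
counts toward Poisson behaviour.

The VST and rlog here are deliberately simplified re-derivations of the
familiar blind transforms: a parametric dispersion trend fitted by moments and
nonnegative least squares, then a closed form (VST) or ridge-style shrinkage
(rlog).  They are used as monotone-ish preprocessing for Euclidean distances;
correctness for this package is defined at the dendrogram level, not as value
equality with any external implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .io_counts import CountMatrix

__all__ = [
    "SizeFactors",
    "DispersionTrend",
    "median_ratio_size_factors",
    "normalized_counts",
    "log1_transform",
    "fit_dispersion_trend",
    "vst",
    "rlog",
    "power_transform_beta",
]


@dataclass
class SizeFactors:
    """Per-sample positive scale factors; sample j's counts are divided by s_j."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("one size factor per sample required")
        if not np.all(self.values > 0):
            raise ValueError("size factors must be strictly positive")


@dataclass
class DispersionTrend:
    """Parametric dispersion-mean trend alpha(mu) = a0 + a1 / mu."""

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("trend coefficients must be nonnegative")

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            alpha = self.a0 + self.a1 / mu
        return np.where(mu > 0, alpha, 0.0)


def _counts(cm) -> np.ndarray:
    if isinstance(cm, CountMatrix):
        return cm.counts.astype(float)
    return np.asarray(cm, dtype=float)


def median_ratio_size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each gene with strictly positive counts in every sample, compute the
    ratio of each sample's count to the gene's geometric mean across samples;
    a sample's size factor is the median of its ratios.  Genes containing any
    zero are excluded from the median.
    """
    k = _counts(cm)
    all_positive = np.all(k > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "size factors are undefined (consider total-count normalization)")
    kp = k[all_positive]
    log_geo_mean = np.mean(np.log(kp), axis=1, keepdims=True)
    ratios = kp / np.exp(log_geo_mean)
    s = np.median(ratios, axis=0)
    ids = cm.sample_ids if isinstance(cm, CountMatrix) else [str(j) for j in range(k.shape[1])]
    return SizeFactors(list(ids), s)


def normalized_counts(cm, size_factors: SizeFactors) -> np.ndarray:
    return _counts(cm) / np.asarray(size_factors.values, dtype=float)[None, :]


def log1_transform(cm, size_factors: SizeFactors | None = None) -> np.ndarray:
    """Natural log of counts + 1; no normalization unless size factors are given.

    The raw (unnormalized) form is what feeds the log-scale Pearson
    dissimilarity; the base of the logarithm is irrelevant to a correlation.
    """
    x = _counts(cm) if size_factors is None else normalized_counts(cm, size_factors)
    return np.log1p(x)


def gene_dispersions(cm, size_factors: SizeFactors) -> np.ndarray:
    """Method-of-moments per-gene dispersion on normalized counts.

    alpha_g = max(0, (var_g - mean_g) / mean_g^2), with the n-1 sample
    variance; genes with zero mean get alpha 0.
    """
    x = normalized_counts(cm, size_factors)
    if x.shape[1] < 2:
        raise ValueError("dispersion estimation requires at least 2 samples")
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, 0.0)
    return np.clip(alpha, 0.0, None)


def fit_dispersion_trend(cm, size_factors: SizeFactors,
                         min_mean: float = 1.0) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu to gene-wise moment dispersions.

    Nonnegative least squares of the *unclipped* moment estimates
    (var - mean) / mean^2 on [1, 1/mu], restricted to genes with mean >=
    ``min_mean``.  Clipping individual estimates at zero before regression
    would bias the trend upward; instead only the fitted coefficients are
    constrained nonnegative, so Poisson data yields a0 ≈ a1 ≈ 0.
    """
    x = normalized_counts(cm, size_factors)
    if x.shape[1] < 2:
        raise ValueError("dispersion trend requires at least 2 samples")
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    keep = mean >= min_mean
    if not keep.any():
        return DispersionTrend(0.0, 0.0)
    mu = mean[keep]
    alpha = (var[keep] - mu) / mu**2
    design = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, _ = scipy.optimize.nnls(design, alpha)
    return DispersionTrend(float(coef[0]), float(coef[1]))


def vst(cm, size_factors: SizeFactors, trend: DispersionTrend) -> np.ndarray:
    """Closed-form variance-stabilizing transform of normalized counts.

    For v(mu) = mu + (a0 + a1/mu) mu^2 the integral of 1/sqrt(v) gives, on the
    log2 scale,

        vst(x) = log2( (1 + a1 + 2 a0 x + 2 sqrt(a0 x (1 + a1 + a0 x))) / (4 a0) )

    which is strictly increasing in x and log2-like for large x.  When a0 = 0
    the formula degenerates; the transform falls back to log2(x + 1).
    """
    x = _counts(cm) if size_factors is None else normalized_counts(cm, size_factors)
    if (x < 0).any():
        raise ValueError("vst requires nonnegative input")
    a0, a1 = trend.a0, trend.a1
    if a0 <= 0:
        return np.log2(x + 1.0)
    return np.log2((1 + a1 + 2 * a0 * x + 2 * np.sqrt(a0 * x * (1 + a1 + a0 * x)))
                   / (4 * a0))


def rlog(cm, size_factors: SizeFactors, trend: DispersionTrend,
         shrink_c: float = 1.0) -> np.ndarray:
    """Regularized log: shifted log2 of normalized counts shrunk toward the gene mean.

    y_gj = log2(k_gj / s_j + 0.5); the output is m_g + lambda_g (y_gj - m_g)
    with m_g the gene mean of y and shrinkage weight
    lambda_g = 1 / (1 + shrink_c * alpha(mu_g)), so high-count/low-dispersion
    genes stay close to plain log2 normalized counts while noisy genes are
    pulled toward their mean.
    """
    x = normalized_counts(cm, size_factors)
    if x.shape[1] < 2:
        raise ValueError("rlog requires at least 2 samples")
    y = np.log2(x + 0.5)
    m = y.mean(axis=1, keepdims=True)
    alpha = trend(x.mean(axis=1))
    lam = (1.0 / (1.0 + shrink_c * alpha))[:, None]
    return m + lam * (y - m)


def power_transform_beta(cm, grid_step: float = 0.01) -> float:
    """Select the power beta in (0, 1] that makes k**beta look Poisson.

    Grid search over beta = grid_step, 2*grid_step, ..., 1.00: for each beta
    compute the Pearson goodness-of-fit statistic of the transformed matrix
    against its row x column / total independence expectation,

        X^2(beta) = sum_gj (k_gj^beta - e_gj)^2 / e_gj ,

    and return the beta whose X^2 is closest to the statistic's degrees of
    freedom (n_genes - 1)(n_samples - 1).  Poisson-like data selects beta near
    1; overdispersed data selects a smaller beta, deflating the counts.
    """
    k = _counts(cm)
    if k.sum() == 0:
        raise ValueError("power transform undefined for an all-zero matrix")
    g, s = k.shape
    dof = (g - 1) * (s - 1)
    betas = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    best_beta, best_gap = 1.0, np.inf
    for beta in betas:
        t = k**beta
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        e = row * col / t.sum()
        mask = e > 0
        x2 = float((((t - e) ** 2)[mask] / e[mask]).sum())
        gap = abs(x2 - dof)
        if gap < best_gap:
            best_gap, best_beta = gap, float(beta)
    return best_beta
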