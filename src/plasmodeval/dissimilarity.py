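"""The eight sample-by-sample dissimilarity measures.

Euclidean family: raw counts (``raw``), median-of-ratios normalized counts
(``rnr``), variance-stabilized counts (``vsd``), regularized-log counts
(``rld``).  Correlation family: 1 - Pearson on raw counts (``pea``), 1 -
Pearson on log(count+1) (``plg``), 1 - Spearman on raw counts (``spe``).
Model family: the Poisson log-likelihood-ratio dissimilarity (``poi``),
computed on power-transformed, total-count-normalized data.

The Poisson LLR is reported without the conventional factor 2; complete
linkage is invariant under monotone rescaling, so dendrograms are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.spatial.distance
import scipy.stats

from .io_counts import CountMatrix
from . import transforms

__all__ = [
    "MEASURES",
    "DissimilarityMatrix",
    "euclidean_dissimilarity",
    "correlation_dissimilarity",
    "poisson_dissimilarity",
    "compute_measure",
]

MEASURES = ("raw", "rnr", "vsd", "rld", "pea", "plg", "spe", "poi")


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative sample × sample matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    measure_id: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("dissimilarity matrix must be square over sample_ids")
        if np.isnan(v).any():
            raise ValueError("dissimilarity matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        v = (v + v.T) / 2.0
        if (v < -1e-10).any():
            raise ValueError("dissimilarity matrix must be nonnegative")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _data_and_ids(data, sample_ids):
    if isinstance(data, CountMatrix):
        return data.counts.astype(float), list(data.sample_ids)
    x = np.asarray(data, dtype=float)
    ids = list(sample_ids) if sample_ids is not None else [str(j) for j in range(x.shape[1])]
    return x, ids


def euclidean_dissimilarity(data, sample_ids=None, measure_id="euclidean") -> DissimilarityMatrix:
    """Euclidean distance between samples (columns) of a genes × samples matrix."""
    x, ids = _data_and_ids(data, sample_ids)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("input contains NaN")
    # pdist subtracts coordinates pairwise: exact zeros for identical columns,
    # no Gram-matrix cancellation
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x.T))
    return DissimilarityMatrix(ids, d, measure_id)


def correlation_dissimilarity(data, flavor: str, sample_ids=None,
                              measure_id=None) -> DissimilarityMatrix:
    """1 - correlation between samples; ``flavor`` is 'pearson' or 'spearman'.

    Spearman uses average ranks for ties and is therefore invariant under any
    strictly monotone transformation of the counts.
    """
    x, ids = _data_and_ids(data, sample_ids)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if flavor == "pearson":
        sd = x.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"constant column for sample {ids[bad[0]]!r}: "
                             "Pearson correlation undefined")
        r = np.corrcoef(x, rowvar=False)
    elif flavor == "spearman":
        for j in range(x.shape[1]):
            if np.unique(x[:, j]).size < 2:
                raise ValueError(f"sample {ids[j]!r} has fewer than 2 distinct "
                                 "values: Spearman correlation undefined")
        ranks = scipy.stats.rankdata(x, axis=0)
        r = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown correlation flavor {flavor!r}")
    r = np.atleast_2d(r)
    return DissimilarityMatrix(ids, 1.0 - r, measure_id or flavor)


def poisson_dissimilarity(cm, apply_power: bool = True, sample_ids=None) -> DissimilarityMatrix:
    """Poisson log-likelihood-ratio dissimilarity between samples.

    Optionally replaces counts k by k**beta (beta selected by the power
    transform to absorb overdispersion), then normalizes by each sample's
    total.  For samples i, j the null (common-rate) fitted value for gene g is
    N_ig = n_i (k_gi + k_gj) / (n_i + n_j) with n_i the sample total, and

        d_ij = sum_g [ k_gi log(k_gi / N_ig) + k_gj log(k_gj / N_jg) ]

    with the 0 log 0 = 0 convention.  Symmetric and zero for identical samples.
    """
    x, ids = _data_and_ids(cm, sample_ids)
    if (x < 0).any():
        raise ValueError("Poisson dissimilarity requires nonnegative counts")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if apply_power:
        beta = transforms.power_transform_beta(x)
        x = x**beta
    totals = x.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {ids[zero[0]]!r} has zero total count")
    m = x.shape[1]
    d = np.zeros((m, m))

    def half_llr(k, fitted):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = k * np.log(k / fitted)
        return np.where(k > 0, term, 0.0).sum()

    for i in range(m):
        for j in range(i + 1, m):
            pooled = (x[:, i] + x[:, j]) / (totals[i] + totals[j])
            n_i = totals[i] * pooled
            n_j = totals[j] * pooled
            d[i, j] = d[j, i] = half_llr(x[:, i], n_i) + half_llr(x[:, j], n_j)
    return DissimilarityMatrix(ids, d, "poi")


def compute_measure(cm: CountMatrix, measure_id: str) -> DissimilarityMatrix:
    """Dispatch a measure identifier to its transformation + distance recipe."""
    if measure_id not in MEASURES:
        raise ValueError(f"unknown measure {measure_id!r}; choose from {MEASURES}")
    k = cm.counts.astype(float)
    if measure_id == "raw":
        return euclidean_dissimilarity(k, cm.sample_ids, "raw")
    if measure_id == "pea":
        return correlation_dissimilarity(k, "pearson", cm.sample_ids, "pea")
    if measure_id == "plg":
        return correlation_dissimilarity(np.log1p(k), "pearson", cm.sample_ids, "plg")
    if measure_id == "spe":
        return correlation_dissimilarity(k, "spearman", cm.sample_ids, "spe")
    if measure_id == "poi":
        return poisson_dissimilarity(cm, apply_power=True)
    sf = transforms.median_ratio_size_factors(cm)
    if measure_id == "rnr":
        return euclidean_dissimilarity(transforms.normalized_counts(cm, sf),
                                       cm.sample_ids, "rnr")
    trend = transforms.fit_dispersion_trend(cm, sf)
    if measure_id == "vsd":
        return euclidean_dissimilarity(transforms.vst(cm, sf, trend),
                                       cm.sample_ids, "vsd")
    return euclidean_dissimilarity(transforms.rlog(cm, sf, trend),
                                   cm.sample_ids, "rld")
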