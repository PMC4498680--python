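"""Two-group differential-expression testing on normalized counts.

Provides the DE gene sets and per-gene effects that the effect-injection
plasmode generator transplants.  The test is a negative-binomial Wald test
with method-of-moments dispersion: per gene, the log2 fold change of group
mean normalized counts, its delta-method standard error under the NB
mean-variance relationship, and a two-sided p-value from a t reference
distribution with n - 2 degrees of freedom (the heavier tail keeps the type-I
error near nominal at the small group sizes typical here).  Benjamini-
Hochberg q-values are appended.  Generators also accept an externally
produced DE table, so results from any other DE pipeline can be injected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_counts import CountMatrix, SampleMeta
from .transforms import SizeFactors, gene_dispersions, normalized_counts

__all__ = ["estimate_dispersions", "nb_two_group_test", "bh_adjust", "DE_COLUMNS"]

DE_COLUMNS = ("gene_id", "log2_fold_change", "p_value", "q_value")


def estimate_dispersions(cm: CountMatrix, size_factors: SizeFactors) -> np.ndarray:
    """Method-of-moments dispersion alpha_g on normalized counts (pooled samples)."""
    return gene_dispersions(cm, size_factors)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _within_group_dispersion(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Pooled within-group moment dispersion, clipped at 0."""
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    var_w = ((n_a - 1) * x_a.var(axis=1, ddof=1) + (n_b - 1) * x_b.var(axis=1, ddof=1)) \
        / (n_a + n_b - 2)
    mean_w = (x_a.sum(axis=1) + x_b.sum(axis=1)) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mean_w) / mean_w**2
    return np.clip(np.where(mean_w > 0, alpha, 0.0), 0.0, None)


def nb_two_group_test(cm: CountMatrix, meta: SampleMeta,
                      size_factors: SizeFactors,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene two-group NB Wald test on normalized counts.

    Returns a DataFrame with columns gene_id, log2_fold_change (second group
    vs first, groups in sorted label order), p_value, q_value.  When a group
    mean is zero the fold change uses ``pseudocount`` added to both group
    means to stay finite.
    """
    meta.validate_against(cm)
    groups = sorted({meta.group_of(s) for s in cm.sample_ids})
    if len(groups) != 2:
        raise ValueError(f"exactly two group labels required, found {groups}")
    cols_a = [j for j, s in enumerate(cm.sample_ids) if meta.group_of(s) == groups[0]]
    cols_b = [j for j, s in enumerate(cm.sample_ids) if meta.group_of(s) == groups[1]]
    if min(len(cols_a), len(cols_b)) < 2:
        raise ValueError("each group needs at least 2 samples")

    x = normalized_counts(cm, size_factors)
    x_a, x_b = x[:, cols_a], x[:, cols_b]
    n_a, n_b = len(cols_a), len(cols_b)
    mean_a, mean_b = x_a.mean(axis=1), x_b.mean(axis=1)
    alpha = _within_group_dispersion(x_a, x_b)

    needs_pc = (mean_a == 0) | (mean_b == 0)
    m_a = np.where(needs_pc, mean_a + pseudocount, mean_a)
    m_b = np.where(needs_pc, mean_b + pseudocount, mean_b)
    lfc = np.log2(m_b) - np.log2(m_a)

    # delta method: var(log2 mean) = var(mean) / (mean ln2)^2 with NB variance
    var_mean_a = (m_a + alpha * m_a**2) / n_a
    var_mean_b = (m_b + alpha * m_b**2) / n_b
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(var_mean_a / (m_a**2 * ln2sq) + var_mean_b / (m_b**2 * ln2sq))

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    stat = np.where(lfc == 0, 0.0, stat)                 # identical means: no evidence
    degenerate = (se == 0) & (lfc != 0)                  # zero variance, distinct means
    stat = np.where(degenerate, np.where(lfc > 0, np.inf, -np.inf), stat)
    dof = n_a + n_b - 2
    p = 2.0 * scipy.stats.t.sf(np.abs(stat), df=dof)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame({"gene_id": cm.gene_ids, "log2_fold_change": lfc,
                         "p_value": p, "q_value": q})
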