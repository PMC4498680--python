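"""Aggregate cophenetic correlations across plasmode replicates.

Three summaries quantify how dissimilarity measures behave over an ensemble
of plasmodes:

* **agreement** — for each pair of measures, the mean and SD over replicates
  of the cophenetic correlation between their dendrograms on the same
  replicate (do two measures see the same hierarchy?);
* **consistency** — for each measure, the mean and SD of cophenetic
  correlations over all replicate pairs (does a measure reproduce the same
  hierarchy across replicates?);
* **reference correlation** — per replicate, the correlation of a measure's
  dissimilarities with the known reference dissimilarity of a mixture design
  (does the measure recover the planted structure?).

SDs use the n-1 denominator; correlations are plain Pearson on raw cophenetic
values (no Fisher z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .hclust_cophenetic import cophenetic_correlation
from .plasmode_mixture import ReferenceSimilarity

__all__ = ["AgreementReport", "agreement", "consistency", "reference_correlation",
           "agreement_heatmap"]

logger = logging.getLogger(__name__)


@dataclass
class AgreementReport:
    """Mean (conceptually upper-triangle) and SD (lower-triangle) matrices of
    between-measure cophenetic correlations; both stored full and symmetric."""

    measures: list[str]
    mean: pd.DataFrame
    sd: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        """Single matrix with means above the diagonal and SDs below it —
        the conventional compact rendering."""
        out = self.mean.copy().astype(float)
        for i, a in enumerate(self.measures):
            for j, b in enumerate(self.measures):
                if i > j:
                    out.loc[a, b] = self.sd.loc[a, b]
        return out


def _aligned_correlation(entry_a, entry_b) -> float:
    """Cophenetic correlation between two (matrix, leaf_ids) entries."""
    (c_a, ids_a), (c_b, ids_b) = entry_a, entry_b
    return cophenetic_correlation(c_a, c_b, ids_a, ids_b)


def agreement(coph: dict[tuple[int, str], tuple[np.ndarray, list[str]]],
              measures: list[str] | None = None) -> AgreementReport:
    """Between-measure agreement over replicates.

    ``coph`` maps (replicate index, measure id) to a (cophenetic matrix,
    leaf id list) pair.  Every replicate must carry every measure.
    """
    replicates = sorted({k for k, _ in coph})
    if measures is None:
        measures = sorted({m for _, m in coph})
    missing = [(k, m) for k in replicates for m in measures if (k, m) not in coph]
    if missing:
        raise ValueError(f"missing cophenetic matrices for {missing}")
    mean = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    sd = pd.DataFrame(np.zeros((len(measures), len(measures))),
                      index=measures, columns=measures)
    for i, a in enumerate(measures):
        for j in range(i + 1, len(measures)):
            b = measures[j]
            r = np.array([_aligned_correlation(coph[(k, a)], coph[(k, b)])
                          for k in replicates])
            mean.loc[a, b] = mean.loc[b, a] = float(np.mean(r))
            sd.loc[a, b] = sd.loc[b, a] = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    return AgreementReport(list(measures), mean, sd)


def consistency(coph: dict[int, tuple[np.ndarray, list[str]]]) -> tuple[float, float]:
    """Within-measure consistency: mean and SD of cophenetic correlations over
    all unordered replicate pairs.  With exactly one pair the SD is reported
    as 0 by convention (logged)."""
    keys = sorted(coph)
    if len(keys) < 2:
        raise ValueError("consistency needs at least 2 replicates")
    r = [_aligned_correlation(coph[a], coph[b])
         for i, a in enumerate(keys) for b in keys[i + 1:]]
    if len(r) == 1:
        logger.info("single replicate pair: SD reported as 0 by convention")
        return float(r[0]), 0.0
    return float(np.mean(r)), float(np.std(r, ddof=1))


def reference_correlation(d: DissimilarityMatrix, ref: ReferenceSimilarity) -> float:
    """Pearson correlation of a measure's lower-triangle dissimilarities with
    the reference dissimilarity 1 - s, aligned by sample id."""
    if sorted(d.sample_ids) != sorted(ref.sample_ids):
        raise ValueError("dissimilarity and reference cover different samples")
    order = [ref.sample_ids.index(s) for s in d.sample_ids]
    d_ref = ref.d_ref[np.ix_(order, order)]
    tri = np.tril_indices(len(order), k=-1)
    x, y = d.values[tri], d_ref[tri]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance lower triangle: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def agreement_heatmap(report: AgreementReport, path) -> None:
    """Render the combined mean/SD matrix as a heat map (mean above diagonal,
    SD below), for visual inspection of measure families."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combined = report.combined().to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(combined, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(report.measures)), report.measures, rotation=45)
    ax.set_yticks(range(len(report.measures)), report.measures)
    for i in range(len(report.measures)):
        for j in range(len(report.measures)):
            ax.text(j, i, f"{combined[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    fig.colorbar(im, ax=ax, label="mean (upper) / SD (lower)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
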