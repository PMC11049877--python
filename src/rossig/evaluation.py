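"""Discriminative performance of a score: ROC/AUC, rank-sum test, PCA.

The AUC is computed two independent ways — as the Mann-Whitney rank
statistic (ties half-credited) and as the trapezoidal area under the full
threshold-sweep ROC curve — and the two agree to floating tolerance; the
rank statistic is the reported value. The positive class is fixed to
``survivor`` with ascending scores predicting survival: no automatic
orientation flipping, so a signature pointing the wrong way shows up as
AUC < 0.5 rather than being silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve

from .signature import GeneSignature

__all__ = ["RocResult", "PcaResult", "roc_auc", "group_difference_test", "pca_signature"]


@dataclass
class RocResult:
    auc: float
    curve_points: np.ndarray  # (n_points, 2): false positive rate, true positive rate
    positive_class: str
    n_pos: int
    n_neg: int


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    genes_used: list[str]


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U; ties contribute 1/2."""
    ranks = stats.rankdata(scores)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, outcomes) -> RocResult:
    """ROC curve and AUC with survivors as the positive class.

    ``outcomes`` holds ``survivor`` / ``nonsurvivor`` labels (or booleans,
    True = survivor) aligned with ``scores``.
    """
    scores = np.asarray(scores, dtype=float)
    positive = _as_positive(outcomes)
    if scores.shape != positive.shape:
        raise ValueError("scores and outcomes differ in length")
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    auc = rank_auc(scores, positive)
    fpr, tpr, _ = roc_curve(positive, scores, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return RocResult(
        auc=auc, curve_points=curve, positive_class="survivor",
        n_pos=n_pos, n_neg=n_neg,
    )


def _as_positive(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype == bool:
        return arr
    return arr.astype(str) == "survivor"


def group_difference_test(scores, groups) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups of scores.

    ``groups`` is a binary labelling aligned with ``scores``. The null is
    enumerated exactly for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction (and continuity correction)
    is used. Returns a p-value in (0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq.size}")
    x = scores[labels == uniq[0]]
    y = scores[labels == uniq[1]]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (scores.size <= 20 and not has_ties) else "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0))


def pca_signature(
    expr: pd.DataFrame,
    sig: GeneSignature,
    k: int = 2,
    scale: bool = False,
) -> PcaResult:
    """PCA of the samples in signature-gene space.

    Works on the gene-centered samples x genes matrix via SVD; by default no
    unit-variance scaling is applied (the survival score already
    standardizes), ``scale=True`` divides each gene by its standard
    deviation first.
    """
    present = [g for g in sig.genes if g in expr.index]
    if len(present) < 2:
        raise ValueError("need at least 2 signature genes present in the matrix")
    x = expr.loc[present].to_numpy(dtype=float).T  # samples x genes
    if k > min(len(present), x.shape[0] - 1):
        raise ValueError("k exceeds min(genes used, samples - 1)")
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance gene under scale=True")
        x = x / sd
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    coordinates = pd.DataFrame(
        coords, index=expr.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(
        coordinates=coordinates,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        genes_used=present,
    )
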