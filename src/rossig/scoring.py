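"""The sepsis survival score and mean-threshold stratification.

For sample *j* the score is the weighted sum of z-standardized signature
gene expression,

    score_j = sum_i W_i * (e_ij - mu_i) / S_i,

where ``mu_i`` and ``S_i`` are the mean and (n-1 denominator) standard
deviation of gene *i* across all samples of the scored matrix. By default
the standardization parameters are recomputed within each dataset, so a
validation cohort needs nothing from discovery; pass ``frozen_params`` for
deployment-style scoring with fixed parameters. Higher scores predict
survival under the packaged signature's orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import GeneSignature

__all__ = ["ScoreResult", "StratifiedGroups", "survival_score", "stratify_by_mean"]


@dataclass
class ScoreResult:
    """Per-sample scores plus the standardization parameters used."""

    scores: pd.Series  # index: sample ids
    gene_params: pd.DataFrame  # columns: gene_id, mu, s
    signature_ref: str = ""
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class StratifiedGroups:
    """Mean-score split: strictly above the mean is ``high_score``."""

    threshold: float
    assignment: pd.Series  # index: sample ids, values high_score/low_score

    @property
    def high(self) -> list[str]:
        return self.assignment.index[self.assignment == "high_score"].tolist()

    @property
    def low(self) -> list[str]:
        return self.assignment.index[self.assignment == "low_score"].tolist()


def survival_score(
    expr: pd.DataFrame,
    sig: GeneSignature,
    frozen_params: pd.DataFrame | None = None,
) -> ScoreResult:
    """Score every sample of ``expr`` with the weighted z-score sum.

    Signature genes missing from the matrix — or with zero standard
    deviation, which the standardization cannot absorb — are dropped with a
    warning and listed in ``dropped_genes``; the score is a plain sum over
    the remaining genes (no renormalization by gene count).
    """
    present = [g for g in sig.genes if g in expr.index]
    dropped = [g for g in sig.genes if g not in expr.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")

    sub = expr.loc[present].to_numpy(dtype=float)
    if frozen_params is not None:
        params = frozen_params.set_index("gene_id")
        missing = [g for g in present if g not in params.index]
        if missing:
            raise ValueError(f"frozen_params lacks genes: {missing[:5]}")
        mu = params.loc[present, "mu"].to_numpy(dtype=float)
        s = params.loc[present, "s"].to_numpy(dtype=float)
    else:
        mu = sub.mean(axis=1)
        s = sub.std(axis=1, ddof=1)

    usable = s > 0
    if not usable.all():
        zero_sd = [g for g, u in zip(present, usable) if not u]
        warnings.warn(
            f"dropping zero-variance signature genes: {zero_sd[:5]}",
            stacklevel=2,
        )
        dropped += zero_sd
        present = [g for g, u in zip(present, usable) if u]
        sub, mu, s = sub[usable], mu[usable], s[usable]
        if not present:
            raise ValueError("every present signature gene has zero variance")

    w = sig.weights.loc[present].to_numpy(dtype=float)
    z = (sub - mu[:, None]) / s[:, None]
    scores = pd.Series(w @ z, index=expr.columns, name="score")
    params = pd.DataFrame({"gene_id": present, "mu": mu, "s": s})
    return ScoreResult(
        scores=scores,
        gene_params=params,
        signature_ref=str(sig.source_labels),
        dropped_genes=dropped,
    )


def stratify_by_mean(result: ScoreResult) -> StratifiedGroups:
    """Split samples at the mean score; ties at the mean go to low_score."""
    scores = result.scores
    if len(scores) < 2:
        raise ValueError("stratification needs at least 2 samples")
    threshold = float(scores.mean())
    assignment = pd.Series(
        np.where(scores > threshold, "high_score", "low_score"),
        index=scores.index,
        name="group",
    )
    return StratifiedGroups(threshold=threshold, assignment=assignment)
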