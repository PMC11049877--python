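"""Random-signature null benchmark for the summed two-cohort AUC.

The observed signature is compared against signatures of the same size
drawn uniformly at random from a gene pool (whole genome or a
survival-related subset). Each draw is weighted like the real signature —
+1/-1 by the sign of the gene's discovery-cohort log2 fold change — then
scored in both cohorts with per-dataset standardization, and its
discovery + validation AUC sum is recorded. The observed signature's
placement is reported as a percentile using strictly-below counting, so
ties with null draws count against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .evaluation import rank_auc
from .io import outcome_mask
from .signature import GeneSignature

__all__ = ["NullDistribution", "random_signature", "null_distribution"]


@dataclass
class NullDistribution:
    pool_label: str
    draws: pd.DataFrame  # draw_index, auc_discovery, auc_validation, auc_sum
    n_draws: int
    signature_size: int
    observed_sum: float
    observed_auc_discovery: float
    observed_auc_validation: float
    percentile: float
    seed: int | None

    @property
    def sums(self) -> np.ndarray:
        return self.draws["auc_sum"].to_numpy()


def _fc_signs(deg_table: pd.DataFrame, pool: list[str]) -> pd.Series:
    signs = deg_table.set_index("gene_id")["log2fc"].reindex(pool)
    missing = signs.index[signs.isna()].tolist()
    if missing:
        raise ValueError(f"pool genes without a discovery log2fc: {missing[:5]}")
    return np.sign(signs)


def random_signature(
    pool: list[str],
    size: int,
    deg_table: pd.DataFrame,
    rng: np.random.Generator,
) -> GeneSignature:
    """Uniform random same-size signature, weighted by discovery fold-change sign.

    Genes whose discovery log2fc is exactly zero carry no usable direction
    and are removed from the pool before sampling.
    """
    signs = _fc_signs(deg_table, list(pool))
    usable = signs[signs != 0]
    if len(usable) < size:
        raise ValueError(f"pool has {len(usable)} usable genes, need {size}")
    chosen = rng.choice(usable.index.to_numpy(), size=size, replace=False)
    fc = deg_table.set_index("gene_id")["log2fc"].loc[chosen]
    entries = pd.DataFrame(
        {"gene_id": chosen, "log2fc": fc.to_numpy(),
         "weight": np.sign(fc.to_numpy()).astype(int)}
    )
    return GeneSignature(entries, {"signature": "random"})


class _CohortScorer:
    """Z-scores a cohort once so each draw is a single mat-vec product."""

    def __init__(self, expr: pd.DataFrame, meta: pd.DataFrame) -> None:
        values = expr.to_numpy(dtype=float)
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        keep = sd[:, 0] > 0
        self.z = (values[keep] - mu[keep]) / sd[keep]
        self.index = {g: i for i, g in enumerate(expr.index[keep])}
        self.positive = outcome_mask(meta, list(expr.columns)).to_numpy()
        if self.positive.all() or not self.positive.any():
            raise ValueError("cohort needs both survivors and non-survivors")

    def auc(self, genes: np.ndarray, weights: np.ndarray) -> float:
        rows = np.array([self.index[g] for g in genes if g in self.index])
        used = np.array([g in self.index for g in genes])
        if not rows.size:
            raise ValueError("no usable signature gene in cohort")
        scores = weights[used] @ self.z[rows]
        return rank_auc(scores, self.positive)


def null_distribution(
    expr_disc: pd.DataFrame,
    expr_val: pd.DataFrame,
    meta: pd.DataFrame,
    pool: list[str],
    deg_table: pd.DataFrame,
    observed: GeneSignature,
    size: int = 37,
    n_draws: int = 10_000,
    seed: int | None = 0,
    pool_label: str = "whole_genome",
    exhaustive: bool = False,
) -> NullDistribution:
    """Summed-AUC null distribution and the observed signature's percentile.

    With ``exhaustive=True`` every size-subset of the pool is enumerated
    instead of sampled (tiny pools only); ``n_draws`` is then ignored.
    Percentile = 100 * (#draws strictly below observed sum) / n_draws.
    """
    signs = _fc_signs(deg_table, list(pool))
    usable = signs[signs != 0].index.to_numpy()
    if len(usable) < size:
        raise ValueError(f"pool has {len(usable)} usable genes, need {size}")
    fc = deg_table.set_index("gene_id")["log2fc"]

    disc = _CohortScorer(expr_disc, meta[meta["cohort"] == "discovery"])
    val = _CohortScorer(expr_val, meta[meta["cohort"] == "validation"])

    if exhaustive:
        subsets = [np.array(c) for c in combinations(sorted(usable), size)]
    else:
        rng = np.random.default_rng(seed)
        subsets = [
            rng.choice(usable, size=size, replace=False) for _ in range(n_draws)
        ]

    records = np.empty((len(subsets), 2))
    for i, genes in enumerate(subsets):
        weights = np.sign(fc.loc[genes].to_numpy(dtype=float))
        try:
            records[i, 0] = disc.auc(genes, weights)
            records[i, 1] = val.auc(genes, weights)
        except ValueError as exc:  # propagate with the failing draw named
            raise ValueError(f"draw {i} failed: {exc}") from exc

    draws = pd.DataFrame(
        {
            "draw_index": np.arange(len(subsets)),
            "auc_discovery": records[:, 0],
            "auc_validation": records[:, 1],
            "auc_sum": records.sum(axis=1),
        }
    )

    obs_genes = np.array(observed.genes)
    obs_weights = observed.weights.to_numpy(dtype=float)
    obs_disc = disc.auc(obs_genes, obs_weights)
    obs_val = val.auc(obs_genes, obs_weights)
    observed_sum = obs_disc + obs_val
    percentile = 100.0 * float((draws["auc_sum"] < observed_sum).sum()) / len(draws)

    return NullDistribution(
        pool_label=pool_label,
        draws=draws,
        n_draws=len(draws),
        signature_size=size,
        observed_sum=float(observed_sum),
        observed_auc_discovery=float(obs_disc),
        observed_auc_validation=float(obs_val),
        percentile=percentile,
        seed=None if exhaustive else seed,
    )
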