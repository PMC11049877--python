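"""Two-group differential expression with a fold-change / FDR filter.

Survivors are compared against non-survivors gene by gene with a two-sided
Welch t-test (unequal variances); ``log2fc`` is the difference of group
means on the log2 scale (survivor minus non-survivor). Multiplicity is
controlled with Benjamini-Hochberg across all testable genes, and the
significance filter keeps genes with ``|log2fc| > log2(fc_threshold)`` and
``q < fdr``. Genes that are constant within both groups cannot be tested;
they are emitted with a degenerate flag, ``p = 1`` and no q-value, and are
excluded from the BH adjustment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import outcome_mask

__all__ = ["compute_deg", "bh_adjust", "filter_deg"]

DEG_COLUMNS = ["gene_id", "log2fc", "t_stat", "p_value", "q_value", "degenerate_flag"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_deg(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t-test between survivors and non-survivors.

    Returns one row per gene of ``expr`` with columns
    ``gene_id, log2fc, t_stat, p_value, q_value, degenerate_flag``.
    Requires at least two samples in each outcome group.
    """
    is_surv = outcome_mask(meta, list(expr.columns)).to_numpy()
    n_pos, n_neg = int(is_surv.sum()), int((~is_surv).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {n_pos} survivors / {n_neg} non-survivors"
        )
    values = expr.to_numpy(dtype=float)
    surv, nons = values[:, is_surv], values[:, ~is_surv]

    log2fc = surv.mean(axis=1) - nons.mean(axis=1)
    var_s = surv.var(axis=1, ddof=1)
    var_n = nons.var(axis=1, ddof=1)
    degenerate = (var_s == 0) & (var_n == 0)

    t_stat = np.zeros(len(expr))
    p_value = np.ones(len(expr))
    testable = ~degenerate
    if testable.any():
        res = stats.ttest_ind(
            surv[testable], nons[testable], axis=1, equal_var=False
        )
        t_stat[testable] = res.statistic
        p_value[testable] = res.pvalue

    q_value = np.full(len(expr), np.nan)
    if testable.any():
        q_value[testable] = bh_adjust(p_value[testable])

    return pd.DataFrame(
        {
            "gene_id": expr.index.astype(str),
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "degenerate_flag": degenerate,
        }
    ).reset_index(drop=True)


def filter_deg(
    records: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Keep genes with ``|log2fc| > log_base(fc_threshold)`` and ``q < fdr``.

    Both comparisons are strict. ``log_base`` covers the (unlikely) case of
    fold changes reported in a base other than 2; the cutoff on the stored
    column is ``log(fc_threshold) / log(log_base)``.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    cutoff = math.log(fc_threshold) / math.log(log_base)
    keep = (
        ~records["degenerate_flag"].astype(bool)
        & (records["log2fc"].abs() > cutoff)
        & (records["q_value"] < fdr)
    )
    out = records[keep].copy()
    out = out.reindex(out["log2fc"].abs().sort_values(ascending=False, kind="mergesort").index)
    return out.reset_index(drop=True)
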