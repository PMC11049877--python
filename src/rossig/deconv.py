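"""Reference-based immune-cell deconvolution via non-negative least squares.

Each bulk sample is modelled as a non-negative combination of per-cell-type
reference expression profiles (a signature matrix on the linear scale);
coefficients are fit by NNLS and rescaled to sum to one. This is a
deliberately simple stand-in for nu-SVR-based deconvolution: it makes no
claim of numerical concordance with that method and accepts any conforming
signature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .evaluation import group_difference_test
from .deg import bh_adjust
from .scoring import StratifiedGroups

__all__ = [
    "DeconvResult",
    "validate_reference",
    "read_reference",
    "write_reference",
    "synthetic_reference",
    "deconvolve",
    "compare_fractions",
]


@dataclass
class DeconvResult:
    """Per-sample cell-type fractions (rows sum to 1 unless degenerate)."""

    fractions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series
    degenerate: pd.Series  # True where NNLS returned the all-zero solution


def validate_reference(ref: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x cell-types signature matrix (linear scale)."""
    if ref.shape[1] < 2:
        raise ValueError("reference needs at least 2 cell types")
    if ref.index.has_duplicates or ref.columns.has_duplicates:
        raise ValueError("reference gene ids and cell types must be unique")
    values = ref.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("reference profiles must be non-negative")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("reference contains an all-zero gene row")
    return ref


def read_reference(path: str | Path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t", index_col="gene_id").astype(float)
    return validate_reference(ref)


def write_reference(ref: pd.DataFrame, path: str | Path) -> Path:
    validate_reference(ref)
    ref.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    return Path(path)


def synthetic_reference(
    n_cell_types: int = 6,
    n_genes: int = 60,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A small synthetic signature matrix with marker-block structure.

    Each cell type receives an equal block of marker genes expressed ~50x
    above a low common baseline, giving well-separated linear-scale
    profiles that NNLS can resolve. A synthetic stand-in for curated
    references, used by tests and the demo pipeline.
    """
    if n_genes < n_cell_types:
        raise ValueError("need at least one gene per cell type")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"M{i + 1:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    profiles = rng.uniform(1.0, 5.0, size=(n_genes, n_cell_types))
    block = n_genes // n_cell_types
    for t in range(n_cell_types):
        rows = slice(t * block, (t + 1) * block)
        profiles[rows, t] = rng.uniform(80.0, 120.0, size=block)
    ref = pd.DataFrame(
        profiles,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"celltype_{t + 1}" for t in range(n_cell_types)],
    )
    return validate_reference(ref)


def deconvolve(
    mixture_expr: pd.DataFrame,
    ref: pd.DataFrame,
    log2_input: bool = True,
) -> DeconvResult:
    """Estimate cell-type fractions for every sample of a bulk matrix.

    Genes are matched by id between mixture and reference; at least as many
    shared genes as cell types are required. ``log2_input=True`` (the
    default, matching the rest of the pipeline) exponentiates the mixture
    to the linear scale before solving. An all-zero NNLS solution is
    flagged degenerate instead of raising.
    """
    validate_reference(ref)
    shared = [g for g in ref.index if g in mixture_expr.index]
    if len(shared) < ref.shape[1]:
        raise ValueError(
            f"{len(shared)} shared genes < {ref.shape[1]} cell types"
        )
    a = ref.loc[shared].to_numpy(dtype=float)
    b = mixture_expr.loc[shared].to_numpy(dtype=float)
    if log2_input:
        b = np.power(2.0, b)

    fractions = np.zeros((b.shape[1], ref.shape[1]))
    residuals = np.zeros(b.shape[1])
    degenerate = np.zeros(b.shape[1], dtype=bool)
    for j in range(b.shape[1]):
        coef, rnorm = nnls(a, b[:, j])
        total = coef.sum()
        if total == 0:
            degenerate[j] = True
        else:
            fractions[j] = coef / total
        residuals[j] = rnorm

    samples = mixture_expr.columns
    return DeconvResult(
        fractions=pd.DataFrame(fractions, index=samples, columns=ref.columns),
        residual_norm=pd.Series(residuals, index=samples, name="residual_norm"),
        degenerate=pd.Series(degenerate, index=samples, name="degenerate"),
    )


def compare_fractions(
    result: DeconvResult,
    groups: StratifiedGroups | pd.Series,
) -> pd.DataFrame:
    """Rank-sum comparison of each cell type's fractions between two groups.

    Returns per cell type the high-minus-low mean difference, the two-sided
    Wilcoxon rank-sum p-value and the BH-adjusted q-value.
    """
    labels = groups.assignment if isinstance(groups, StratifiedGroups) else groups
    labels = labels.reindex(result.fractions.index)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    hi = [g for g in uniq if g == "high_score"] or [uniq[1]]
    high_mask = (labels == hi[0]).to_numpy()
    if high_mask.all() or not high_mask.any():
        raise ValueError("both groups must be non-empty")

    rows = []
    for cell_type in result.fractions.columns:
        frac = result.fractions[cell_type].to_numpy(dtype=float)
        diff = float(frac[high_mask].mean() - frac[~high_mask].mean())
        p = group_difference_test(frac, high_mask)
        rows.append({"cell_type": cell_type, "mean_difference": diff, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"])
    return out
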