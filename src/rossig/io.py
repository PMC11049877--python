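"""Readers and writers for the plain-text formats shared by every stage.

All tables are UTF-8, tab-separated, with a mandatory header row:

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  values are log2 intensities;
* sample metadata — columns ``sample_id``, ``outcome`` (``survivor`` /
  ``nonsurvivor``) and ``cohort`` (``discovery`` / ``validation``);
* gene list — one identifier per line, no header.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

OUTCOMES = ("survivor", "nonsurvivor")
COHORTS = ("discovery", "validation")

# fixed float formatting keeps file bytes identical across runs
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """A file violates the expected on-disk layout."""


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) and return it.

    Requires unique gene and sample identifiers and finite float values.
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError("expression matrix contains non-finite values")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id")
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return validate_expression(expr.astype(float))


def write_expression(expr: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)
    return path


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample_id", "outcome", "cohort"} - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["outcome"]) - set(OUTCOMES)
    if bad:
        raise FormatError(f"unknown outcome labels: {sorted(bad)}")
    bad = set(meta["cohort"]) - set(COHORTS)
    if bad:
        raise FormatError(f"unknown cohort labels: {sorted(bad)}")
    for cohort, sub in meta.groupby("cohort"):
        if sub["sample_id"].duplicated().any():
            raise FormatError(f"duplicate sample ids within cohort {cohort!r}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_metadata(meta)
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
    return path


def outcome_mask(meta: pd.DataFrame, sample_ids) -> pd.Series:
    """Boolean survivor indicator aligned to ``sample_ids``.

    Raises if any sample lacks metadata or carries a duplicate row.
    """
    sub = meta[meta["sample_id"].isin(sample_ids)]
    lookup = sub.set_index("sample_id")["outcome"]
    missing = [s for s in sample_ids if s not in lookup.index]
    if missing:
        raise FormatError(f"samples without metadata: {missing[:5]}")
    return lookup.reindex(sample_ids).eq("survivor")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
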