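"""The free-radical-associated gene signature and its on-disk format.

A signature is an ordered list of ``(gene_id, log2fc, weight)`` entries where
the weight is +1 for genes up-regulated in survivors and -1 for genes
down-regulated, i.e. ``weight = sign(log2fc)``. The packaged 37-gene
signature fixture ships with the module, as does a curated ROS-style gene
list (a synthetic stand-in, see ``load_ros_list``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "SignatureFormatError",
    "EmptySignatureWarning",
    "build_signature",
    "read_signature",
    "write_signature",
    "load_table1_signature",
    "load_ros_list",
    "TABLE1_SYMBOLS",
]

_ENTRY_COLUMNS = ["gene_id", "log2fc", "weight"]


class SignatureFormatError(ValueError):
    """A signature table violates the weight/fold-change contract."""


class EmptySignatureWarning(UserWarning):
    """The DEG list and the curated gene list do not intersect."""


@dataclass
class GeneSignature:
    """Ordered weighted gene list; ``weight = sign(log2fc)`` elementwise."""

    entries: pd.DataFrame
    source_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        entries = pd.DataFrame(self.entries, columns=_ENTRY_COLUMNS).reset_index(
            drop=True
        )
        entries["gene_id"] = entries["gene_id"].astype(str).str.strip()
        entries["log2fc"] = entries["log2fc"].astype(float)
        entries["weight"] = entries["weight"].astype(int)
        if entries["gene_id"].duplicated().any():
            dups = entries.loc[entries["gene_id"].duplicated(), "gene_id"].tolist()
            raise SignatureFormatError(f"duplicate gene ids: {dups[:5]}")
        bad = entries.index[
            ~entries["weight"].isin([-1, 1])
            | (entries["log2fc"] == 0.0)
            | (np.sign(entries["log2fc"]) != entries["weight"])
        ]
        if len(bad):
            row = entries.loc[bad[0]]
            raise SignatureFormatError(
                f"row {bad[0]} ({row['gene_id']}): weight {row['weight']} "
                f"inconsistent with log2fc {row['log2fc']}"
            )
        self.entries = entries

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return self.entries["gene_id"].tolist()

    @property
    def weights(self) -> pd.Series:
        """Weights as a Series indexed by gene id, in signature order."""
        return self.entries.set_index("gene_id")["weight"].astype(float)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


def build_signature(
    degs: pd.DataFrame,
    gene_list: list[str],
    source_labels: dict[str, str] | None = None,
) -> GeneSignature:
    """Intersect filtered DEGs with a curated gene list and weight by sign.

    ``degs`` must carry ``gene_id`` and ``log2fc`` columns (already filtered
    for significance). Entries are ordered by descending log2fc — the
    positive block first — matching the packaged fixture's layout. An empty
    intersection yields an empty signature with :class:`EmptySignatureWarning`
    rather than an error.
    """
    if len(gene_list) == 0:
        raise ValueError("curated gene list is empty")
    wanted = {g.strip() for g in gene_list}
    hit = degs[degs["gene_id"].astype(str).str.strip().isin(wanted)]
    hit = hit.sort_values("log2fc", ascending=False, kind="mergesort")
    entries = pd.DataFrame(
        {
            "gene_id": hit["gene_id"].astype(str),
            "log2fc": hit["log2fc"].astype(float),
            "weight": np.sign(hit["log2fc"]).astype(int),
        }
    )
    if entries.empty:
        warnings.warn(
            "DEG list and curated gene list do not intersect; empty signature",
            EmptySignatureWarning,
            stacklevel=2,
        )
        entries = pd.DataFrame(columns=_ENTRY_COLUMNS)
    return GeneSignature(entries, source_labels or {})


def write_signature(sig: GeneSignature, path: str | Path) -> Path:
    path = Path(path)
    sig.entries.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_signature(path: str | Path) -> GeneSignature:
    """Read a signature TSV, validating the weight/sign contract per row."""
    table = pd.read_csv(path, sep="\t")
    missing = set(_ENTRY_COLUMNS) - set(table.columns)
    if missing:
        raise SignatureFormatError(f"missing columns: {sorted(missing)}")
    return GeneSignature(table[_ENTRY_COLUMNS])


def load_table1_signature() -> GeneSignature:
    """The packaged 37-gene free-radical signature fixture.

    26 entries carry weight +1 (up in survivors) and 11 carry weight -1.
    """
    ref = resources.files("rossig.data").joinpath("table1_signature.tsv")
    with resources.as_file(ref) as path:
        sig = read_signature(path)
    sig.source_labels = {"signature": "table1_signature.tsv"}
    return sig


def load_ros_list() -> list[str]:
    """The packaged 137-gene curated free-radical / ROS gene list.

    This is a synthetic stand-in: the 37 signature symbols plus 100 curated
    well-known oxidative-stress gene symbols. The original appendix list is
    not redistributable here; only its size (137) and its 37-gene overlap
    with the signature are preserved, which is all any computation uses.
    """
    ref = resources.files("rossig.data").joinpath("ros_list_synthetic.txt")
    return [
        line.strip()
        for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


TABLE1_SYMBOLS: tuple[str, ...] = (
    "KRT1", "BCL2", "TYSND1", "DHRS4", "EPHX2", "IFNG", "CCL5", "MYC",
    "SRC", "PRDX4", "GSS", "HACL1", "DNAJA3", "GSTP1", "PRDX2", "PTGS2",
    "HSPD1", "FMO5", "DNAJC9", "CCT4", "IL12RB1", "HSPA9", "CROT", "CCT3",
    "JUN", "SLC27A2", "GSR", "JAK2", "DNAJC5", "DNAJC4", "RHOU", "GCLM",
    "MSRA", "SOCS3", "PECR", "CYP1B1", "ARG1",
)
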