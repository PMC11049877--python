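"""Synthetic two-cohort sepsis expression data with planted survival signal.

Emulates the structure the downstream analysis assumes: a discovery and a
validation cohort of log2 microarray-like intensities, a binary 28-day
survival outcome per patient, a planted set of survival-associated genes,
and a curated ROS-style gene list that overlaps the planted set. The
generator is fully seeded so every downstream stage is testable without any
external download, and it emits a ground-truth record for parameter-recovery
tests.

Model: for gene *g* and sample *j*,

    x_gj = baseline_g + s_j * d_g * effect_g / 2 + eps_gj

where ``s_j`` is +1 for survivors and −1 for non-survivors, ``d_g`` is the
planted direction (0 for non-planted genes) and ``eps_gj`` is independent
Gaussian noise with a per-gene standard deviation. Genes are independent;
correlated blocks, batch effects and missing values are deliberately out of
scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .signature import TABLE1_SYMBOLS

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulationError",
    "simulate_cohorts",
    "make_ros_list",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


class SimulationError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-cohort world.

    Defaults mirror the emulated study design: 265 discovery + 106
    validation patients, a 137-gene curated ROS list sharing 37 genes with
    the planted survival-associated set, and a one-log2-unit planted shift.
    """

    n_genes: int = 2000
    n_samples_discovery: int = 265
    n_samples_validation: int = 106
    survivor_fraction: float = 0.7
    n_planted: int = 150
    effect_log2fc: float = 1.0
    frac_planted_up: float = 26 / 37
    gene_sd_range: tuple[float, float] = (0.2, 0.6)
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    ros_list_size: int = 137
    ros_overlap_with_planted: int = 37
    seed: int = 0
    # degenerate effect_log2fc == 0 (null world) must be requested explicitly
    allow_null_effect: bool = False
    # rename the ROS-overlap planted genes to the 37 packaged signature
    # symbols so fixture weights can be exercised verbatim
    use_table1_symbols: bool = False

    def validate(self) -> "SimConfig":
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be positive")
        for fld in ("n_samples_discovery", "n_samples_validation"):
            if getattr(self, fld) <= 0:
                raise SimulationError(f"{fld} must be positive")
        if not 0.0 < self.survivor_fraction < 1.0:
            raise SimulationError("survivor_fraction must lie in (0, 1)")
        if not 0 <= self.n_planted <= self.n_genes:
            raise SimulationError("n_planted must satisfy 0 <= n_planted <= n_genes")
        if self.effect_log2fc < 0:
            raise SimulationError("effect_log2fc must be non-negative")
        if self.effect_log2fc == 0 and not self.allow_null_effect:
            raise SimulationError(
                "effect_log2fc = 0 requires allow_null_effect=True"
            )
        if not 0.0 <= self.frac_planted_up <= 1.0:
            raise SimulationError("frac_planted_up must lie in [0, 1]")
        lo, hi = self.gene_sd_range
        if not (0 < lo <= hi):
            raise SimulationError("gene_sd_range lower bound must be > 0 and <= upper")
        lo, hi = self.baseline_mean_range
        if lo > hi:
            raise SimulationError("baseline_mean_range must be ordered")
        if self.ros_overlap_with_planted > min(self.ros_list_size, self.n_planted):
            raise SimulationError(
                "ros_overlap_with_planted exceeds min(ros_list_size, n_planted)"
            )
        if self.ros_list_size > self.n_genes:
            raise SimulationError("ros_list_size exceeds n_genes")
        if self.use_table1_symbols and self.ros_overlap_with_planted != len(
            TABLE1_SYMBOLS
        ):
            raise SimulationError(
                "use_table1_symbols requires ros_overlap_with_planted == 37"
            )
        return self


@dataclass
class TruthRecord:
    """Ground truth of one simulated world, for recovery tests."""

    planted_genes: list[str]
    planted_direction: dict[str, int]  # +1 up in survivors, -1 down
    effect_log2fc: float
    outcome_labels: dict[str, dict[str, str]]  # cohort -> sample_id -> outcome
    ros_list: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def _outcomes(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    n_surv = int(round(frac * n))
    n_surv = min(max(n_surv, 1), n - 1)  # keep both groups non-empty
    labels = np.array(["survivor"] * n_surv + ["nonsurvivor"] * (n - n_surv))
    rng.shuffle(labels)
    return labels


def _cohort_matrix(
    rng: np.random.Generator,
    baselines: np.ndarray,
    sds: np.ndarray,
    shift: np.ndarray,
    outcomes: np.ndarray,
) -> np.ndarray:
    sign = np.where(outcomes == "survivor", 1.0, -1.0)
    noise = rng.normal(0.0, 1.0, size=(baselines.size, outcomes.size)) * sds[:, None]
    return baselines[:, None] + shift[:, None] * sign[None, :] + noise


def simulate_cohorts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw discovery and validation cohorts from one planted truth.

    Returns ``(expr_discovery, expr_validation, metadata, truth)``. The two
    cohorts share planted genes, directions and effect size but have
    independent noise realizations and their own sample counts. Identical
    ``config`` (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"G{i + 1:06d}" for i in range(config.n_genes)])
    planted_idx = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    n_up = int(round(config.frac_planted_up * config.n_planted))
    directions = np.zeros(config.n_genes, dtype=int)
    signs = np.array([1] * n_up + [-1] * (config.n_planted - n_up))
    rng.shuffle(signs)
    directions[planted_idx] = signs

    # ROS list drawn before symbol injection so overlap membership is fixed
    overlap_idx = rng.choice(planted_idx, size=config.ros_overlap_with_planted,
                             replace=False)
    non_planted = np.setdiff1d(np.arange(config.n_genes), planted_idx)
    filler_idx = rng.choice(
        non_planted, size=config.ros_list_size - config.ros_overlap_with_planted,
        replace=False,
    )

    if config.use_table1_symbols:
        # rename the overlap genes to the packaged signature symbols and give
        # them the fixture's up/down pattern (26 up, 11 down)
        from .signature import load_table1_signature

        table1 = load_table1_signature()
        for j, (sym, w) in enumerate(
            zip(table1.entries["gene_id"], table1.entries["weight"])
        ):
            gene_ids[overlap_idx[j]] = sym
            directions[overlap_idx[j]] = int(w)

    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sds = rng.uniform(*config.gene_sd_range, size=config.n_genes)
    shift = directions * config.effect_log2fc / 2.0

    out_disc = _outcomes(rng, config.n_samples_discovery, config.survivor_fraction)
    out_val = _outcomes(rng, config.n_samples_validation, config.survivor_fraction)
    disc = _cohort_matrix(rng, baselines, sds, shift, out_disc)
    val = _cohort_matrix(rng, baselines, sds, shift, out_val)

    disc_ids = [f"D{i + 1:04d}" for i in range(config.n_samples_discovery)]
    val_ids = [f"V{i + 1:04d}" for i in range(config.n_samples_validation)]
    expr_disc = pd.DataFrame(disc, index=pd.Index(gene_ids, name="gene_id"),
                             columns=disc_ids)
    expr_val = pd.DataFrame(val, index=pd.Index(gene_ids, name="gene_id"),
                            columns=val_ids)

    meta = pd.DataFrame(
        {
            "sample_id": disc_ids + val_ids,
            "outcome": np.concatenate([out_disc, out_val]),
            "cohort": ["discovery"] * len(disc_ids) + ["validation"] * len(val_ids),
        }
    )

    planted_genes = gene_ids[np.sort(planted_idx)].tolist()
    truth = TruthRecord(
        planted_genes=planted_genes,
        planted_direction={
            g: int(directions[i])
            for i, g in zip(np.sort(planted_idx), gene_ids[np.sort(planted_idx)])
        },
        effect_log2fc=config.effect_log2fc,
        outcome_labels={
            "discovery": dict(zip(disc_ids, out_disc.tolist())),
            "validation": dict(zip(val_ids, out_val.tolist())),
        },
        seed=config.seed,
    )
    ros = gene_ids[np.sort(np.concatenate([overlap_idx, filler_idx]))].tolist()
    truth.ros_list = ros
    return expr_disc, expr_val, meta, truth


def make_ros_list(truth: TruthRecord, config: SimConfig) -> list[str]:
    """The curated ROS-style gene list of this simulated world.

    Length ``ros_list_size`` with exactly ``ros_overlap_with_planted``
    planted members; the remainder is drawn from non-planted genes without
    replacement at simulation time.
    """
    config.validate()
    ros = list(truth.ros_list)
    planted = set(truth.planted_genes)
    n_overlap = sum(g in planted for g in ros)
    if len(ros) != config.ros_list_size or n_overlap != config.ros_overlap_with_planted:
        raise SimulationError(
            "truth record inconsistent with config: "
            f"list size {len(ros)}, overlap {n_overlap}"
        )
    return ros


def write_fixture_bundle(
    expr_disc: pd.DataFrame,
    expr_val: pd.DataFrame,
    meta: pd.DataFrame,
    truth: TruthRecord,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the full bundle as plain text; round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_discovery": io.write_expression(
            expr_disc, directory / "expression_discovery.tsv"
        ),
        "expression_validation": io.write_expression(
            expr_val, directory / "expression_validation.tsv"
        ),
        "metadata": io.write_metadata(meta, directory / "metadata.tsv"),
        "ros_list": io.write_gene_list(truth.ros_list, directory / "ros_list.txt"),
        "truth": directory / "truth.json",
    }
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths


def read_fixture_bundle(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    directory = Path(directory)
    expr_disc = io.read_expression(directory / "expression_discovery.tsv")
    expr_val = io.read_expression(directory / "expression_validation.tsv")
    meta = io.read_metadata(directory / "metadata.tsv")
    truth = TruthRecord.from_json((directory / "truth.json").read_text("utf-8"))
    return expr_disc, expr_val, meta, truth
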