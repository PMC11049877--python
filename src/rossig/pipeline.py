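"""End-to-end orchestration: simulate -> DEG -> signature -> score ->
evaluate -> null benchmark -> enrichment -> deconvolution.

One YAML (or dict) config drives every stage; all thresholds default to the
analysis' canonical values (fold change 1.5, FDR 0.05, signature size 37,
10,000 null draws). Randomness flows from a single master seed through a
per-stage sub-seed derived by hashing the stage name with the master seed,
so inserting or disabling one stage never reshuffles another stage's draws.
Every run ends with a manifest listing each produced file and its SHA-256
checksum; identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, deconv, deg, enrichment, evaluation, io, nullbench, scoring
from . import signature as sigmod
from . import simdata

__all__ = ["RunManifest", "PipelineError", "ConfigError", "run_pipeline",
           "stage_seed", "DEFAULT_CONFIG", "STAGES"]

log = logging.getLogger("rossig.pipeline")

STAGES = ["simulate", "deg", "signature", "score", "evaluate", "nullbench",
          "enrich", "deconv"]
_DEPS = {
    "simulate": [],
    "deg": ["simulate"],
    "signature": ["deg"],
    "score": ["signature"],
    "evaluate": ["score"],
    "nullbench": ["signature"],
    "enrich": ["deg"],
    "deconv": ["score"],
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},  # SimConfig field overrides
    "deg": {"fc_threshold": 1.5, "fdr": 0.05},
    "score": {},
    "nullbench": {"n_draws": 10_000, "size": 37},
    "enrich": {"n_random_sets": 20, "set_size_range": [20, 80],
               "n_permutations": 200},
    "deconv": {"n_cell_types": 6, "n_genes": 60},
}


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_outputs: list[dict] = field(default_factory=list)
    versions: str = f"rossig {__version__}"

    def add(self, stage: str, path: Path, out_dir: Path) -> None:
        self.stage_outputs.append(
            {
                "stage": stage,
                "path": str(path.relative_to(out_dir)),
                "checksum": io.file_checksum(path),
            }
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def stage_seed(master_seed: int, stage: str) -> int:
    """Sub-seed for one stage: stage name hashed with the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _resolve_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text("utf-8")) or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a YAML file path")
    resolved = {k: (dict(v) if isinstance(v, dict) else v)
                for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if key not in resolved:
            raise ConfigError(f"unknown config section: {key!r}")
        if isinstance(resolved[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            resolved[key].update(value)
        else:
            resolved[key] = value
    unknown = set(resolved["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    enabled = [s for s in STAGES if s in resolved["stages"]]
    for stage in enabled:
        missing = [d for d in _DEPS[stage] if d not in enabled]
        if missing:
            raise ConfigError(
                f"stage {stage!r} enabled but upstream {missing} disabled"
            )
    resolved["stages"] = enabled
    return resolved


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Run the enabled stages in dependency order and write a manifest.

    ``seed`` overrides the config's master seed. Any stage failure aborts
    the run with the failing stage named; the manifest is written last.
    """
    cfg = _resolve_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, seed=cfg["seed"])
    ctx: dict = {}

    for stage in cfg["stages"]:
        log.info("stage %s: start", stage)
        try:
            _RUNNERS[stage](cfg, ctx, out_dir, manifest)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done", stage)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    return manifest


# --- stage runners ---------------------------------------------------------


def _run_simulate(cfg, ctx, out_dir, manifest):
    sim_cfg = simdata.SimConfig(
        **{**cfg["simulate"], "seed": stage_seed(cfg["seed"], "simulate")}
    )
    expr_disc, expr_val, meta, truth = simdata.simulate_cohorts(sim_cfg)
    paths = simdata.write_fixture_bundle(expr_disc, expr_val, meta, truth, out_dir)
    for path in paths.values():
        manifest.add("simulate", path, out_dir)
    ctx.update(expr_disc=expr_disc, expr_val=expr_val, meta=meta, truth=truth,
               ros_list=truth.ros_list)


def _run_deg(cfg, ctx, out_dir, manifest):
    meta_disc = ctx["meta"][ctx["meta"]["cohort"] == "discovery"]
    table = deg.compute_deg(ctx["expr_disc"], meta_disc)
    filtered = deg.filter_deg(table, cfg["deg"]["fc_threshold"], cfg["deg"]["fdr"])
    for name, frame in [("deg_discovery.tsv", table), ("deg_filtered.tsv", filtered)]:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest.add("deg", path, out_dir)
    ctx.update(deg_table=table, deg_filtered=filtered)


def _run_signature(cfg, ctx, out_dir, manifest):
    sig = sigmod.build_signature(
        ctx["deg_filtered"], ctx["ros_list"],
        {"deg": "deg_filtered.tsv", "gene_list": "ros_list.txt"},
    )
    path = sigmod.write_signature(sig, out_dir / "signature.tsv")
    manifest.add("signature", path, out_dir)
    ctx["signature"] = sig


def _run_score(cfg, ctx, out_dir, manifest):
    for cohort, expr in [("discovery", ctx["expr_disc"]),
                         ("validation", ctx["expr_val"])]:
        result = scoring.survival_score(expr, ctx["signature"])
        groups = scoring.stratify_by_mean(result)
        table = pd.DataFrame(
            {"sample_id": result.scores.index, "score": result.scores.to_numpy(),
             "group": groups.assignment.to_numpy()}
        )
        path = out_dir / f"scores_{cohort}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest.add("score", path, out_dir)
        path = out_dir / f"score_params_{cohort}.tsv"
        result.gene_params.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest.add("score", path, out_dir)
        ctx[f"scores_{cohort}"] = result
        ctx[f"groups_{cohort}"] = groups


def _run_evaluate(cfg, ctx, out_dir, manifest):
    rows = []
    for cohort, expr in [("discovery", ctx["expr_disc"]),
                         ("validation", ctx["expr_val"])]:
        result = ctx[f"scores_{cohort}"]
        outcomes = io.outcome_mask(ctx["meta"], list(result.scores.index))
        roc = evaluation.roc_auc(result.scores, outcomes)
        p = evaluation.group_difference_test(result.scores, outcomes.to_numpy())
        pca = evaluation.pca_signature(expr, ctx["signature"], k=2)
        rows.append(
            {"cohort": cohort, "auc": roc.auc, "p_value": p,
             "pc1_fraction": pca.explained_variance_fraction[0],
             "pc2_fraction": pca.explained_variance_fraction[1]}
        )
        path = out_dir / f"roc_{cohort}.tsv"
        pd.DataFrame(roc.curve_points, columns=["fpr", "tpr"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")
        manifest.add("evaluate", path, out_dir)
        path = out_dir / f"pca_{cohort}.tsv"
        pca.coordinates.to_csv(path, sep="\t", index_label="sample_id",
                               float_format="%.10g")
        manifest.add("evaluate", path, out_dir)
    path = out_dir / "evaluation.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.add("evaluate", path, out_dir)


def _run_nullbench(cfg, ctx, out_dir, manifest):
    seed = stage_seed(cfg["seed"], "nullbench")
    whole = list(ctx["expr_disc"].index.astype(str))
    survival = ctx["deg_filtered"]["gene_id"].tolist()
    pools = [("whole_genome", whole)]
    if len(survival) >= cfg["nullbench"]["size"]:
        pools.append(("survival_related", survival))
    summary = {}
    for label, pool in pools:
        null = nullbench.null_distribution(
            ctx["expr_disc"], ctx["expr_val"], ctx["meta"], pool,
            ctx["deg_table"], ctx["signature"],
            size=cfg["nullbench"]["size"], n_draws=cfg["nullbench"]["n_draws"],
            seed=seed, pool_label=label,
        )
        path = out_dir / f"null_{label}.tsv"
        null.draws.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest.add("nullbench", path, out_dir)
        summary[label] = {
            "observed_sum": null.observed_sum,
            "auc_discovery": null.observed_auc_discovery,
            "auc_validation": null.observed_auc_validation,
            "percentile": null.percentile,
            "n_draws": null.n_draws,
            "seed": seed,
        }
        ctx[f"null_{label}"] = null
    path = out_dir / "null_summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
    manifest.add("nullbench", path, out_dir)


def _run_enrich(cfg, ctx, out_dir, manifest):
    rng = np.random.default_rng(stage_seed(cfg["seed"], "enrich"))
    universe = list(ctx["expr_disc"].index.astype(str))
    lo, hi = cfg["enrich"]["set_size_range"]
    sets = [enrichment.GeneSet(
        "ROS_CURATED", "curated free-radical list",
        tuple(g for g in ctx["ros_list"] if g in set(universe)),
    )]
    for i in range(cfg["enrich"]["n_random_sets"]):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(enrichment.GeneSet(f"RANDOM_{i + 1:03d}", "random set",
                                       tuple(members)))
    collection = enrichment.GeneSetCollection(sets)
    path = enrichment.write_gmt(collection, out_dir / "gene_sets.gmt")
    manifest.add("enrich", path, out_dir)

    ora = enrichment.ora_hypergeometric(
        ctx["deg_filtered"]["gene_id"].tolist(), collection, universe
    )
    path = out_dir / "ora.tsv"
    ora.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.add("enrich", path, out_dir)

    ranking = (
        ctx["deg_table"][~ctx["deg_table"]["degenerate_flag"].astype(bool)]
        .sort_values("t_stat", ascending=False, kind="mergesort")
        .rename(columns={"t_stat": "weight"})[["gene_id", "weight"]]
        .reset_index(drop=True)
    )
    rows = []
    nes_seed = stage_seed(cfg["seed"], "enrich-nes")
    for gene_set in collection:
        res = enrichment.gsea_nes(
            ranking, gene_set,
            n_permutations=cfg["enrich"]["n_permutations"], seed=nes_seed,
        )
        rows.append({"set_name": gene_set.name, "es": res.es, "nes": res.nes,
                     "p_value": res.p_value, "unstable": res.unstable})
    path = out_dir / "gsea.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.add("enrich", path, out_dir)


def _run_deconv(cfg, ctx, out_dir, manifest):
    rng = np.random.default_rng(stage_seed(cfg["seed"], "deconv"))
    n_genes = cfg["deconv"]["n_genes"]
    gene_ids = rng.choice(ctx["expr_disc"].index.to_numpy(), size=n_genes,
                          replace=False).tolist()
    ref = deconv.synthetic_reference(
        n_cell_types=cfg["deconv"]["n_cell_types"], n_genes=n_genes,
        gene_ids=gene_ids, seed=stage_seed(cfg["seed"], "deconv-ref"),
    )
    path = deconv.write_reference(ref, out_dir / "deconv_reference.tsv")
    manifest.add("deconv", path, out_dir)

    result = deconv.deconvolve(ctx["expr_disc"], ref)
    path = out_dir / "fractions_discovery.tsv"
    result.fractions.to_csv(path, sep="\t", index_label="sample_id",
                            float_format="%.10g")
    manifest.add("deconv", path, out_dir)

    comparison = deconv.compare_fractions(result, ctx["groups_discovery"])
    path = out_dir / "fraction_comparison.tsv"
    comparison.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.add("deconv", path, out_dir)


_RUNNERS = {
    "simulate": _run_simulate,
    "deg": _run_deg,
    "signature": _run_signature,
    "score": _run_score,
    "evaluate": _run_evaluate,
    "nullbench": _run_nullbench,
    "enrich": _run_enrich,
    "deconv": _run_deconv,
}
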