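"""Random-signature draws and the summed-AUC null distribution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rossig.evaluation import rank_auc
from rossig.io import outcome_mask
from rossig.nullbench import null_distribution, random_signature
from rossig.signature import GeneSignature


def _deg_table(fcs):
    return pd.DataFrame(
        [{"gene_id": g, "log2fc": fc} for g, fc in fcs.items()]
    )


def test_exhaustive_pool_gives_unique_signature():
    table = _deg_table({f"g{i}": 0.5 + i for i in range(37)})
    sig = random_signature(table["gene_id"].tolist(), 37, table,
                           np.random.default_rng(0))
    assert sorted(sig.genes) == sorted(table["gene_id"])
    assert (sig.entries["weight"] == 1).all()


def test_seed_contract():
    table = _deg_table({f"g{i}": (-1) ** i * (0.2 + i) for i in range(20)})
    pool = table["gene_id"].tolist()
    a = random_signature(pool, 5, table, np.random.default_rng(42))
    b = random_signature(pool, 5, table, np.random.default_rng(42))
    assert a.genes == b.genes
    rng = np.random.default_rng(42)
    first = random_signature(pool, 5, table, rng)
    second = random_signature(pool, 5, table, rng)
    assert first.genes == a.genes
    assert first.genes != second.genes


def test_weights_follow_discovery_sign():
    table = _deg_table({"up": 0.9, "down": -0.4, "alsoup": 0.1})
    sig = random_signature(["up", "down", "alsoup"], 3, table,
                           np.random.default_rng(1))
    w = sig.weights
    assert w["up"] == 1 and w["alsoup"] == 1 and w["down"] == -1


def test_zero_fc_genes_excluded_and_pool_size_checked():
    table = _deg_table({"a": 0.5, "b": 0.0, "c": -0.2})
    sig = random_signature(["a", "b", "c"], 2, table, np.random.default_rng(0))
    assert "b" not in sig.genes
    with pytest.raises(ValueError):
        random_signature(["a", "b", "c"], 3, table, np.random.default_rng(0))
    with pytest.raises(ValueError):
        random_signature(["a", "missing"], 1, table, np.random.default_rng(0))


def test_subset_sampling_is_uniform():
    """Over C(3,2)=3 possible subsets, 3000 draws split uniformly."""
    table = _deg_table({"a": 0.5, "b": 0.7, "c": -0.2})
    rng = np.random.default_rng(8)
    counts = {}
    for _ in range(3000):
        sig = random_signature(["a", "b", "c"], 2, table, rng)
        counts[tuple(sorted(sig.genes))] = counts.get(tuple(sorted(sig.genes)), 0) + 1
    assert len(counts) == 3
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 0.001


def _tiny_world():
    from rossig.simdata import SimConfig, simulate_cohorts

    cfg = SimConfig(n_genes=40, n_samples_discovery=30, n_samples_validation=20,
                    n_planted=10, ros_list_size=8, ros_overlap_with_planted=4,
                    effect_log2fc=1.5, seed=21)
    return simulate_cohorts(cfg)


def _observed_from(table, genes):
    fc = table.set_index("gene_id")["log2fc"]
    return GeneSignature(
        pd.DataFrame({"gene_id": genes, "log2fc": fc.loc[genes].to_numpy(),
                      "weight": np.sign(fc.loc[genes]).astype(int).to_numpy()})
    )


def test_null_distribution_determinism_and_bounds():
    from rossig.deg import compute_deg

    expr_disc, expr_val, meta, truth = _tiny_world()
    table = compute_deg(expr_disc, meta[meta["cohort"] == "discovery"])
    pool = list(expr_disc.index)
    observed = _observed_from(table, truth.planted_genes[:5])
    runs = [
        null_distribution(expr_disc, expr_val, meta, pool, table, observed,
                          size=5, n_draws=200, seed=9)
        for _ in range(2)
    ]
    pd.testing.assert_frame_equal(runs[0].draws, runs[1].draws)
    sums = runs[0].sums
    assert np.all((sums >= 0) & (sums <= 2))
    assert 0 <= runs[0].percentile <= 100


def test_observed_sum_matches_direct_scoring():
    """The observed signature's summed AUC equals an independent
    standardize-score-rank computation."""
    from rossig.deg import compute_deg

    expr_disc, expr_val, meta, truth = _tiny_world()
    table = compute_deg(expr_disc, meta[meta["cohort"] == "discovery"])
    observed = _observed_from(table, truth.planted_genes[:5])
    null = null_distribution(expr_disc, expr_val, meta, list(expr_disc.index),
                             table, observed, size=5, n_draws=10, seed=0)

    expected = 0.0
    for expr in (expr_disc, expr_val):
        sub = expr.loc[observed.genes].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1,
                                                              keepdims=True)
        scores = observed.weights.to_numpy() @ z
        positive = outcome_mask(meta, list(expr.columns)).to_numpy()
        expected += rank_auc(scores, positive)
    assert null.observed_sum == pytest.approx(expected, abs=1e-12)


def test_exhaustive_percentile_matches_brute_force_rank():
    """Enumerating all C(5,2) subsets reproduces the observed draw's exact
    strictly-below rank."""
    from rossig.deg import compute_deg

    expr_disc, expr_val, meta, truth = _tiny_world()
    table = compute_deg(expr_disc, meta[meta["cohort"] == "discovery"])
    pool = list(expr_disc.index[:5])
    observed = _observed_from(table, [pool[0], pool[3]])

    null = null_distribution(expr_disc, expr_val, meta, pool, table, observed,
                             size=2, exhaustive=True)
    assert null.n_draws == 10  # C(5,2)

    fc = table.set_index("gene_id")["log2fc"]
    sums = []
    for genes in itertools.combinations(sorted(pool), 2):
        total = 0.0
        for expr in (expr_disc, expr_val):
            sub = expr.loc[list(genes)].to_numpy()
            z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(
                axis=1, ddof=1, keepdims=True)
            w = np.sign(fc.loc[list(genes)].to_numpy())
            positive = outcome_mask(meta, list(expr.columns)).to_numpy()
            total += rank_auc(w @ z, positive)
        sums.append(total)
    expected_percentile = 100 * sum(s < null.observed_sum for s in sums) / len(sums)
    assert null.percentile == pytest.approx(expected_percentile, abs=1e-12)
    # the observed subset is itself one of the enumerated draws
    assert any(abs(s - null.observed_sum) < 1e-12 for s in sums)


def test_effect_monotonicity_of_percentile():
    """A stronger planted effect never worsens the planted signature's
    median percentile (small effect grid, stochastic)."""
    from rossig.deg import compute_deg
    from rossig.simdata import SimConfig, simulate_cohorts

    medians = []
    for effect in (0.3, 1.5):
        percentiles = []
        for seed in range(3):
            cfg = SimConfig(n_genes=60, n_samples_discovery=30,
                            n_samples_validation=20, n_planted=8,
                            ros_list_size=8, ros_overlap_with_planted=4,
                            effect_log2fc=effect, seed=30 + seed)
            expr_disc, expr_val, meta, truth = simulate_cohorts(cfg)
            table = compute_deg(expr_disc, meta[meta["cohort"] == "discovery"])
            observed = _observed_from(table, truth.planted_genes)
            null = null_distribution(expr_disc, expr_val, meta,
                                     list(expr_disc.index), table, observed,
                                     size=8, n_draws=150, seed=seed)
            percentiles.append(null.percentile)
        medians.append(np.median(percentiles))
    assert medians[1] >= medians[0]
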