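"""ROC/AUC rank statistic, rank-sum group test, and signature-space PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rossig.evaluation import (
    group_difference_test,
    pca_signature,
    roc_auc,
)
from rossig.signature import GeneSignature


def brute_force_auc(scores, positive):
    """Pair counting: concordant pairs + half credit for ties."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_separation():
    res = roc_auc([2.0, 3.0, 0.0, 1.0], ["survivor", "survivor",
                                         "nonsurvivor", "nonsurvivor"])
    assert res.auc == 1.0
    assert res.n_pos == 2 and res.n_neg == 2


def test_auc_all_ties_is_half():
    res = roc_auc([1.0] * 6, [True, True, True, False, False, False])
    assert res.auc == 0.5


def test_auc_pair_counting_example():
    # survivors [3, 1] vs non-survivors [2, 0]: 3 of 4 pairs concordant
    res = roc_auc([3.0, 1.0, 2.0, 0.0], [True, True, False, False])
    assert res.auc == 0.75


def test_auc_matches_brute_force_on_small_instances():
    rng = np.random.default_rng(4)
    for n in range(2, 9):
        for n_pos in range(1, n):
            for _ in range(10):
                scores = rng.integers(0, 4, size=n).astype(float)
                positive = np.zeros(n, dtype=bool)
                positive[rng.choice(n, n_pos, replace=False)] = True
                res = roc_auc(scores, positive)
                assert res.auc == pytest.approx(
                    brute_force_auc(scores, positive), abs=1e-12)


def test_trapezoid_equals_rank_auc():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        positive = rng.random(n) < 0.5
        if positive.all() or not positive.any():
            continue
        res = roc_auc(scores, positive)
        trap = np.trapezoid(res.curve_points[:, 1], res.curve_points[:, 0])
        assert abs(trap - res.auc) < 1e-10


def test_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=30)
    positive = rng.random(30) < 0.4
    res = roc_auc(scores, positive)
    assert tuple(res.curve_points[0]) == (0.0, 0.0)
    assert tuple(res.curve_points[-1]) == (1.0, 1.0)
    assert np.all(np.diff(res.curve_points[:, 0]) >= 0)
    assert np.all(np.diff(res.curve_points[:, 1]) >= 0)


def test_auc_complement_under_negation():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=25)  # tie-free almost surely
    positive = rng.random(25) < 0.5
    a = roc_auc(scores, positive).auc
    b = roc_auc(-scores, positive).auc
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [True, True])


def test_ranksum_identical_multisets():
    p = group_difference_test([1.0, 2.0, 1.0, 2.0], [0, 0, 1, 1])
    assert p == 1.0


def test_ranksum_exact_hand_case():
    # A [3,4] vs B [1,2]: extreme split, exact two-sided p = 2/C(4,2) = 1/3
    p = group_difference_test([3.0, 4.0, 1.0, 2.0], ["a", "a", "b", "b"])
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_ranksum_exact_enumeration_oracle():
    """Exact p equals the enumeration of all label assignments."""
    scores = np.array([0.3, 1.9, 0.7, 2.5, 1.1, 0.2])
    labels = np.array([0, 0, 0, 1, 1, 1])

    def statistic(lab):
        ranks = _ranks(scores)
        return ranks[lab == 1].sum()

    obs = statistic(labels)
    n = len(scores)
    mean = labels.sum() * (n + 1) / 2
    count = total = 0
    for pos in itertools.combinations(range(n), int(labels.sum())):
        lab = np.zeros(n, dtype=int)
        lab[list(pos)] = 1
        total += 1
        if abs(statistic(lab) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    p_oracle = count / total
    p = group_difference_test(scores, labels)
    assert p == pytest.approx(p_oracle, abs=1e-12)


def _ranks(x):
    from scipy.stats import rankdata

    return rankdata(x)


def test_ranksum_label_permutation_invariance():
    scores = [5.0, 1.0, 3.0, 2.0, 4.0, 0.5]
    labels = [1, 0, 1, 0, 1, 0]
    p1 = group_difference_test(scores, labels)
    order = [3, 0, 5, 2, 1, 4]
    p2 = group_difference_test([scores[i] for i in order],
                               [labels[i] for i in order])
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_ranksum_empty_group_rejected():
    with pytest.raises(ValueError):
        group_difference_test([1.0, 2.0], [0, 0])


def _sig(genes):
    return GeneSignature(
        pd.DataFrame(
            [{"gene_id": g, "log2fc": 1.0, "weight": 1} for g in genes]
        )
    )


def test_pca_rank_one_data():
    pattern = np.array([1.0, 2.0, 3.0, 4.0])
    expr = pd.DataFrame(
        [1.0 * pattern, 2.0 * pattern, -0.5 * pattern],
        index=pd.Index(["a", "b", "c"], name="gene_id"),
        columns=[f"s{i}" for i in range(4)],
    )
    res = pca_signature(expr, _sig(["a", "b", "c"]), k=2)
    assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_two_orthogonal_equal_variance_patterns():
    u = np.array([1.0, 1.0, -1.0, -1.0])
    v = np.array([1.0, -1.0, 1.0, -1.0])
    expr = pd.DataFrame(
        [u, u, v, v],
        index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
        columns=[f"s{i}" for i in range(4)],
    )
    res = pca_signature(expr, _sig(["a", "b", "c", "d"]), k=2)
    np.testing.assert_allclose(res.explained_variance_fraction, [0.5, 0.5],
                               atol=1e-12)


def test_pca_fractions_non_increasing(small_world):
    expr_disc, _, _, truth = small_world
    res = pca_signature(expr_disc, _sig(truth.planted_genes[:10]), k=5)
    frac = res.explained_variance_fraction
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1 + 1e-9
    assert res.coordinates.shape == (expr_disc.shape[1], 5)


def test_pca_input_validation(small_world):
    expr_disc, _, _, truth = small_world
    with pytest.raises(ValueError):
        pca_signature(expr_disc, _sig(truth.planted_genes[:1]))
    with pytest.raises(ValueError):
        pca_signature(expr_disc, _sig(truth.planted_genes[:3]), k=4)
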