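"""GMT parsing, hypergeometric ORA, and the GSEA running score / NES."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from rossig.enrichment import (
    GeneSet,
    GeneSetCollection,
    GmtFormatError,
    gsea_nes,
    gsea_running_score,
    ora_hypergeometric,
    read_gmt,
    write_gmt,
)


def test_read_gmt_basic(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tA\tB\n\nS2\tother\tC\tD\tE\n")
    coll = read_gmt(path)
    assert [s.name for s in coll] == ["S1", "S2"]
    assert coll.sets[0].members == ("A", "B")


def test_read_gmt_errors_and_dedup(tmp_path):
    short = tmp_path / "short.gmt"
    short.write_text("S1\tdesc\n")
    with pytest.raises(GmtFormatError, match="line 1"):
        read_gmt(short)
    dup_name = tmp_path / "dup.gmt"
    dup_name.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
    with pytest.raises(GmtFormatError, match="duplicate"):
        read_gmt(dup_name)
    dup_member = tmp_path / "dupm.gmt"
    dup_member.write_text("S1\td\tA\tA\tB\n")
    with pytest.warns(UserWarning):
        coll = read_gmt(dup_member)
    assert coll.sets[0].members == ("A", "B")


def test_gmt_round_trip(tmp_path):
    coll = GeneSetCollection(
        [GeneSet("S1", "a", ("X", "Y")), GeneSet("S2", "b", ("Z",)),
         GeneSet("S3", "c", ("P", "Q", "R"))]
    )
    path = write_gmt(coll, tmp_path / "rt.gmt")
    back = read_gmt(path)
    assert back.sets == coll.sets


def test_ora_exact_tail():
    """Universe 20, set 5, query 5, full overlap: p = 1/C(20,5)."""
    universe = [f"g{i}" for i in range(20)]
    coll = GeneSetCollection([GeneSet("S", "", tuple(universe[:5]))])
    res = ora_hypergeometric(universe[:5], coll, universe)
    assert res.loc[0, "overlap"] == 5
    assert res.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5), rel=1e-9)


def test_ora_zero_overlap_and_saturation():
    universe = [f"g{i}" for i in range(20)]
    coll = GeneSetCollection([GeneSet("S", "", tuple(universe[:5]))])
    res = ora_hypergeometric(universe[10:15], coll, universe)
    assert res.loc[0, "overlap"] == 0
    assert res.loc[0, "p_value"] == pytest.approx(1.0)
    res = ora_hypergeometric(universe, coll, universe)
    assert res.loc[0, "p_value"] == pytest.approx(1.0)


def test_ora_rejects_query_outside_universe():
    coll = GeneSetCollection([GeneSet("S", "", ("a",))])
    with pytest.raises(ValueError, match="stray"):
        ora_hypergeometric(["a", "stray"], coll, ["a", "b"])


def test_ora_bh_shared_with_deg_module():
    from rossig.deg import bh_adjust

    universe = [f"g{i}" for i in range(30)]
    coll = GeneSetCollection(
        [GeneSet(f"S{k}", "", tuple(universe[k: k + 6])) for k in range(5)]
    )
    res = ora_hypergeometric(universe[:6], coll, universe)
    np.testing.assert_allclose(res["q_value"], bh_adjust(res["p_value"]),
                               rtol=1e-15)


def _ranking(weights):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(weights))], "weight": weights}
    )


def test_running_score_top_hit():
    """N=4, weights [4,3,2,1], set = top gene: profile peaks at +1."""
    es, profile = gsea_running_score(_ranking([4.0, 3.0, 2.0, 1.0]), {"g0"})
    assert es == pytest.approx(1.0)
    np.testing.assert_allclose(profile, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)


def test_running_score_bottom_hit_negative():
    es, profile = gsea_running_score(_ranking([4.0, 3.0, 2.0, 0.01]), {"g3"})
    assert es == pytest.approx(-1.0)
    assert profile[-1] == pytest.approx(0.0, abs=1e-12)


def test_running_profile_telescopes_to_zero_and_is_bounded():
    rng = np.random.default_rng(10)
    for _ in range(20):
        n = int(rng.integers(5, 30))
        weights = rng.normal(size=n)
        k = int(rng.integers(1, n))
        members = {f"g{i}" for i in rng.choice(n, size=k, replace=False)}
        _, profile = gsea_running_score(_ranking(weights), members)
        assert profile[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.abs(profile) <= 1 + 1e-9)


def test_running_score_reversal_symmetry():
    """Reversing a symmetric ranking mirrors the profile (6-gene instance,
    checked against direct recomputation)."""
    weights = [3.0, 2.0, 1.0, 1.0, 2.0, 3.0]
    members = {"g1", "g4"}  # symmetric placement
    _, profile = gsea_running_score(_ranking(weights), members)
    rev = _ranking(weights[::-1])
    rev["gene_id"] = [f"g{5 - i}" for i in range(6)]
    _, profile_rev = gsea_running_score(rev, members)
    np.testing.assert_allclose(profile_rev[:-1], -profile[-2::-1], atol=1e-12)


def test_running_score_rejects_degenerate_sets():
    with pytest.raises(ValueError):
        gsea_running_score(_ranking([1.0, 2.0]), {"g0", "g1"})
    with pytest.raises(ValueError):
        gsea_running_score(_ranking([1.0, 2.0]), {"absent"})


def test_nes_seed_contract():
    ranking = _ranking([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
    a = gsea_nes(ranking, {"g0", "g1"}, n_permutations=50, seed=3)
    b = gsea_nes(ranking, {"g0", "g1"}, n_permutations=50, seed=3)
    assert a.nes == b.nes and a.p_value == b.p_value


def test_nes_exhaustive_matches_brute_force():
    """Exhaustive NES/p over all C(6,2) placements equals a test-side
    enumeration oracle."""
    weights = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5]
    ranking = _ranking(weights)
    res = gsea_nes(ranking, {"g0", "g1"}, exhaustive=True)

    def es_of(members):
        es, _ = gsea_running_score(ranking, members)
        return es

    null = [es_of({f"g{i}", f"g{j}"})
            for i, j in itertools.combinations(range(6), 2)]
    observed = es_of({"g0", "g1"})
    same_sign = [e for e in null if np.sign(e) == np.sign(observed)]
    p_oracle = sum(abs(e) >= abs(observed) for e in same_sign) / len(same_sign)
    nes_oracle = observed / np.mean(np.abs(same_sign))
    assert res.es == pytest.approx(observed, abs=1e-12)
    assert res.nes == pytest.approx(nes_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.n_same_sign == len(same_sign)


def test_nes_null_calibration():
    """Random sets give |NES| centered near 1 over replicates."""
    rng = np.random.default_rng(12)
    weights = np.sort(rng.normal(size=40))[::-1]
    nes_values = []
    for rep in range(20):
        members = {f"g{i}" for i in rng.choice(40, size=5, replace=False)}
        res = gsea_nes(_ranking(weights), members, n_permutations=100, seed=rep)
        nes_values.append(abs(res.nes))
    assert 0.6 < np.mean(nes_values) < 1.6
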