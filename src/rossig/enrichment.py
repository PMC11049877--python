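"""Gene-set analysis: hypergeometric over-representation and GSEA.

Two complementary modes. Over-representation (ORA) asks whether a discrete
query gene list overlaps a gene set more than chance within a stated
universe, via the upper-tail hypergeometric probability with
Benjamini-Hochberg adjustment across sets. GSEA asks whether a set
concentrates at either end of a continuously ranked gene list, via the
classical weighted Kolmogorov-Smirnov running sum: walking the ranking,
set hits increment the sum by |weight|^exponent (normalized over set
hits) and misses decrement it by 1/(N - N_hits); the enrichment score (ES)
is the signed maximum deviation, and the normalized score (NES) divides by
the mean same-sign |ES| under gene-label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtFormatError",
    "read_gmt",
    "write_gmt",
    "ora_hypergeometric",
    "gsea_running_score",
    "gsea_nes",
]


class GmtFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GmtFormatError(f"duplicate set names: {dup[:5]}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtFormatError(f"line {lineno}: expected >= 3 tab-separated fields")
        name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(members):
            warnings.warn(
                f"set {name!r}: dropped {len(members) - len(deduped)} duplicate members",
                stacklevel=2,
            )
        sets.append(GeneSet(name, desc, tuple(deduped)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([s.name, s.description, *s.members]) for s in collection
    ]
    path.write_text("".join(f"{line}\n" for line in lines), encoding="utf-8")
    return path


def ora_hypergeometric(
    query: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    Sets are intersected with the universe before testing; p is the
    probability of an overlap at least as large as observed, q is BH across
    sets. ``ease=True`` applies the conservative EASE variant that deducts
    one from the observed overlap before taking the tail.
    """
    uni = set(universe)
    offenders = sorted(set(query) - uni)
    if offenders:
        raise ValueError(f"query genes outside universe: {offenders[:5]}")
    q_set = set(query)
    m, n_query = len(uni), len(q_set)

    rows = []
    for gene_set in collection:
        members = set(gene_set.members) & uni
        overlap = len(members & q_set)
        observed = max(overlap - 1, 0) if ease else overlap
        p = float(stats.hypergeom.sf(observed - 1, m, len(members), n_query))
        rows.append(
            {
                "set_name": gene_set.name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": m,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"])
    else:
        result["q_value"] = []
    return result


def _running_profile(
    weights: np.ndarray, is_hit: np.ndarray, exponent: float
) -> np.ndarray:
    n, n_hits = is_hit.size, int(is_hit.sum())
    hit_w = np.abs(weights) ** exponent
    denom = hit_w[is_hit].sum()
    if denom == 0:
        raise ValueError("all set-hit weights are zero; running sum undefined")
    steps = np.where(is_hit, hit_w / denom, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def gsea_running_score(
    ranking: pd.DataFrame,
    gene_set,
    exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and running profile over a ranked gene list.

    ``ranking`` carries ``gene_id`` and ``weight`` columns ordered from most
    to least associated (e.g. by signed t-statistic); ``gene_set`` is a
    :class:`GeneSet` or iterable of members. The set must hit the ranking
    partially — a set covering all or none of it has no signal.
    """
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    genes = ranking["gene_id"].astype(str).to_numpy()
    if len(set(genes)) != len(genes):
        raise ValueError("ranking contains duplicate genes")
    weights = ranking["weight"].to_numpy(dtype=float)
    is_hit = np.isin(genes, list(members))
    n_hits = int(is_hit.sum())
    if n_hits == 0 or n_hits == len(genes):
        raise ValueError("gene set must overlap the ranking partially")
    profile = _running_profile(weights, is_hit, exponent)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


@dataclass
class NesResult:
    es: float
    nes: float
    p_value: float
    n_same_sign: int
    unstable: bool


def gsea_nes(
    ranking: pd.DataFrame,
    gene_set,
    exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> NesResult:
    """Gene-label permutation NES and empirical p-value for one set.

    The null keeps the ranking (hence the weight multiset) fixed and
    re-places the set's hit positions at random. NES divides the observed
    ES by the mean |null ES| of matching sign; p is the same-sign null tail
    fraction with the +1 pseudocount of an empirical permutation test.
    Fewer than 10 same-sign permutations flags the result unstable. With
    ``exhaustive=True`` all hit placements are enumerated (tiny rankings
    only).
    """
    es, _ = gsea_running_score(ranking, gene_set, exponent)
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    genes = ranking["gene_id"].astype(str).to_numpy()
    weights = ranking["weight"].to_numpy(dtype=float)
    n = genes.size
    n_hits = int(np.isin(genes, list(members)).sum())

    if exhaustive:
        if comb(n, n_hits) > 200_000:
            raise ValueError("exhaustive enumeration infeasible for this size")
        placements = combinations(range(n), n_hits)
    else:
        rng = np.random.default_rng(seed)
        placements = (
            rng.choice(n, size=n_hits, replace=False) for _ in range(n_permutations)
        )

    null_es = []
    for pos in placements:
        is_hit = np.zeros(n, dtype=bool)
        is_hit[list(pos)] = True
        profile = _running_profile(weights, is_hit, exponent)
        null_es.append(profile[np.argmax(np.abs(profile))])
    null_es = np.asarray(null_es)

    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    n_same = int(same_sign.size)
    unstable = n_same < 10
    if n_same == 0:
        nes = float("nan")
        p = 1.0 / (null_es.size + 1)
    else:
        nes = float(es / np.mean(np.abs(same_sign)))
        if exhaustive:
            p = float((np.abs(same_sign) >= abs(es)).sum()) / n_same
        else:
            p = (float((np.abs(same_sign) >= abs(es)).sum()) + 1.0) / (n_same + 1.0)
    return NesResult(es=es, nes=nes, p_value=min(p, 1.0), n_same_sign=n_same,
                     unstable=unstable)
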