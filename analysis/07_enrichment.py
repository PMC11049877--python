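"""Gene-set analysis of the survival DEGs.

Builds a demonstration gene-set collection (the curated ROS list plus
seeded random sets from the simulated universe), then runs hypergeometric
over-representation on the filtered DEG list and the GSEA running score
with permutation NES on the t-statistic ranking. With real KEGG/MSigDB
collections supply your own GMT via --gmt.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rossig.enrichment import (
    GeneSet,
    GeneSetCollection,
    gsea_nes,
    ora_hypergeometric,
    read_gmt,
    write_gmt,
)
from rossig.io import read_gene_list
from rossig.simdata import read_fixture_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--gmt", type=Path, default=None,
                        help="optional real gene-set collection")
    parser.add_argument("--perms", type=int, default=200)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    expr_disc, _, _, _ = read_fixture_bundle(args.results / "data")
    universe = list(expr_disc.index.astype(str))
    deg_table = pd.read_csv(args.results / "deg_discovery.tsv", sep="\t")
    filtered = pd.read_csv(args.results / "deg_filtered.tsv", sep="\t")
    ros = read_gene_list(args.results / "data" / "ros_list.txt")

    if args.gmt:
        collection = read_gmt(args.gmt)
    else:
        rng = np.random.default_rng(args.seed)
        sets = [GeneSet("ROS_CURATED", "curated free-radical list",
                        tuple(g for g in ros if g in set(universe)))]
        for i in range(10):
            size = int(rng.integers(20, 81))
            sets.append(GeneSet(f"RANDOM_{i + 1:03d}", "random set",
                                tuple(rng.choice(universe, size, replace=False))))
        collection = GeneSetCollection(sets)
        write_gmt(collection, args.results / "gene_sets.gmt")

    ora = ora_hypergeometric(filtered["gene_id"].tolist(), collection, universe)
    ora.to_csv(args.results / "ora.tsv", sep="\t", index=False,
               float_format="%.10g")
    top = ora.sort_values("p_value").iloc[0]
    print(f"ORA: top set {top['set_name']} overlap {top['overlap']}/"
          f"{top['set_size']} (q = {top['q_value']:.3g})")

    ranking = (
        deg_table[~deg_table["degenerate_flag"].astype(bool)]
        .sort_values("t_stat", ascending=False, kind="mergesort")
        .rename(columns={"t_stat": "weight"})[["gene_id", "weight"]]
        .reset_index(drop=True)
    )
    rows = []
    for gene_set in collection:
        res = gsea_nes(ranking, gene_set, n_permutations=args.perms,
                       seed=args.seed)
        rows.append({"set_name": gene_set.name, "es": res.es, "nes": res.nes,
                     "p_value": res.p_value, "unstable": res.unstable})
    gsea = pd.DataFrame(rows)
    gsea.to_csv(args.results / "gsea.tsv", sep="\t", index=False,
                float_format="%.10g")
    best = gsea.reindex(gsea["nes"].abs().sort_values(ascending=False).index).iloc[0]
    print(f"GSEA: strongest set {best['set_name']} ES {best['es']:.3f}, "
          f"NES {best['nes']:.2f}, p {best['p_value']:.3g}")


if __name__ == "__main__":
    main()
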