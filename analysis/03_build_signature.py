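"""Intersect the filtered survival DEGs with the curated ROS gene list.

The intersection, weighted +1/-1 by fold-change direction, is the
free-radical-associated survival signature; written to results/signature.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rossig.io import read_gene_list
from rossig.signature import build_signature, write_signature


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    filtered = pd.read_csv(args.results / "deg_filtered.tsv", sep="\t")
    ros = read_gene_list(args.results / "data" / "ros_list.txt")
    sig = build_signature(filtered, ros,
                          {"deg": "deg_filtered.tsv", "gene_list": "ros_list.txt"})
    write_signature(sig, args.results / "signature.tsv")

    up = int((sig.entries["weight"] == 1).sum())
    print(f"signature of {sig.n} genes ({up} up-weighted, {sig.n - up} "
          f"down-weighted) from {len(filtered)} DEGs x {len(ros)} curated genes")


if __name__ == "__main__":
    main()
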