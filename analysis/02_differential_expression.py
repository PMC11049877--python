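"""Survivor vs non-survivor differential expression in the discovery cohort.

Welch t-test per gene with BH FDR; the significance filter keeps genes with
fold change above 1.5 and q below 0.05. Writes the full per-gene table and
the filtered list under results/.
"""

import argparse
from pathlib import Path

from rossig.deg import compute_deg, filter_deg
from rossig.simdata import read_fixture_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--fc", type=float, default=1.5)
    parser.add_argument("--fdr", type=float, default=0.05)
    args = parser.parse_args()

    expr_disc, _, meta, truth = read_fixture_bundle(args.results / "data")
    table = compute_deg(expr_disc, meta[meta["cohort"] == "discovery"])
    filtered = filter_deg(table, args.fc, args.fdr)

    table.to_csv(args.results / "deg_discovery.tsv", sep="\t", index=False,
                 float_format="%.10g")
    filtered.to_csv(args.results / "deg_filtered.tsv", sep="\t", index=False,
                    float_format="%.10g")

    planted = set(truth.planted_genes)
    hits = set(filtered["gene_id"])
    print(f"{len(filtered)} of {len(table)} genes pass |FC| > {args.fc}, "
          f"q < {args.fdr}")
    print(f"  {len(hits & planted)} of them are planted "
          f"(recall {len(hits & planted) / len(planted):.2f}, "
          f"precision {len(hits & planted) / max(len(hits), 1):.2f})")


if __name__ == "__main__":
    main()
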