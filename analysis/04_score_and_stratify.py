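"""Sepsis survival scores for both cohorts, split at the cohort mean.

Per-dataset standardization: each cohort's scores use its own per-gene
mean and standard deviation. Writes scores_{cohort}.tsv (sample, score,
high/low group) and the standardization parameters.
"""

import argparse
from pathlib import Path

import pandas as pd

from rossig.scoring import stratify_by_mean, survival_score
from rossig.signature import read_signature
from rossig.simdata import read_fixture_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    expr_disc, expr_val, meta, _ = read_fixture_bundle(args.results / "data")
    sig = read_signature(args.results / "signature.tsv")

    for cohort, expr in [("discovery", expr_disc), ("validation", expr_val)]:
        result = survival_score(expr, sig)
        groups = stratify_by_mean(result)
        pd.DataFrame(
            {"sample_id": result.scores.index,
             "score": result.scores.to_numpy(),
             "group": groups.assignment.to_numpy()}
        ).to_csv(args.results / f"scores_{cohort}.tsv", sep="\t", index=False,
                 float_format="%.10g")
        result.gene_params.to_csv(args.results / f"score_params_{cohort}.tsv",
                                  sep="\t", index=False, float_format="%.10g")
        print(f"{cohort}: {len(groups.high)} high-score / {len(groups.low)} "
              f"low-score samples (mean threshold {groups.threshold:.3f})")


if __name__ == "__main__":
    main()
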