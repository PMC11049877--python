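"""How well the score separates survivors from non-survivors.

ROC/AUC (survivor-positive), two-sided rank-sum test of scores between
outcomes, and a 2-component PCA of signature-gene expression per cohort.
"""

import argparse
from pathlib import Path

import pandas as pd

from rossig.evaluation import group_difference_test, pca_signature, roc_auc
from rossig.io import outcome_mask
from rossig.signature import read_signature
from rossig.simdata import read_fixture_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    expr_disc, expr_val, meta, _ = read_fixture_bundle(args.results / "data")
    sig = read_signature(args.results / "signature.tsv")

    rows = []
    for cohort, expr in [("discovery", expr_disc), ("validation", expr_val)]:
        scores = pd.read_csv(args.results / f"scores_{cohort}.tsv", sep="\t")
        positive = outcome_mask(meta, scores["sample_id"].tolist())
        roc = roc_auc(scores["score"], positive)
        p = group_difference_test(scores["score"], positive.to_numpy())
        pca = pca_signature(expr, sig, k=2)
        explained = 100 * pca.explained_variance_fraction.sum()
        rows.append({"cohort": cohort, "auc": roc.auc, "p_value": p,
                     "pc1_fraction": pca.explained_variance_fraction[0],
                     "pc2_fraction": pca.explained_variance_fraction[1]})
        pd.DataFrame(roc.curve_points, columns=["fpr", "tpr"]).to_csv(
            args.results / f"roc_{cohort}.tsv", sep="\t", index=False,
            float_format="%.10g")
        pca.coordinates.to_csv(args.results / f"pca_{cohort}.tsv", sep="\t",
                               index_label="sample_id", float_format="%.10g")
        print(f"{cohort}: AUC {roc.auc:.3f}, rank-sum p {p:.3g}, "
              f"PC1+PC2 explain {explained:.1f}% of signature-gene variance")

    pd.DataFrame(rows).to_csv(args.results / "evaluation.tsv", sep="\t",
                              index=False, float_format="%.10g")


if __name__ == "__main__":
    main()
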