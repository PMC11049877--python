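"""Simulate the two-cohort sepsis expression world used by every later step.

Writes the discovery (265 samples) and validation (106 samples) log2
expression matrices, sample outcomes, the 137-gene curated ROS-style list
and the ground-truth record under results/data/.
"""

import argparse
from pathlib import Path

from rossig.simdata import SimConfig, simulate_cohorts, write_fixture_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = SimConfig(seed=args.seed)
    expr_disc, expr_val, meta, truth = simulate_cohorts(cfg)
    paths = write_fixture_bundle(expr_disc, expr_val, meta, truth,
                                 args.results / "data")

    n_surv = (meta["outcome"] == "survivor").sum()
    print(f"simulated {cfg.n_genes} genes; discovery {expr_disc.shape[1]} + "
          f"validation {expr_val.shape[1]} samples "
          f"({n_surv} survivors overall)")
    print(f"planted {len(truth.planted_genes)} survival-associated genes; "
          f"ROS list of {len(truth.ros_list)} shares "
          f"{len(set(truth.planted_genes) & set(truth.ros_list))} of them")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
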