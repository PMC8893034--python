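#!/usr/bin/env python
"""Outcome classification trees: MRI-only and MRI + clinical features.

Grows and cost-complexity-prunes a Gini tree (depth <= 2, terminal nodes
>= 3 patients) on each feature set, reports the confusion matrix,
accuracy, per-class PPV/NPV/sensitivity/specificity, and the accuracy
stratified by stroke type (ischemic vs any hemorrhagic involvement).
"""

import argparse
from pathlib import Path

import pandas as pd

from lesionload import RunConfig, run_cart_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path,
                    default=Path("results/clinical/cohort_grouped.csv"))
    ap.add_argument("--overlap", type=Path,
                    default=Path("results/overlap/overlap_table.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cart"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort).merge(
        pd.read_csv(args.overlap).drop(columns=["hemisphere"]), on="patient_id"
    )
    cfg = RunConfig(seed=args.seed)
    for fs in ("mri_only", "mri_plus_clinical"):
        result = run_cart_stage(cohort, fs, cfg, output_dir=args.out)
        print(f"\n=== {fs} ===")
        print(result["tree_text"], end="")
        print(f"accuracy {result['accuracy_percent']:.1f}% "
              f"(depth {result['tree_depth']})")
        for name, s in result["accuracy_by_stroke_type"].items():
            print(f"  {name}: {s['n_correct']}/{s['n']} "
                  f"({s['accuracy_percent']:.0f}%)")
    print(f"\ntree JSON + metrics -> {args.out}")


if __name__ == "__main__":
    main()
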