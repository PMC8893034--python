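#!/usr/bin/env python
"""The statistical battery: correlations and group comparisons.

Runs Spearman correlations of each tract's lesion overlap (and the
whole-CST / non-M1 aggregates and lesion volume) against E-ARAT with
Bonferroni flagging at 0.05/6, Kruskal-Wallis tests across the three
outcome groups per metric with Dunn pairwise adjusted p-values, and the
stroke-type comparison on E-ARAT.
"""

import argparse
from pathlib import Path

import pandas as pd

from lesionload import RunConfig, run_stats_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path,
                    default=Path("results/clinical/cohort_grouped.csv"))
    ap.add_argument("--overlap", type=Path,
                    default=Path("results/overlap/overlap_table.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats_report.json"))
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort).merge(
        pd.read_csv(args.overlap).drop(columns=["hemisphere"]), on="patient_id"
    )
    report = run_stats_stage(cohort, RunConfig(), output_path=args.out)

    print(f"Bonferroni-adjusted correlation threshold: "
          f"{report['alpha_bonferroni_correlations']:.4f}")
    print("Spearman correlations with E-ARAT:")
    entries = {**report["tract_correlations_vs_earat"],
               **report["aggregate_correlations_vs_earat"]}
    for name, e in entries.items():
        star = " *" if e["significant_adjusted"] else ""
        print(f"  {name:16s} r_s({e['df']}) = {e['r']:+.3f}, p = {e['p']:.4g}{star}")
    lv = report["lesion_volume_correlation_vs_earat"]
    print(f"  lesion volume    r_s({lv['df']}) = {lv['r']:+.3f}, p = {lv['p']:.3g}")

    print("Kruskal-Wallis across outcome groups (whole-CST load):")
    kw = report["kruskal_wallis_by_outcome_group"]["cst_percent"]
    print(f"  H({kw['df']}) = {kw['H']:.2f}, p = {kw['p']:.4g}")
    for c in kw["pairwise"]:
        print(f"  {c['pair']:15s} median diff {c['median_difference']:+.2f}%, "
              f"p_adj = {c['p_adjusted']:.4g}")
    skw = report["stroke_type_kw_on_earat"]
    print(f"stroke type on E-ARAT: H({skw['df']}) = {skw['H']:.2f}, p = {skw['p']:.3g}")
    print(f"full report -> {args.out}")


if __name__ == "__main__":
    main()
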