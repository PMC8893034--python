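"""Config-driven end-to-end analysis stages.

Chains the imaging, overlap, clinical-score, statistics and CART modules
into the study's analysis flow: per-patient lesion-overlap scoring and a
cohort heat map; the correlation / Kruskal-Wallis battery against E-ARAT;
and the two CART variants (MRI-only features, MRI plus clinical). Every
JSON output records the configuration hash and seeds used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .cart import TreeConfig, classification_report, grow_tree, predict, prune
from .clinical import outcome_clusters
from .grids import HeatMap, LesionMask, heat_map, write_volume, VolumeGrid
from .overlap import cohort_overlap_table, patient_overlap_row
from .tracts import CST_REGIONS, TractAtlas

log = logging.getLogger("lesionload")

MRI_FEATURES = [f"{r}_percent" for r in CST_REGIONS] + [
    "cst_percent",
    "non_m1_percent",
    "lesion_volume_mm3",
]
CLINICAL_FEATURES = [
    "age",
    "acute_esafe",
    "ar_esafe",
    "stroke_ischemic",
    "stroke_hemorrhagic",
    "stroke_mixed",
    "prior_stroke",
    "white_matter_disease",
]


@dataclass
class RunConfig:
    """Paths and knobs for a pipeline run."""

    output_dir: str = "results"
    alpha: float = 0.05
    n_correlation_comparisons: int = 6  # Bonferroni divisor for per-tract tests
    tree: TreeConfig = field(default_factory=TreeConfig)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def run_overlap_stage(
    masks: Sequence[LesionMask],
    atlas: TractAtlas,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, HeatMap, list[str]]:
    """Per-patient overlap metrics plus the cohort heat map.

    Per-patient failures are logged and skipped (the run continues); the
    ids of failed patients are returned. When ``output_dir`` is given the
    table is written as CSV and the heat map as two NIfTI volumes
    (counts and percent).
    """
    config = config or RunConfig()
    rows, ok_masks, failures = [], [], []
    for m in masks:
        try:
            rows.append(patient_overlap_row(m, atlas))
            ok_masks.append(m)
            log.info(
                "patient %s: %d tracts affected", m.patient_id, rows[-1]["n_tracts_affected"]
            )
        except Exception as exc:  # noqa: BLE001 - per-patient isolation is the contract
            failures.append(m.patient_id)
            log.error("patient %s failed: %s", m.patient_id, exc)
    table = pd.DataFrame(rows)
    hmap = heat_map(ok_masks)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "overlap_table.csv", index=False)
        write_volume(hmap.grid, out / "heatmap_counts.nii.gz")
        pct = VolumeGrid(
            np.round(hmap.percent_grid).astype(np.int64),
            hmap.grid.voxel_size,
            hmap.grid.space_tag,
        )
        write_volume(pct, out / "heatmap_percent.nii.gz")
        (out / "overlap_meta.json").write_text(
            json.dumps({**_stamp(config), "n_patients": len(ok_masks),
                        "failed_patients": failures}, indent=1)
        )
    return table, hmap, failures


def _corr_entry(res: st.CorrelationResult, threshold: float) -> dict:
    return {
        "method": res.method,
        "r": res.coefficient,
        "n": res.n,
        "df": res.df,
        "p": res.p_two_tailed,
        "significant_adjusted": bool(res.p_two_tailed < threshold),
    }


def run_stats_stage(
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    output_path: str | Path | None = None,
) -> dict:
    """The correlation and group-comparison battery against E-ARAT.

    Needs columns: the six per-tract percents, ``cst_percent``,
    ``non_m1_percent``, ``lesion_volume_mm3``, ``earat``, ``group`` and
    ``stroke_type``. Reports Spearman correlations (per tract and
    aggregate, Bonferroni-flagged at alpha/6), Kruskal-Wallis across
    outcome groups per metric with Dunn pairwise adjusted p's, the
    lesion-volume correlation, and a stroke-type comparison on E-ARAT
    (ischemic vs any hemorrhagic involvement).
    """
    config = config or RunConfig()
    tract_cols = [f"{r}_percent" for r in CST_REGIONS]
    needed = tract_cols + [
        "cst_percent", "non_m1_percent", "lesion_volume_mm3",
        "earat", "group", "stroke_type",
    ]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")

    alpha_corr = st.bonferroni_alpha(config.alpha, config.n_correlation_comparisons)
    earat = cohort["earat"].to_numpy(dtype=float)

    correlations = {}
    for col in tract_cols:
        correlations[col] = _corr_entry(st.spearman(cohort[col], earat), alpha_corr)
    aggregates = {
        col: _corr_entry(st.spearman(cohort[col], earat), alpha_corr)
        for col in ("cst_percent", "non_m1_percent")
    }
    lesion_volume_corr = _corr_entry(
        st.spearman(cohort["lesion_volume_mm3"], earat), config.alpha
    )

    group_order = [g for g in ("Good", "Limited", "Poor") if g in set(cohort["group"])]
    kw = {}
    for col in tract_cols + ["cst_percent", "non_m1_percent", "lesion_volume_mm3"]:
        groups = [cohort.loc[cohort["group"] == g, col].to_numpy() for g in group_order]
        res = st.kruskal_wallis(groups)
        pairs = st.pairwise_posthoc(groups, labels=group_order)
        kw[col] = {
            "H": res.h,
            "df": res.df,
            "p": res.p,
            "group_sizes": list(res.group_sizes),
            "pairwise": [
                {
                    "pair": c.pair,
                    "median_difference": c.median_difference,
                    "z": c.z,
                    "p_adjusted": c.p_adjusted,
                }
                for c in pairs
            ],
        }

    is_hem = cohort["stroke_type"].isin(["hemorrhagic", "mixed"])
    stroke_groups = [earat[~is_hem.to_numpy()], earat[is_hem.to_numpy()]]
    if all(len(g) for g in stroke_groups):
        res = st.kruskal_wallis(stroke_groups)
        stroke_kw = {"H": res.h, "df": res.df, "p": res.p,
                     "group_sizes": list(res.group_sizes)}
    else:
        stroke_kw = {"note": "only one stroke-type stratum present"}

    report = {
        **_stamp(config),
        "alpha": config.alpha,
        "alpha_bonferroni_correlations": alpha_corr,
        "tract_correlations_vs_earat": correlations,
        "aggregate_correlations_vs_earat": aggregates,
        "lesion_volume_correlation_vs_earat": lesion_volume_corr,
        "kruskal_wallis_by_outcome_group": kw,
        "stroke_type_kw_on_earat": stroke_kw,
    }
    if output_path is not None:
        Path(output_path).parent.mkdir(parents=True, exist_ok=True)
        Path(output_path).write_text(json.dumps(report, indent=1))
    return report


def assign_outcome_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a ``group`` column from a 3-cluster partition of E-ARAT."""
    out = cohort.copy()
    groups = outcome_clusters(out["earat"].to_numpy(dtype=float))
    out["group"] = groups.labels
    return out


def _feature_table(cohort: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    if feature_set not in ("mri_only", "mri_plus_clinical"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    X = cohort.copy()
    for t in ("ischemic", "hemorrhagic", "mixed"):
        X[f"stroke_{t}"] = (X["stroke_type"] == t).astype(int)
    cols = list(MRI_FEATURES)
    if feature_set == "mri_plus_clinical":
        cols += [c for c in CLINICAL_FEATURES if c in X.columns]
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"cohort table lacks feature columns {missing}")
    return X[cols]


def run_cart_stage(
    cohort: pd.DataFrame,
    feature_set: str = "mri_only",
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Grow and prune the outcome-classification tree on one feature set.

    Emits the tree (JSON and indented text), the confusion matrix,
    accuracy, per-class PPV/NPV/sensitivity/specificity, and accuracy
    stratified by stroke type (ischemic vs any hemorrhagic involvement).
    """
    config = config or RunConfig()
    if cohort["group"].nunique() < 2:
        raise ValueError("single-class cohort: nothing for the tree to separate")
    X = _feature_table(cohort, feature_set)
    y = cohort["group"].to_numpy(dtype=object)
    tcfg = TreeConfig(
        max_depth=config.tree.max_depth,
        min_terminal_size=config.tree.min_terminal_size,
        pruning=config.tree.pruning,
        cv_folds=config.tree.cv_folds,
        seed=config.seed,
    )
    tree = prune(grow_tree(X, y, tcfg), X, y, tcfg)
    y_pred = predict(tree, X)
    class_order = [g for g in ("Good", "Limited", "Poor") if g in set(y) | set(y_pred)]
    rep = classification_report(y, y_pred, class_order=class_order)

    strata = {}
    is_hem = cohort["stroke_type"].isin(["hemorrhagic", "mixed"]).to_numpy()
    for name, sel in (("ischemic", ~is_hem), ("any_hemorrhagic", is_hem)):
        if sel.any():
            correct = int((y[sel] == y_pred[sel]).sum())
            strata[name] = {
                "n": int(sel.sum()),
                "n_correct": correct,
                "accuracy_percent": 100.0 * correct / int(sel.sum()),
            }

    result = {
        **_stamp(config),
        "feature_set": feature_set,
        "tree": tree.to_dict(),
        "tree_text": tree.render(),
        "tree_depth": tree.tree_depth,
        "confusion_matrix": {
            "classes": list(rep.confusion.index),
            "rows_true_cols_predicted": rep.confusion.to_numpy().tolist(),
        },
        "accuracy_percent": rep.accuracy_percent,
        "per_class_percent": rep.per_class.to_dict(orient="index"),
        "accuracy_by_stroke_type": strata,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"cart_{feature_set}.json").write_text(json.dumps(result, indent=1))
        rep.per_class.assign(accuracy=rep.accuracy_percent).to_csv(
            out / f"cart_{feature_set}_metrics.csv"
        )
    return result
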