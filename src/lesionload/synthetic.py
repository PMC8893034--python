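"""Synthetic stroke cohorts: atlas, lesions, and clinical covariates.

The generator emulates the statistical structure the analysis assumes so
that every stage runs, and is validated, with no protected patient data:

* a six-region-per-hemisphere tract atlas of disjoint tube-shaped tracts
  (with a small configurable left/right homolog size asymmetry);
* blob-free "voxel budget" lesions that hit each tract with a prescribed
  overlap percentage (exact to the nearest voxel) plus random bulk
  outside the tracts — sufficient to exercise the overlap arithmetic,
  making no claim to vascular realism;
* clinical covariates whose outcome (E-ARAT) is a linear function of
  lesion load, admission strength, and age plus Gaussian noise, with
  group-conditional distributions anchored to a 34-patient reference
  cohort: outcome groups 52.9 / 35.3 / 11.8 %, whole-CST lesion-load
  medians 3.9 / 11.5 / 31.7 %, AR E-SAFE medians 8 / 3.5 / 0.5, acute
  E-SAFE medians 6 / 3 / 0, E-ARAT medians 42.3 / 28.1 / 11.5, ages
  normal(64, 10) truncated to 36-84, stroke types 70.6 % ischemic /
  23.5 % hemorrhagic / 5.9 % mixed.

One master seed deterministically derives every per-patient seed, so a
cohort is reproducible and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import ARAT_MAX, OUTCOME_LABELS, e_arat, RaterItemRange
from .grids import LesionMask, VolumeGrid
from .tracts import CST_REGIONS, Tract, TractAtlas

__all__ = [
    "SyntheticConfig",
    "CohortResult",
    "make_atlas",
    "make_lesion",
    "make_cohort",
    "make_planted_rule_cohort",
]

# Group-conditional anchors (medians and printed ranges) for the three
# outcome groups, in (Good, Limited, Poor) order.
_CST_MEDIANS = (3.9, 11.5, 31.7)
_CST_RANGES = ((0.0, 22.5), (6.0, 35.1), (13.0, 61.8))
_AR_ESAFE = ((8.0, 1.5, 4, 10), (3.5, 2.0, 0, 8), (0.5, 0.7, 0, 2))  # mean, sd, lo, hi
_ACUTE_ESAFE = ((6.0, 1.5, 1, 8), (3.0, 2.0, 0, 8), (0.0, 0.0, 0, 0))
_EARAT_TARGET_MEDIANS = (42.3, 28.1, 11.5)


def _solve_outcome_weights() -> tuple[float, float, float]:
    """Intercept, AR-E-SAFE weight, and total lesion-load weight.

    Solved once, analytically, so that plugging each group's median AR
    E-SAFE and median CST load into the linear outcome model returns that
    group's median E-ARAT (three equations, three unknowns).
    """
    a = np.array(
        [[1.0, _AR_ESAFE[g][0], -_CST_MEDIANS[g]] for g in range(3)]
    )
    b = np.array(_EARAT_TARGET_MEDIANS)
    intercept, w_safe, w_load = np.linalg.solve(a, b)
    return float(intercept), float(w_safe), float(w_load)


_INTERCEPT, _W_SAFE, _W_LOAD = _solve_outcome_weights()


@dataclass
class SyntheticConfig:
    """Everything that defines a synthetic cohort. Defaults are the study
    conditions; change them only to model a different cohort."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_patients: int = 34
    group_proportions: tuple[float, float, float] = (18 / 34, 12 / 34, 4 / 34)
    age_mean: float = 64.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (36.0, 84.0)
    stroke_type_proportions: tuple[float, float, float] = (0.706, 0.235, 0.059)
    # outcome model: intercept + w_safe*AR_ESAFE - (weights over tract loads)
    # - w_age*(age - age_mean) + N(0, noise_sd), clamped to [0, 57].
    # The lesion-load weight is split over whole-CST, PMv and PMd terms.
    load_weight_split: tuple[float, float, float] = (0.6, 0.25, 0.15)
    age_weight: float = 0.05
    # None -> solved analytically from the reference-group medians
    intercept: float | None = None
    safe_weight: float | None = None
    load_weight: float | None = None
    noise_sd: float = 3.5
    rater_sd: float = 5.0  # per-rater chart-review noise on E-ARAT
    rater_halfwidth: tuple[float, float] = (1.0, 4.0)  # score-range halfwidth
    tract_spread: float = 3.0  # per-tract deviation around patient severity, %
    homolog_asymmetry: int = 2  # |n_L - n_R| voxels per region
    bulk_voxels: tuple[int, int] = (20, 200)  # extra lesion outside tracts
    make_masks: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if abs(sum(self.stroke_type_proportions) - 1) > 1e-9:
            raise ValueError("stroke type proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


@dataclass
class CohortResult:
    cohort: pd.DataFrame
    masks: list[LesionMask]
    atlas: TractAtlas
    ground_truth: dict


def make_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    homolog_asymmetry: int = 2,
    seed: int = 0,
) -> TractAtlas:
    """Six tube-shaped tracts per hemisphere, pairwise disjoint.

    Tracts are 2x2-voxel columns running along z, anchored on a small
    grid of (x, y) positions in the left hemisphere and mirrored across
    the midsagittal plane; the right homolog loses ``homolog_asymmetry``
    voxels from its upper end, emulating slight left/right CST size
    differences. Deterministic for a given geometry (the seed is accepted
    for interface symmetry and recorded use only).
    """
    nx, ny, nz = grid_shape
    if nx < 24 or ny < 24 or nz < 12:
        raise ValueError(f"grid {grid_shape} too small for 12 disjoint tracts")
    xs = (max(2, nx // 8), max(2, nx // 8) + 5)
    ys = (ny // 8, ny // 2 - 2, ny - ny // 4)
    z0, z1 = nz // 5, nz - nz // 5
    anchors = {
        "M1": (xs[0], ys[0]), "PMd": (xs[0], ys[1]), "PMv": (xs[0], ys[2]),
        "SMA": (xs[1], ys[0]), "preSMA": (xs[1], ys[1]), "S1": (xs[1], ys[2]),
    }
    if xs[1] + 2 > nx // 2:
        raise ValueError(f"grid {grid_shape} too narrow: tracts would cross the midline")
    if any(y + 2 > ny for _, y in anchors.values()):
        raise ValueError(f"grid {grid_shape} too small in y for 3 tract rows")

    tracts: list[Tract] = []
    for region in CST_REGIONS:
        x0, y0 = anchors[region]
        left = np.zeros(grid_shape, dtype=bool)
        left[x0:x0 + 2, y0:y0 + 2, z0:z1] = True
        tracts.append(Tract(region, "L", left))
        right = left[::-1, :, :].copy()
        if homolog_asymmetry:
            idx = np.argwhere(right)
            # drop the lexicographically last voxels (upper end of the tube)
            for x, y, z in idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))][
                -homolog_asymmetry:
            ]:
                right[x, y, z] = False
        tracts.append(Tract(region, "R", right))
    grid = VolumeGrid(np.zeros(grid_shape, dtype=np.int64), voxel_size, "synthetic")
    return TractAtlas(tracts, grid)


def make_lesion(
    atlas: TractAtlas,
    targets: dict[str, float],
    affected_hemisphere: str,
    seed: int,
    patient_id: str = "",
    bulk_voxels: int = 0,
) -> LesionMask:
    """A lesion hitting each affected-hemisphere tract at a target percent.

    For each region, ``round(target/100 * n_voxels)`` tract voxels are
    lesioned in deterministic (lexicographic index) order, so the realised
    overlap is within half a voxel of the target; ``bulk_voxels`` random
    non-tract voxels of the affected hemisphere are added as lesion bulk.
    """
    shape = atlas.grid.shape
    lesion = np.zeros(shape, dtype=np.int64)
    for region, pct in targets.items():
        if not (0.0 <= pct <= 100.0):
            raise ValueError(f"{region}: target overlap {pct} outside [0, 100]")
        tract = atlas.get(region, affected_hemisphere)
        k = int(round(pct / 100.0 * tract.n_voxels))
        if k:
            idx = np.argwhere(tract.mask)
            idx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))][:k]
            lesion[idx[:, 0], idx[:, 1], idx[:, 2]] = 1

    if bulk_voxels:
        rng = np.random.default_rng(seed)
        in_any_tract = np.zeros(shape, dtype=bool)
        for t in atlas.tracts:
            in_any_tract |= t.mask
        nx = shape[0]
        half = np.zeros(shape, dtype=bool)
        if affected_hemisphere == "L":
            half[: nx // 2] = True
        else:
            half[nx - nx // 2:] = True
        candidates = np.argwhere(half & ~in_any_tract & (lesion == 0))
        take = min(bulk_voxels, len(candidates))
        chosen = candidates[rng.choice(len(candidates), size=take, replace=False)]
        lesion[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = 1

    grid = VolumeGrid(lesion, atlas.grid.voxel_size, atlas.grid.space_tag)
    return LesionMask(grid, affected_hemisphere, patient_id)


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _split_safe(total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split a SAFE total into valid SA and FE manual-muscle-test grades."""
    lo = max(0, total - 5)
    hi = min(5, total)
    sa = int(rng.integers(lo, hi + 1))
    return sa, total - sa


def make_cohort(config: SyntheticConfig | None = None) -> CohortResult:
    """Generate a full synthetic cohort: masks, cohort table, ground truth.

    Group labels are drawn from the configured proportions; each patient
    gets group-conditional lesion severity, per-tract overlap targets,
    E-SAFE scores, an age, a stroke type, an affected hemisphere, a
    model-generated E-ARAT, and two simulated rater score ranges whose
    midpoint average reconstructs an estimated E-ARAT.
    """
    config = config or SyntheticConfig()
    master = np.random.SeedSequence(config.master_seed)
    rng = np.random.default_rng(master)
    atlas = make_atlas(
        config.grid_shape, config.voxel_size, config.homolog_asymmetry,
        seed=config.master_seed,
    )
    region_list = list(CST_REGIONS)
    intercept = _INTERCEPT if config.intercept is None else config.intercept
    w_safe = _W_SAFE if config.safe_weight is None else config.safe_weight
    w_load = _W_LOAD if config.load_weight is None else config.load_weight
    w_cst, w_pmv, w_pmd = (s * w_load for s in config.load_weight_split)

    patient_seeds = master.spawn(config.n_patients)
    rows = []
    masks: list[LesionMask] = []
    truth_patients = []
    for i in range(config.n_patients):
        prng = np.random.default_rng(patient_seeds[i])
        pid = f"SYN{i + 1:03d}"
        g = int(prng.choice(3, p=config.group_proportions))
        group = OUTCOME_LABELS[g]

        # lesion severity: log-normal around the group's median whole-CST
        # load, clipped to the group's printed range
        lo, hi = _CST_RANGES[g]
        severity = float(
            np.clip(_CST_MEDIANS[g] * np.exp(prng.normal(0.0, 0.5)), lo, hi)
        )
        targets = {
            r: float(np.clip(prng.normal(severity, config.tract_spread), 0.0, 100.0))
            for r in region_list
        }

        age = _truncated_normal(
            prng, config.age_mean, config.age_sd, *config.age_range
        )
        stroke_type = ("ischemic", "hemorrhagic", "mixed")[
            int(prng.choice(3, p=config.stroke_type_proportions))
        ]
        hemisphere = "L" if prng.random() < 0.5 else "R"

        m, sd, s_lo, s_hi = _AR_ESAFE[g]
        ar_esafe = int(round(_truncated_normal(prng, m, sd, s_lo, s_hi)))
        m, sd, s_lo, s_hi = _ACUTE_ESAFE[g]
        acute_esafe = int(round(_truncated_normal(prng, m, sd, s_lo, s_hi)))
        sa, fe = _split_safe(ar_esafe, prng)

        earat_true = float(
            np.clip(
                intercept
                + w_safe * ar_esafe
                - w_cst * severity
                - w_pmv * targets["PMv"]
                - w_pmd * targets["PMd"]
                - config.age_weight * (age - config.age_mean)
                + prng.normal(0.0, config.noise_sd),
                0.0,
                ARAT_MAX,
            )
        )
        rater_ranges = []
        for rater in ("rater1", "rater2"):
            mid = float(np.clip(earat_true + prng.normal(0.0, config.rater_sd), 0, ARAT_MAX))
            hw = float(prng.uniform(*config.rater_halfwidth))
            rater_ranges.append(
                RaterItemRange(
                    rater,
                    float(np.clip(mid - hw, 0, ARAT_MAX)),
                    float(np.clip(mid + hw, 0, ARAT_MAX)),
                )
            )
        earat = e_arat(rater_ranges, patient_id=pid).final

        # comorbidity indicators: uninformative covariates available to CART
        prior_stroke = int(prng.random() < 0.206)
        white_matter_disease = int(prng.random() < 0.706)

        row = {
            "patient_id": pid,
            "group_true": group,
            "age": round(age, 1),
            "stroke_type": stroke_type,
            "hemisphere": hemisphere,
            "sa": sa,
            "fe": fe,
            "acute_esafe": acute_esafe,
            "ar_esafe": ar_esafe,
            "prior_stroke": prior_stroke,
            "white_matter_disease": white_matter_disease,
            "rater1_min": rater_ranges[0].total_min,
            "rater1_max": rater_ranges[0].total_max,
            "rater2_min": rater_ranges[1].total_min,
            "rater2_max": rater_ranges[1].total_max,
            "earat": earat,
        }
        for r in region_list:
            row[f"{r}_target_percent"] = targets[r]
        rows.append(row)
        truth_patients.append(
            {"patient_id": pid, "group": group, "severity": severity,
             "targets": targets, "earat_true": earat_true,
             "spawn_key": list(patient_seeds[i].spawn_key)}
        )
        if config.make_masks:
            bulk = int(prng.integers(config.bulk_voxels[0], config.bulk_voxels[1] + 1))
            masks.append(
                make_lesion(
                    atlas, targets, hemisphere,
                    seed=int(prng.integers(2**31)),
                    patient_id=pid, bulk_voxels=bulk,
                )
            )

    cohort = pd.DataFrame(rows)
    ground_truth = {
        "config": asdict(config),
        "outcome_model": {
            "intercept": intercept,
            "w_ar_esafe": w_safe,
            "w_load_total": w_load,
            "load_weight_split": list(config.load_weight_split),
            "w_age": config.age_weight,
            "noise_sd": config.noise_sd,
        },
        "master_seed": config.master_seed,
        "patients": truth_patients,
    }
    return CohortResult(cohort, masks, atlas, ground_truth)


def make_planted_rule_cohort(
    n: int,
    seed: int,
    root_feature: str = "PMd_percent",
    root_threshold: float = 15.0,
    second_feature: str = "PMv_percent",
    second_threshold: float = 15.0,
    margin: float = 4.0,
    n_noise_features: int = 3,
    depth: int = 2,
    label_noise: float = 0.0,
    class_probs: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Features and labels exactly following a planted depth-1 or -2 rule.

    The rule mirrors the tree structure under test: high root-feature
    values are Poor; otherwise high second-feature values are Limited,
    the rest Good (depth=1 drops the second test and the Limited class).
    No observation falls within ``margin`` of a threshold on the feature
    that decides it, so a correct tree recovers thresholds inside the
    gaps. ``label_noise`` flips each label to a random other class with
    that probability (useful for exercising pruning).
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    rng = np.random.default_rng(seed)
    half = margin / 2.0
    lo_max_root = root_threshold - half
    lo_max_second = second_threshold - half
    classes = ["Good", "Limited", "Poor"] if depth == 2 else ["Good", "Poor"]
    if class_probs is None:
        class_probs = [1.0 / len(classes)] * len(classes)
    labels = np.asarray(classes, dtype=object)[
        rng.choice(len(classes), size=n, p=list(class_probs))
    ]

    root = np.empty(n)
    second = np.empty(n)
    for i, lab in enumerate(labels):
        if lab == "Poor":
            root[i] = rng.uniform(root_threshold + half, 60.0)
            second[i] = rng.uniform(0.0, 60.0)
        else:
            root[i] = rng.uniform(0.0, lo_max_root)
            if depth == 2 and lab == "Limited":
                second[i] = rng.uniform(second_threshold + half, 60.0)
            else:
                second[i] = rng.uniform(0.0, lo_max_second)
    X = pd.DataFrame({root_feature: root, second_feature: second})
    for j in range(n_noise_features):
        X[f"noise_{j + 1}"] = rng.uniform(0.0, 60.0, size=n)

    if label_noise:
        flip = rng.random(n) < label_noise
        for i in np.flatnonzero(flip):
            others = [c for c in classes if c != labels[i]]
            labels[i] = others[int(rng.integers(len(others)))]
    return X, labels
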