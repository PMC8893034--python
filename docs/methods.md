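# Methods

## Overlap arithmetic and grid conventions

All volumes live on one shared voxel grid; the package never resamples.
Shape or voxel-size mismatches raise immediately, because silent
nearest-neighbour resampling would change overlap counts. Voxel indices
are 0-based; axis 0 is left–right with the midsagittal plane at
`nx / 2`, so hemisphere flipping for the cohort heat map is a reversal
of axis 0 (`x → nx − 1 − x`). Lesion masks are binary; non-binary
inputs are binarised (nonzero → 1) with a warning, since clinical masks
sometimes carry label values. Lesion volume is voxel count × voxel
volume.

Per-tract lesion load is `100 · |lesion ∩ tract| / |tract|`. Aggregates
use summed counts — `100 · Σ o_t / Σ n_t` — not a union and not an
unweighted mean of percentages, so each tract contributes in proportion
to its size; where a generic atlas has overlapping tracts, each tract is
still counted independently. Only the affected hemisphere's tracts enter
any metric because left/right tract homologs differ slightly in size. A
tract counts as "affected" from 1 overlapped voxel (no published
threshold exists; the choice is recorded here and configurable).
Percentages are carried at full precision and rounded only for display.

## Clinical estimation scores

The per-rater reduction of an ARAT chart-review range to one number is
the range midpoint — the median of a two-point set — and the final
E-ARAT averages the two raters. This midpoint reading is the package's
single biggest estimation assumption: chart review yields only (min,
max) bounds per rater, and no per-item reduction rule is standard.

Inter-rater agreement uses ICC(3,1): two-way ANOVA with subjects random
and raters fixed, single measures, consistency form
`(MS_subjects − MS_error) / (MS_subjects + (k − 1) MS_error)`. The
consistency (not absolute-agreement) form was chosen because a fixed
additive rater offset should not count as disagreement for fixed raters;
the implementation is cross-checked against pingouin's `ICC(C,1)` in the
test suite. Zero between-subject variance returns NaN with a note rather
than an arbitrary value.

Outcome grouping solves 1-D k-means *exactly* by dynamic programming
over the sorted scores (optimal 1-D partitions are contiguous), rather
than seeded iterative k-means — same objective, no seed dependence, and
testable against exhaustive partition search. Labels follow descending
centers: Good, Limited, Poor. Centers closer than the 12-point ARAT MCID
produce a warning, not an error, since the partition is still the
optimum.

## Statistical battery

Spearman/Pearson/Kruskal-Wallis use the standard tie-corrected kernels
(scipy), wrapped to report n, df = n − 2 and two-tailed p. Spearman's p
uses the t approximation `t = r √((n−2)/(1−r²))`; an exact permutation
enumeration is provided for n ≤ 8 as a cross-check. Kruskal-Wallis on a
pooled-constant sample returns H = 0 by convention. Pairwise post-hoc
comparisons are Dunn-type z statistics on the pooled tie-corrected
ranks with Bonferroni multiplication (`p_adj = min(1, p · n_pairs)`),
mirroring the "adjusted significance" output of classical statistics
packages; the reported effect size is the difference of group medians.
All tests are two-tailed at α = 0.05; correlation families use
α/6 ≈ 0.0083 (six tracts) and three-way comparisons α/3 ≈ 0.0167.

## Classification tree

The CART is authored here to be fully deterministic: greedy binary
splits maximising weighted Gini decrease; candidate thresholds at
midpoints of consecutive sorted unique values; left branch strictly
below the threshold (boundary rows go right — published trees mix
`<` and `≤` renderings, one convention is used throughout); ties in
impurity decrease break to the lowest feature index in declared column
order, then the smallest threshold; leaf ties break to the earlier
class. Defaults: depth ≤ 2, terminal nodes ≥ 3 — the small-cohort
clinical configuration. No surrogate splits: the cohorts here are
complete by construction, and a missing value at prediction time is an
error, not a guess.

Automated pruning is minimal cost-complexity pruning: candidate
penalties come from the full tree's pruning path (geometric interior
points), each is scored by seeded k-fold (default 10) cross-validated
misclassification, and the largest penalty within one standard error of
the minimum risk is applied (1-SE rule). Pruning never deepens a tree;
the fold seed is recorded in every report. sklearn's
`DecisionTreeClassifier` serves as an independent oracle in tests, never
as the implementation.

Feature sets mirror the analysis design: `mri_only` = six per-tract
percentages + whole-CST % + non-M1 % + lesion volume;
`mri_plus_clinical` adds age, acute and AR E-SAFE, stroke-type
indicator columns, and comorbidity indicators. Stratified accuracy
groups "any hemorrhagic involvement" (hemorrhagic + mixed) against
purely ischemic strokes.

## Synthetic cohort generator

The generator defines the study conditions; it is not a tuning knob.
Defaults encode the reference cohort: 34 patients; outcome groups at
52.9/35.3/11.8 %; ages normal(64, 10) truncated to 36–84; stroke types
70.6 % ischemic, 23.5 % hemorrhagic, 5.9 % mixed; group-conditional
whole-CST lesion-load severities log-normal around medians
3.9/11.5/31.7 % clipped to the groups' observed ranges; AR E-SAFE and
acute E-SAFE integer draws around group medians 8/3.5/0.5 and 6/3/0.

The outcome model is invented (only group medians and ranges are
published, not a generative model): E-ARAT = intercept + w·(AR E-SAFE)
− (lesion-load weights over CST/PMv/PMd) − 0.05·(age − 64) + N(0, 3.5),
clamped to [0, 57]. The intercept and the two main weights are solved
analytically from the three group-median equations, so calibration is a
one-time linear solve, not an iterative fit. Two simulated raters add
N(0, 5) chart-review noise and a 1–4-point range halfwidth; the rater
noise value makes the simulated inter-rater ICC land in the mid-0.8s,
the agreement level reported for careful chart review.

Lesions are voxel budgets, not vascular territories: each tract of the
affected hemisphere gets `round(target% · n_voxels)` lesioned voxels in
deterministic index order (so realised overlap is exact to the nearest
voxel, i.e. ±1.25 percentage points on an 80-voxel tract), plus 20–200
random bulk voxels outside all tracts. The atlas is twelve disjoint
2×2-voxel tubes on a 32³ grid of 2 mm voxels, with the right homolog 2
voxels smaller than the left. Consequences for interpretation: passing
tests validate the scoring arithmetic, the statistics and the
classifier on data with the assumed structure; they say nothing about
lesion segmentation quality, spatial normalization error, or the true
anatomy of CST projections. One master `SeedSequence` spawns every
per-patient stream, so cohorts are reproducible and extensible (the
first n patients of a larger cohort are identical).

A separate planted-rule generator emits cohorts whose labels follow an
exact depth-1 or depth-2 threshold rule with a margin (no observations
within ±2 units of a deciding threshold at the default 4-unit margin),
plus uniform distractor features and optional label noise — used to
verify that the tree recovers planted structure and that pruning
removes noise-fitting splits.

## Problem sizes and numerical choices

Analysis drivers and tests run at the reference scale (n = 34, 32³
grids); recovery and significance frequency studies use 50 seeded
cohorts at n = 200, the scale at which the planted effects should be
detected essentially always. Oracle-equivalence checks run exhaustive
triple-loop voxel counting on random grids up to 8×8×8, where
enumeration is exact and fast. Exact-clustering checks enumerate all
ordered 3-partitions for n ≤ 12. Floating-point ties in the tree search
and the clustering DP break deterministically (earliest split / lowest
feature index) with a 1e-12 comparison slack.

## Known limitations

- No registration/normalization: inputs must already share a grid.
- The E-ARAT midpoint reduction and the linear outcome model are
  modelling choices, not published procedures.
- Probabilistic (partial-volume weighted) lesion load is out of scope;
  masks and atlases are binary.
- The pruning CV risk is misclassification only; no class weighting.
- Synthetic lesions are not spatially realistic and the synthetic
  atlas is geometric; both exist to exercise the arithmetic.
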