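# lesionload

Corticospinal-tract (CST) lesion-load analysis for stroke cohorts: from
binary lesion masks and a labeled sensorimotor tract atlas to per-tract
lesion-overlap percentages, chart-estimated clinical scores, outcome
grouping, nonparametric group statistics, and a decision-tree outcome
classifier.

## Who this is for

Rehabilitation and neuroimaging researchers who quantify how much of the
descending motor system a stroke lesion disrupts, and who want to relate
that disruption to upper-extremity motor outcome. The pipeline assumes
lesion masks already normalized onto one template voxel grid (e.g.
MNI152 at 2 mm) together with a tract atlas delineating CST
contributions from six cortical seed regions per hemisphere (M1, PMd,
PMv, SMA, preSMA, S1). Because patient imaging is protected, the package
ships a synthetic-cohort generator that reproduces the statistical
structure of a 34-patient reference cohort so every stage runs and is
tested without any real data.

## The quantities at the core

For a tract *t* with *n_t* voxels, of which *o_t* fall inside the
patient's lesion mask, the per-tract lesion load is `100 · o_t / n_t`.
The whole-CST load sums counts before dividing,

    CST% = 100 · Σ_t o_t / Σ_t n_t ,

over the six tracts of the *affected* hemisphere (the hemisphere
contralateral to the paretic limb); the non-M1 load omits only the M1
tract. Clinical scores: SAFE = shoulder-abduction + finger-extension
manual muscle tests (/10); E-ARAT estimates the Action Research Arm Test
(0–57) as the average of two raters' chart-review range midpoints, with
inter-rater agreement measured by a two-way mixed consistency ICC(3,1).
Outcome groups (Good/Limited/Poor) are the exact three-cluster 1-D
k-means partition of E-ARAT (dynamic programming, no seed), flagged if
adjacent centers are closer than the 12-point minimal clinically
important difference. Associations use Spearman's rho and Kruskal-Wallis
tests with Dunn pairwise comparisons and Bonferroni adjustment; outcome
classification uses a deterministic Gini CART (depth ≤ 2, terminal
nodes ≥ 3, cost-complexity pruning chosen by seeded cross-validation
with the 1-SE rule).

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 0   # 34-patient cohort
python analysis/02_lesion_overlap.py             # overlap table + heat map
python analysis/03_clinical_scoring.py           # E-ARAT, ICC, clustering
python analysis/04_group_statistics.py           # correlations + KW battery
python analysis/05_cart_classifiers.py           # the two CART variants
```

On the seed-0 cohort this prints, among other things:

```
inter-rater ICC(3,1) = 0.838 (34 subjects, 2 raters)
cluster centers: {'Good': 43.1, 'Limited': 31.0, 'Poor': 13.5}; min separation 12.0 points (>= 12-point MCID)
  cst_percent      r_s(32) = -0.577, p = 0.0003516 *
Kruskal-Wallis across outcome groups (whole-CST load):
  H(2) = 15.50, p = 0.0004315
=== mri_plus_clinical ===
if ar_esafe < 6.5: ...
accuracy 97.1% (depth 2)
```

Reading: the two simulated raters agree strongly (ICC 0.84); the
three outcome clusters are just clinically distinct (centers 12 points
apart); whole-CST lesion load is significantly negatively correlated
with 3-month upper-extremity function (rho −0.58, below the Bonferroni
threshold 0.05/6 = 0.0083) and differs across outcome groups; and a
depth-2 tree on admission strength plus M1 lesion load classifies the
synthetic cohort's outcome group with 97% training accuracy.

The same stages are exposed as a CLI (`lesionload simulate|overlap|
heatmap|analyze|cart|report`) and as library functions
(`lesionload.run_overlap_stage`, `run_stats_stage`, `run_cart_stage`).

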