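"""Clinical estimation scores and outcome grouping.

SAFE is the sum of shoulder-abduction and finger-extension manual muscle
tests (each 0-5, total /10); the E- prefix marks chart-based estimation.
E-ARAT estimates the Action Research Arm Test (0-57) from two raters who
each produced a min-max score range from chart review: each rater's score
is the midpoint (median) of their range and the final score averages the
two raters. Outcome groups (Good / Limited / Poor) come from an exact
three-cluster 1-D k-means partition of E-ARAT, with a warning when
adjacent cluster centers are closer than the 12-point minimal clinically
important difference (MCID).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SafeScore",
    "RaterItemRange",
    "EaratScore",
    "IccResult",
    "OutcomeGroups",
    "ARAT_MAX",
    "MCID_POINTS",
    "OUTCOME_LABELS",
    "safe_score",
    "e_arat",
    "icc_two_way_mixed",
    "outcome_clusters",
]

ARAT_MAX = 57
MCID_POINTS = 12.0
OUTCOME_LABELS = ("Good", "Limited", "Poor")  # by descending cluster center


@dataclass(frozen=True)
class SafeScore:
    shoulder_abduction: int
    finger_extension: int
    assessment_day: float | None = None
    estimated: bool = True

    def __post_init__(self) -> None:
        for name, v in (
            ("shoulder_abduction", self.shoulder_abduction),
            ("finger_extension", self.finger_extension),
        ):
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 5):
                raise ValueError(f"{name} must be an integer manual-muscle-test grade 0-5, got {v!r}")

    @property
    def total(self) -> int:
        return int(self.shoulder_abduction + self.finger_extension)


def safe_score(
    sa: int, fe: int, assessment_day: float | None = None, estimated: bool = True
) -> SafeScore:
    """SAFE score from shoulder-abduction and finger-extension MMT grades."""
    return SafeScore(sa, fe, assessment_day, estimated)


@dataclass(frozen=True)
class RaterItemRange:
    """One rater's min/max total over the ARAT items for one patient."""

    rater_id: str
    total_min: float
    total_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.total_min <= self.total_max <= ARAT_MAX):
            raise ValueError(
                f"rater {self.rater_id}: need 0 <= min <= max <= {ARAT_MAX}, "
                f"got ({self.total_min}, {self.total_max})"
            )

    @property
    def midpoint(self) -> float:
        return (self.total_min + self.total_max) / 2.0


@dataclass(frozen=True)
class EaratScore:
    patient_id: str
    rater_scores: tuple[float, float]
    final: float


def e_arat(ranges: Sequence[RaterItemRange], patient_id: str = "") -> EaratScore:
    """Estimated ARAT from two raters' chart-review score ranges.

    Each rater's score is the midpoint of their (min, max) range — the
    median of a two-point range — and the final E-ARAT averages the two
    rater scores.
    """
    if len(ranges) != 2:
        raise ValueError(f"e_arat needs exactly two raters, got {len(ranges)}")
    scores = (ranges[0].midpoint, ranges[1].midpoint)
    return EaratScore(patient_id, scores, float(np.mean(scores)))


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation from a two-way mixed model.

    ``ICC(3,1)``: single measures, consistency — raters are fixed effects,
    subjects random. ``icc`` is NaN when the between-subject variance is
    zero (consistency is then undefined); ``note`` says why.
    """

    icc: float
    n_subjects: int
    k_raters: int
    ms_subjects: float
    ms_error: float
    model: str = "two-way mixed, single measures, consistency (ICC(3,1))"
    note: str = ""


def icc_two_way_mixed(ratings: np.ndarray | Sequence[Sequence[float]]) -> IccResult:
    """ICC(3,1) from an ``n_subjects x k_raters`` complete ratings table.

    Two-way ANOVA decomposition with subjects as rows and raters as
    columns: ``ICC = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)`` where MS_R is
    the between-subject mean square and MS_E the residual (interaction)
    mean square after removing the rater main effect.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")
    if np.isnan(x).any():
        raise ValueError("ratings table has missing cells")

    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows <= 0:
        return IccResult(
            float("nan"), n, k, ms_rows, ms_err,
            note="zero between-subject variance; consistency ICC undefined",
        )
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return IccResult(float(icc), n, k, float(ms_rows), float(ms_err))


@dataclass
class OutcomeGroups:
    """Exact k-cluster 1-D partition with labels ordered by center."""

    labels: list[str]
    centers: dict[str, float]  # label -> center, descending center order
    assignments: np.ndarray = field(repr=False)  # cluster index per input value
    min_center_gap: float = float("nan")
    mcid_warning: bool = False


def _exact_1d_kmeans(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Optimal k-partition of sorted values minimising within-cluster SS.

    Dynamic programming over contiguous segments (an optimal 1-D k-means
    partition is always contiguous in sorted order). Returns the start
    index of each segment.
    """
    n = len(sorted_vals)
    pref = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    pref2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def seg_cost(i: int, j: int) -> float:
        # within-segment sum of squares for values[i:j]
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / (j - i)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + seg_cost(i, j)
                if v < best - 1e-12:  # prefer earliest split on exact ties
                    best, arg = v, i
            cost[c, j], split[c, j] = best, arg
    starts = []
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        starts.append(i)
        j = i
    return starts[::-1]


def outcome_clusters(
    values: Sequence[float], k: int = 3, mcid: float = MCID_POINTS
) -> OutcomeGroups:
    """Partition outcome scores into k groups by exact 1-D k-means.

    Clusters are found by dynamic programming over the sorted scores, so
    the partition is the global optimum and needs no seed. Labels are
    assigned in descending center order (Good / Limited / Poor for k=3).
    If any two adjacent centers are closer than ``mcid`` points the groups
    are not clinically distinct; that raises a warning, not an error.
    """
    vals = np.asarray(values, dtype=float)
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct values, got {len(np.unique(vals))}")
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    starts = _exact_1d_kmeans(sorted_vals, k)
    bounds = starts + [len(vals)]

    # cluster index in ascending-value order -> rank by descending center
    centers_asc = [float(sorted_vals[bounds[c]:bounds[c + 1]].mean()) for c in range(k)]
    if k == 3:
        label_names = list(OUTCOME_LABELS)
    else:
        label_names = [f"G{i + 1}" for i in range(k)]
    # ascending centers map to reversed label list (highest center = first label)
    asc_to_label = {c: label_names[k - 1 - c] for c in range(k)}

    assignments = np.empty(len(vals), dtype=int)
    for c in range(k):
        assignments[order[bounds[c]:bounds[c + 1]]] = c
    labels = [asc_to_label[c] for c in assignments]
    centers = {asc_to_label[c]: centers_asc[c] for c in reversed(range(k))}

    gaps = np.diff(centers_asc)
    min_gap = float(gaps.min()) if len(gaps) else float("nan")
    warn = bool(len(gaps) and min_gap < mcid)
    if warn:
        warnings.warn(
            f"adjacent cluster centers only {min_gap:.1f} points apart "
            f"(< MCID {mcid:g}); outcome groups may not be clinically distinct",
            stacklevel=2,
        )
    return OutcomeGroups(labels, centers, assignments, min_gap, warn)
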