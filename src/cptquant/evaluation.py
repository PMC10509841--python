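"""ROC construction, threshold selection and the CAP-class comparison.

The instrument is evaluated against binary ground-truth labels (e.g. a
human-assigned nonzero redness score, or SSS positivity) by sweeping the
classification threshold over the score range 0-3.7.  At each threshold a
prediction is positive iff the score is strictly above it.  Sensitivity is
tp/(tp+fn) and specificity tn/(tn+fp); precision tp/(tp+fp) is exported
alongside.  The ROC curve is smoothed by isotonic regression of
sensitivity on the false-positive rate (shape-preserving, deterministic);
the operating threshold maximizes Youden's J = sensitivity + specificity -
1 on the smoothed curve, and a stringent threshold is the smallest one
whose specificity reaches a configurable floor (default 0.97).

Cohort-level validity is assessed by comparing mean sIgE CAP classes
between sensitivity-category groups with two-sided equal-variance t tests
(star codes * P<.05, ** P<.01, *** P<.001).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .clinical import cap_class, sensitivity_category
from .session import DILUTIONS

__all__ = [
    "ConfusionCounts",
    "confusion_at_threshold",
    "RocCurve",
    "roc_curve",
    "ThresholdSelection",
    "select_thresholds",
    "CapComparison",
    "cap_vs_sensitivity",
    "patient_summary",
    "DEFAULT_THRESHOLD_GRID",
]

#: the published score axis: thresholds swept from 0.0 to 3.7
DEFAULT_THRESHOLD_GRID = np.round(np.linspace(0.0, 3.7, 75), 6)

CATEGORY_ORDER = ("1:1000", "1:100", "1:10", "stock", "none")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def degenerate(self) -> bool:
        """True when one class is absent and a rate is undefined."""
        return (self.tp + self.fn == 0) or (self.tn + self.fp == 0)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> ConfusionCounts:
    """Tally the confusion counts at one threshold (positive iff
    score > threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores > threshold
    return ConfusionCounts(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    counts: list
    smoothed_sensitivity: np.ndarray  # isotonic fit evaluated at the grid
    smoothed_specificity: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": [c.tp for c in self.counts],
                "fp": [c.fp for c in self.counts],
                "tn": [c.tn for c in self.counts],
                "fn": [c.fn for c in self.counts],
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
            }
        )


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    thresholds: Optional[np.ndarray] = None,
) -> RocCurve:
    """Sweep the threshold grid and build the (smoothed) ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both label classes to be present")
    grid = DEFAULT_THRESHOLD_GRID if thresholds is None else np.asarray(thresholds, float)

    counts = [confusion_at_threshold(scores, labels, t) for t in grid]
    sens = np.array([c.sensitivity for c in counts])
    spec = np.array([c.specificity for c in counts])
    prec = np.array([c.precision for c in counts])

    # Smooth each rate as a monotone function of the threshold (sensitivity
    # can only fall, specificity only rise, as the threshold is raised); the
    # smoothed ROC curve is then the piecewise-linear interpolation of the
    # parametric points (1 - specificity(t), sensitivity(t)).  Regressing
    # sensitivity on the false-positive rate directly would average the many
    # thresholds that share a tied rate and collapse the curve.
    iso_sens = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False, out_of_bounds="clip")
    iso_sens.fit(grid, sens)
    smoothed_sens = iso_sens.predict(grid)
    iso_spec = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True, out_of_bounds="clip")
    iso_spec.fit(grid, spec)
    smoothed_spec = iso_spec.predict(grid)

    # AUC of the smoothed parametric curve; append the all-positive corner
    # (1, 1), which the grid never reaches because predictions use a strict
    # inequality
    x = np.concatenate([1.0 - smoothed_spec, [1.0]])
    y = np.concatenate([smoothed_sens, [1.0]])
    order = np.lexsort((y, x))
    x, y = x[order], np.maximum.accumulate(y[order])
    auc = float(np.trapezoid(y, x))

    return RocCurve(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        counts=counts,
        smoothed_sensitivity=smoothed_sens,
        smoothed_specificity=smoothed_spec,
        auc=auc,
    )


@dataclass
class ThresholdSelection:
    optimal_threshold: float
    stringent_threshold: float
    youden_j: float
    floor_attained: bool
    specificity_floor: float


def select_thresholds(curve: RocCurve, specificity_floor: float = 0.97) -> ThresholdSelection:
    """Operating thresholds from a (smoothed) ROC curve.

    The optimal threshold maximizes Youden's J on the smoothed curve, ties
    broken toward higher specificity; the stringent threshold is the
    smallest grid threshold whose smoothed specificity reaches the floor.
    If the floor is unattainable the highest-specificity threshold is
    returned, flagged.
    """
    j = curve.smoothed_sensitivity + curve.smoothed_specificity - 1.0
    best = j.max()
    tie = np.flatnonzero(j >= best - 1e-12)
    # ties toward higher specificity; a remaining plateau of equally optimal
    # thresholds is resolved to its midpoint (the stable operating point)
    spec_best = curve.smoothed_specificity[tie].max()
    tie = tie[curve.smoothed_specificity[tie] >= spec_best - 1e-12]
    i_opt = int(tie[(len(tie) - 1) // 2])

    meets = np.flatnonzero(curve.smoothed_specificity >= specificity_floor)
    if meets.size:
        i_str = meets[0]
        attained = True
    else:
        i_str = int(np.argmax(curve.smoothed_specificity))
        attained = False
    return ThresholdSelection(
        optimal_threshold=float(curve.thresholds[i_opt]),
        stringent_threshold=float(curve.thresholds[i_str]),
        youden_j=float(best),
        floor_attained=attained,
        specificity_floor=specificity_floor,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CapComparison:
    """Per-category CAP summary with pairwise t-test table."""

    summary: pd.DataFrame  # category, mean_cap_class, n
    pairwise: pd.DataFrame  # group_a, group_b, t, p, stars, skipped
    reference: Optional[str] = None

    def versus_reference(self) -> pd.DataFrame:
        if self.reference is None:
            return self.pairwise.iloc[0:0]
        mask = (self.pairwise["group_a"] == self.reference) | (
            self.pairwise["group_b"] == self.reference
        )
        return self.pairwise[mask]


def patient_summary(
    cohort: pd.DataFrame, rule: str = "combined_human", threshold: float = 0.3
) -> pd.DataFrame:
    """Collapse a per-measurement cohort table to one row per patient:
    sensitivity category under the given rule, and CAP class."""
    records = []
    for patient_id, grp in cohort.groupby("patient_id", sort=True):
        grp = grp.iloc[np.argsort([DILUTIONS.index(d) for d in grp["dilution"]])]
        cat = sensitivity_category(
            list(grp["dilution"]),
            sss=list(grp["sss"]),
            redness_grades=list(grp["redness_grade"]),
            scores=list(grp["instrument_score"]),
            rule=rule,
            threshold=threshold,
        )
        sige = float(grp["sige_ku_per_l"].iloc[0])
        records.append(
            {
                "patient_id": patient_id,
                "category": cat.category,
                "rule": rule,
                "sige_ku_per_l": sige,
                "cap_class": cap_class(sige).cap_class,
            }
        )
    return pd.DataFrame(records)


def cap_vs_sensitivity(
    cohort: pd.DataFrame,
    rule: str = "combined_human",
    threshold: float = 0.3,
    reference: Optional[str] = "none",
) -> CapComparison:
    """Mean CAP class per sensitivity category, with pairwise t tests.

    Uses two-sided equal-variance t tests between all category pairs with
    at least 2 patients each (smaller groups are skipped and flagged).
    ``reference`` names the group against which the headline
    sensitive-vs-insensitive contrasts are read (see
    :meth:`CapComparison.versus_reference`).
    """
    patients = patient_summary(cohort, rule=rule, threshold=threshold)
    groups = {
        cat: patients.loc[patients["category"] == cat, "cap_class"].to_numpy()
        for cat in CATEGORY_ORDER
        if (patients["category"] == cat).any()
    }
    summary = pd.DataFrame(
        {
            "category": list(groups),
            "mean_cap_class": [g.mean() for g in groups.values()],
            "n": [len(g) for g in groups.values()],
        }
    )
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ga, gb = groups[a], groups[b]
        if len(ga) < 2 or len(gb) < 2:
            rows.append(
                {"group_a": a, "group_b": b, "t": np.nan, "p": np.nan, "stars": "", "skipped": True}
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(ga, gb, equal_var=True)
        if np.isnan(t) and np.isclose(ga.mean(), gb.mean()):
            # zero pooled variance with equal means: no evidence of difference
            t, p = 0.0, 1.0
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p": float(p),
                "stars": _stars(float(p)),
                "skipped": False,
            }
        )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p", "stars", "skipped"])
    return CapComparison(summary=summary, pairwise=pairwise, reference=reference)
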