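"""Naming trajectory classes against a growth-standard chart.

The reference class is the one whose median curve deviates least (in sum of
squared differences) from the chart medians at the scheduled visits; the
remaining classes receive semantic labels by curve shape. LMS z-scores
(Box-Cox power L, median M, coefficient of variation S) support the
attained-size sensitivity outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmm import TrajectoryAssignment

logger = logging.getLogger(__name__)

LABELS = ("Stable-slow", "Late-moderate", "Stable-moderate", "Rapid")


@dataclass
class ReferenceChart:
    """Growth-standard chart rows for one sex: L/M/S by index value.

    ``index_kind`` is ``age_months`` or ``length_cm``; M is mandatory, L and
    S only needed for z-scores. User-supplied as CSV with columns
    sex, index_kind, index, L, M, S.
    """

    sex: str
    index_kind: str
    index: np.ndarray
    M: np.ndarray
    L: np.ndarray | None = None
    S: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.index) <= 0):
            raise ValueError("chart index must be strictly increasing")
        if np.any(self.M <= 0):
            raise ValueError("chart medians must be positive")
        if self.S is not None and np.any(self.S <= 0):
            raise ValueError("chart S must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str) -> "ReferenceChart":
        sub = df[df["sex"] == sex].sort_values("index")
        if sub.empty:
            raise ValueError(f"chart has no rows for sex={sex!r}")
        kinds = sub["index_kind"].unique()
        if len(kinds) != 1:
            raise ValueError("mixed index kinds in chart")
        return cls(
            sex=sex, index_kind=kinds[0],
            index=sub["index"].to_numpy(float),
            M=sub["M"].to_numpy(float),
            L=sub["L"].to_numpy(float) if "L" in sub else None,
            S=sub["S"].to_numpy(float) if "S" in sub else None,
        )

    @classmethod
    def read_csv(cls, path, sex: str) -> "ReferenceChart":
        return cls.from_frame(pd.read_csv(path), sex)

    def median_at(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if np.any(x < self.index[0]) or np.any(x > self.index[-1]):
            raise ValueError("index outside chart range")
        return np.interp(x, self.index, self.M)

    def lms_at(self, x: float) -> tuple[float, float, float]:
        if self.L is None or self.S is None:
            raise ValueError("chart lacks L/S columns needed for z-scores")
        if not (self.index[0] <= x <= self.index[-1]):
            raise ValueError(f"index {x} outside chart range")
        return (
            float(np.interp(x, self.index, self.L)),
            float(np.interp(x, self.index, self.M)),
            float(np.interp(x, self.index, self.S)),
        )


def class_median_curves(
    assignments: TrajectoryAssignment,
    growth: pd.DataFrame,
    outcome: str = "wfl",
) -> pd.DataFrame:
    """Per-class median outcome at each nominal visit (long format).

    Visits with no class members are absent from the result (and thereby
    excluded from any SSD computed on it).
    """
    merged = growth.dropna(subset=["nominal_visit"]).merge(
        assignments.df[["subject_id", "class_index"]], on="subject_id"
    )
    if merged.empty:
        raise ValueError("no assigned observations")
    counts = merged.groupby("class_index").size()
    K = assignments.df["class_index"].max() + 1
    for k in range(K):
        if counts.get(k, 0) == 0:
            raise ValueError(f"class {k} has no observations")
    out = (
        merged.groupby(["class_index", "nominal_visit"])[outcome]
        .median()
        .rename("median")
        .reset_index()
    )
    return out


@dataclass
class SSDReport:
    """Per-class squared deviation from the chart and the resulting labels."""

    detail: pd.DataFrame           # class_index, visit, class_median, chart_median, diff
    ssd: pd.Series                 # total per class_index
    reference_class: int
    labels: dict[int, str]


def select_reference(
    median_curves: pd.DataFrame,
    chart: ReferenceChart,
    late_cut: float = 9.0,
) -> SSDReport:
    """Pick the reference class by minimal SSD against the chart medians.

    SSD_k = sum over visits of (class median - chart median)^2, computed on
    the intersection of visits available for every class (logged when
    smaller than the union). Semantic labels: the reference is
    "Stable-slow"; among the rest, a class sitting below the chart before
    ``late_cut`` months and above after it is "Late-moderate"; the remaining
    two are "Stable-moderate" and "Rapid" by ascending final median.
    """
    visits_per_class = median_curves.groupby("class_index")["nominal_visit"].apply(set)
    common = set.intersection(*visits_per_class)
    union = set.union(*visits_per_class)
    if common != union:
        logger.warning("SSD computed on %d common visits (union %d)",
                       len(common), len(union))
    if not common:
        raise ValueError("no visit shared by all classes")
    mc = median_curves[median_curves["nominal_visit"].isin(common)].copy()
    mc["chart_median"] = chart.median_at(mc["nominal_visit"].to_numpy())
    mc["diff"] = mc["median"] - mc["chart_median"]
    ssd = (mc["diff"] ** 2).groupby(mc["class_index"]).sum()
    reference = int(ssd.idxmin())

    labels = {reference: "Stable-slow"}
    others = [k for k in ssd.index if k != reference]
    last_visit = max(common)
    final = mc[mc["nominal_visit"] == last_visit].set_index("class_index")["median"]

    def crosses_late(k: int) -> bool:
        sub = mc[mc["class_index"] == k]
        early = sub[sub["nominal_visit"] <= late_cut]["diff"]
        late = sub[sub["nominal_visit"] > late_cut]["diff"]
        if early.empty or late.empty:
            return False
        return (early.median() <= 0) and (late > 0).all()

    late_candidates = [k for k in others if crosses_late(k)]
    remaining = list(others)
    if len(late_candidates) == 1:
        labels[late_candidates[0]] = "Late-moderate"
        remaining.remove(late_candidates[0])
    elif remaining:
        logger.warning("late-crossing class not uniquely identified; "
                       "labels fall back to final-median ordering")
    ordered = sorted(remaining, key=lambda k: final.get(k, np.inf))
    pool = ["Late-moderate", "Stable-moderate", "Rapid"]
    names = pool[-len(ordered):] if len(ordered) <= 3 else \
        pool + [f"Class-{k}" for k in ordered[3:]]
    if len(ordered) == 3 and not late_candidates:
        names = pool  # lowest-final class takes the late label in fallback
    for k, name in zip(ordered, names):
        labels[k] = name
    mc = mc.rename(columns={"median": "class_median", "nominal_visit": "visit"})
    return SSDReport(detail=mc, ssd=ssd, reference_class=reference, labels=labels)


def lms_zscore(value: float, index_value: float, chart: ReferenceChart) -> float:
    """LMS z-score: ((x/M)^L - 1)/(L S) for L != 0, ln(x/M)/S for L == 0.

    L, M, S are linearly interpolated at the index value.
    """
    L, M, S = chart.lms_at(index_value)
    if value <= 0:
        raise ValueError("measurement must be positive")
    if abs(L) < 1e-12:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


def zscores_at_visit(
    growth: pd.DataFrame, chart: ReferenceChart, visit: float = 18.0,
    outcome: str = "wfl",
) -> pd.Series:
    """Per-subject LMS z-score of the outcome at one nominal visit."""
    sub = growth[growth["nominal_visit"] == visit]
    return sub.set_index("subject_id").apply(
        lambda r: lms_zscore(r[outcome], visit, chart), axis=1
    )
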