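"""Inclusion filters and exposure transforms for the analytic sample.

Implements the study-style exclusion cascade (weight-for-length outliers
beyond the per-visit mean +/- 4 SD, subjects with three or fewer measures)
and the biomarker transforms (LOD/sqrt(2) substitution, log2 + scaling,
tertile coding with the middle tertile as reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELEMENTS = ("As", "Hg", "Pb", "Cu", "Mn", "Se")

#: nominal well-child visit schedule, months
VISIT_SCHEDULE = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 12.0, 15.0, 18.0)


def compute_wfl(growth: pd.DataFrame) -> pd.DataFrame:
    """Add weight-for-length in g/cm: 1000 * weight[kg] / length[cm]."""
    out = growth.copy()
    if (out["weight"] <= 0).any() or (out["length"] <= 0).any():
        raise ValueError("weight and length must be strictly positive")
    out["wfl"] = 1000.0 * out["weight"] / out["length"]
    return out


def censor_at_lod(
    values: pd.DataFrame, lods: dict[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substitute below-LOD concentrations by LOD/sqrt(2) and flag them.

    Returns (substituted values, boolean below-LOD flags), both indexed and
    columned like the per-element input. Values at or above the LOD pass
    through unchanged.
    """
    vals = values.copy()
    flags = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    for el, lod in lods.items():
        if lod <= 0:
            raise ValueError(f"LOD for {el} must be positive, got {lod}")
        if el not in vals.columns:
            continue
        col = vals[el].to_numpy(dtype=float)
        if np.any(col < 0):
            raise ValueError(f"negative concentration in column {el}")
        below = col < lod
        col[below] = lod / np.sqrt(2.0)
        vals[el] = col
        flags[el] = below
    return vals, flags


def assign_nominal_visits(
    growth: pd.DataFrame, schedule: tuple[float, ...] = VISIT_SCHEDULE
) -> pd.DataFrame:
    """Map each observation to its nearest scheduled visit.

    An observation is assigned to the closest nominal age provided it lies
    within that visit's window (halfway to the adjacent visits; boundary
    visits extend outward without limit inside [0, 18]). When a subject has
    several observations assigned to one visit, the closest wins; ties go to
    the earlier observation. Unassigned observations get NaN.
    """
    sched = np.asarray(schedule, dtype=float)
    out = growth.copy()
    ages = out["age"].to_numpy(dtype=float)
    idx = np.abs(ages[:, None] - sched[None, :]).argmin(axis=1)
    nominal = sched[idx]
    # window: half the gap to each neighbour
    lo_edge = np.concatenate([[-np.inf], (sched[:-1] + sched[1:]) / 2])
    hi_edge = np.concatenate([(sched[:-1] + sched[1:]) / 2, [np.inf]])
    ok = (ages >= lo_edge[idx]) & (ages <= hi_edge[idx])
    nominal = np.where(ok, nominal, np.nan)
    out["nominal_visit"] = nominal

    # de-duplicate within subject x visit: closest age wins, ties -> earlier row
    out["_dist"] = np.abs(out["age"] - out["nominal_visit"])
    out["_order"] = np.arange(len(out))
    keep = (
        out.dropna(subset=["nominal_visit"])
        .sort_values(["subject_id", "nominal_visit", "_dist", "_order"])
        .drop_duplicates(["subject_id", "nominal_visit"], keep="first")["_order"]
    )
    dup = out["nominal_visit"].notna() & ~out["_order"].isin(keep)
    out.loc[dup, "nominal_visit"] = np.nan
    return out.drop(columns=["_dist", "_order"])


def filter_outliers(
    growth: pd.DataFrame, n_sd: float = 4.0
) -> tuple[pd.DataFrame, list]:
    """Exclude whole subjects with any wfl beyond the per-visit mean +/- n_sd SD.

    Mean and SD are pooled over sexes within each nominal visit. Visits with
    fewer than two observations have an undefined SD and are skipped with a
    warning. Exclusion is at the subject level: one extreme observation
    removes the mother-child pair entirely.
    """
    if "nominal_visit" not in growth.columns:
        raise ValueError("run assign_nominal_visits before filter_outliers")
    flagged: set = set()
    for visit, grp in growth.dropna(subset=["nominal_visit"]).groupby("nominal_visit"):
        if len(grp) < 2:
            warnings.warn(
                f"visit {visit}: fewer than 2 observations, outlier rule skipped"
            )
            continue
        mu = grp["wfl"].mean()
        sd = grp["wfl"].std(ddof=1)
        bad = grp.loc[(grp["wfl"] - mu).abs() > n_sd * sd, "subject_id"]
        flagged.update(bad.tolist())
    kept = growth[~growth["subject_id"].isin(flagged)].copy()
    return kept, sorted(flagged)


def filter_min_measures(
    growth: pd.DataFrame, min_measures: int = 4
) -> tuple[pd.DataFrame, list]:
    """Exclude subjects with fewer than ``min_measures`` observations in [0, 18].

    The default keeps subjects with at least four weight/length measures,
    i.e. removes those with three or fewer.
    """
    in_window = growth[(growth["age"] >= 0) & (growth["age"] <= 18)]
    counts = in_window.groupby("subject_id").size()
    excluded = sorted(counts[counts < min_measures].index.tolist())
    # subjects with zero in-window rows are excluded too
    all_ids = growth["subject_id"].unique()
    excluded = sorted(set(excluded) | (set(all_ids) - set(counts.index)))
    kept = growth[~growth["subject_id"].isin(excluded)].copy()
    return kept, excluded


@dataclass
class ExposureTransform:
    """Analysis-scale exposure columns plus the constants used to build them."""

    log2_scaled: pd.DataFrame
    tertile: pd.DataFrame  # integer codes 0=low, 1=middle (reference), 2=high
    scale_sd: dict[str, float]
    center: dict[str, float]
    cut_points: dict[str, tuple[float, float]] = field(default_factory=dict)


def transform_exposures(
    raw: pd.DataFrame,
    elements: tuple[str, ...] = ELEMENTS,
    center: bool = True,
) -> ExposureTransform:
    """log2-transform and scale concentrations; code sample tertiles.

    Continuous scale: log2(concentration) divided by the sample SD of the
    log2 values (optionally mean-centred first; the centring constant and SD
    are recorded so a doubling contrast — +1 on the log2 scale — is exactly
    1/scale_sd on the analysis scale). Tertiles: three equal-count groups by
    stable rank, middle group the reference.
    """
    log2_scaled = pd.DataFrame(index=raw.index)
    tert = pd.DataFrame(index=raw.index)
    sds: dict[str, float] = {}
    centers: dict[str, float] = {}
    cuts: dict[str, tuple[float, float]] = {}
    for el in elements:
        vals = raw[el].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"non-positive concentration in {el}; apply LOD substitution first")
        lv = np.log2(vals)
        sd = float(np.std(lv, ddof=1))
        if sd == 0:
            raise ValueError(f"constant column {el}: scaling undefined")
        mu = float(lv.mean()) if center else 0.0
        log2_scaled[el] = (lv - mu) / sd
        sds[el] = sd
        centers[el] = mu

        # tertiles by stable rank: deterministic under ties
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(len(vals), dtype=int)
        ranks[order] = np.arange(len(vals))
        n = len(vals)
        edges = [round(n / 3), round(2 * n / 3)]
        codes = np.digitize(ranks, edges)
        tert[el] = codes
        qs = np.quantile(vals, [1 / 3, 2 / 3])
        cuts[el] = (float(qs[0]), float(qs[1]))
    return ExposureTransform(
        log2_scaled=log2_scaled, tertile=tert, scale_sd=sds, center=centers,
        cut_points=cuts,
    )


@dataclass
class PreprocessResult:
    growth: pd.DataFrame
    exposures: ExposureTransform
    exclusions: pd.DataFrame  # subject_id, reason

    @property
    def n_subjects(self) -> int:
        return self.growth["subject_id"].nunique()


def run_preprocess(
    growth: pd.DataFrame,
    exposure_raw: pd.DataFrame,
    schedule: tuple[float, ...] = VISIT_SCHEDULE,
) -> PreprocessResult:
    """Apply the exclusion cascade and exposure transforms.

    Cascade order mirrors the study accounting: (1) per-visit +/-4 SD
    weight-for-length outliers, (2) three-or-fewer measures. The exposure
    transforms are computed on the analytic sample that survives both
    filters, and the exclusion log records one row per dropped subject.
    """
    g = growth if "wfl" in growth.columns else compute_wfl(growth)
    g = assign_nominal_visits(g, schedule)
    g1, out_ids = filter_outliers(g)
    g2, few_ids = filter_min_measures(g1)
    excl = pd.DataFrame(
        [(s, "wfl_outlier_4sd") for s in out_ids]
        + [(s, "le3_measures") for s in few_ids],
        columns=["subject_id", "reason"],
    )
    keep = g2["subject_id"].unique()
    raw = exposure_raw.set_index("subject_id").loc[keep].reset_index()
    tx = transform_exposures(raw.set_index("subject_id"))
    logger.info(
        "preprocess: %d outlier exclusions, %d few-measure exclusions, %d kept",
        len(out_ids), len(few_ids), len(keep),
    )
    return PreprocessResult(growth=g2, exposures=tx, exclusions=excl)
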