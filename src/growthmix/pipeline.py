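"""End-to-end orchestration: simulate/load -> preprocess -> knots -> per-sex
class sweep -> selection -> reference naming -> effect tables -> mixture.

Every stage delegates to the library modules; this module only wires data,
writes artifacts under a run directory, and records a manifest (config hash,
seeds, versions) so each output table is traceable. Sex strata never share
fitted parameters. Model non-convergence is recorded in the outputs, not
raised — only configuration or data errors abort a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import ELEMENTS, run_preprocess
from .splines import SplineSpec, select_knots
from .gmm import (GMMSpec, fit_gmm, add_vcov, modal_assignment,
                  select_model)
from .reference import ReferenceChart, class_median_curves, select_reference
from .effects import (Contrast, doubling_contrast, rrr_onestep, rrr_twostage,
                      cohens_kappa, linear_z_regression, bmi_interaction_twostage)
from .qgc import quantize, qgc_fit
from .simulate import SimConfig, CohortData, generate_cohort

logger = logging.getLogger(__name__)

COVARIATE_TERMS = ("maternal_age", "education", "married", "smoke_exposed",
                   "fish_intake", "prepreg_bmi", "primiparous")
TOXIC = ("As", "Hg", "Pb")
ESSENTIAL = ("Cu", "Mn", "Se")


@dataclass
class PipelineConfig:
    """Run configuration; either input CSV paths or a simulation config."""

    input_dir: str | None = None       # directory with growth/exposures/covariates CSVs
    sim: SimConfig | None = None
    chart_path: str | None = None      # growth-standard chart CSV; synthetic if None
    sex_strata: tuple[str, ...] = ("male", "female")
    K_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    knot_mode: str = "fixed"           # fixed | select2 | select3
    n_starts: int = 20
    qgc_q: int = 4
    qgc_B: int = 500
    weight_channel: bool = True        # also fit weight trajectories for naming
    covariate_terms: tuple[str, ...] = COVARIATE_TERMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dir is None and self.sim is None:
            raise ValueError("either input_dir or sim must be given")
        if self.knot_mode not in ("fixed", "select2", "select3"):
            raise ValueError(f"unknown knot_mode {self.knot_mode!r}")
        if not set(self.K_range) <= set(range(1, 7)):
            raise ValueError("K_range must lie within 1..6")

    def to_yaml_text(self) -> str:
        d = asdict(self)
        if d["sim"] is not None:
            for key in ("class_membership_coefs", "class_mean_coefs", "element_corr"):
                if d["sim"][key] is not None:
                    d["sim"][key] = np.asarray(d["sim"][key]).tolist()
        return yaml.safe_dump(d, sort_keys=True, default_flow_style=None)


def _load_cohort(config: PipelineConfig) -> CohortData:
    if config.input_dir is not None:
        return CohortData.load(config.input_dir)
    return generate_cohort(config.sim)


def _choose_spline(growth: pd.DataFrame, mode: str) -> SplineSpec:
    if mode == "fixed":
        return SplineSpec(knots=(3.5, 9.0))
    n_knots = 2 if mode == "select2" else 3
    grid = np.arange(1.0, 15.0 + 1e-9, 0.5 if n_knots == 2 else 1.0)
    return select_knots(growth["age"].to_numpy(), growth["wfl"].to_numpy(),
                        n_knots=n_knots, grid=grid)


def _fit_sweep(growth, subjects, spline, terms, K_range, n_starts, seed,
               outcome="wfl"):
    fits = {}
    for K in K_range:
        spec = GMMSpec(K=K, spline=spline, membership_terms=terms,
                       n_starts=n_starts, seed=seed + 101 * K)
        fits[K] = fit_gmm(growth, subjects, spec, outcome=outcome)
    return fits


def _subject_table(cohort: CohortData, tx) -> pd.DataFrame:
    """Per-subject analysis columns: transformed exposures + covariates."""
    sub = cohort.covariates.set_index("subject_id").copy()
    for el in ELEMENTS:
        sub[f"{el}_l2s"] = tx.log2_scaled[el]
        sub[f"{el}_tert_low"] = (tx.tertile[el] == 0).astype(float)
        sub[f"{el}_tert_high"] = (tx.tertile[el] == 2).astype(float)
    return sub


def prepare_analysis(cohort: CohortData):
    """Preprocess a cohort and build the per-subject analysis table.

    Returns (growth, subjects, preprocess_result): the filtered long growth
    table with nominal visits, and a subject-indexed frame holding the
    covariates plus transformed exposure columns (``<El>_l2s`` standardized
    log2, ``<El>_tert_low`` / ``<El>_tert_high`` tertile indicators).
    """
    pre = run_preprocess(cohort.growth, cohort.exposures)
    subjects = _subject_table(cohort, pre.exposures)
    keep = pre.growth["subject_id"].unique()
    return pre.growth, subjects.loc[keep], pre


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full analysis; returns the run directory with all artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml_text()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "growthmix_version": __version__,
    }
    (out / "config.yaml").write_text(cfg_text)

    cohort = _load_cohort(config)
    pre = run_preprocess(cohort.growth, cohort.exposures)
    pre.exclusions.to_csv(out / "exclusions.csv", index=False)
    manifest["n_subjects_analytic"] = int(pre.n_subjects)
    manifest["exclusions"] = pre.exclusions.groupby("reason").size().to_dict()

    subjects = _subject_table(cohort, pre.exposures)
    growth = pre.growth

    if config.chart_path is not None:
        chart_df = pd.read_csv(config.chart_path)
    else:
        from .simulate import synthetic_weight_chart
        chart_df = pd.concat([synthetic_weight_chart(s) for s in ("male", "female")])

    for sex in config.sex_strata:
        sdir = out / sex
        sdir.mkdir(exist_ok=True)
        g = growth[growth["sex"] == sex]
        ids = g["subject_id"].unique()
        sub = subjects.loc[ids]
        spline = _choose_spline(g, config.knot_mode)
        manifest[f"{sex}_knots"] = list(spline.knots)
        manifest[f"{sex}_n"] = int(len(ids))

        # class sweep on weight-for-length with the Hg doubling term as the
        # membership exposure (primary continuous exposure)
        terms = ("Hg_l2s",) + config.covariate_terms
        fits = _fit_sweep(g, sub, spline, terms, config.K_range,
                          config.n_starts, config.seed)
        report = select_model(fits)
        report.table.to_csv(sdir / "selection.csv", index=False)
        if report.chosen_K is None:
            logger.warning("%s: no model satisfies the selection rules", sex)
            continue
        fit = fits[report.chosen_K]
        add_vcov(fit)
        fit.save(sdir / "model.json")
        assign = modal_assignment(fit.posterior, fit.subject_ids)

        # reference naming on the weight channel (chart is weight-for-age),
        # transferred to the wfl classes via their agreement
        chart = ReferenceChart.from_frame(chart_df, sex)
        if config.weight_channel:
            wspec = GMMSpec(K=report.chosen_K, spline=spline,
                            membership_terms=terms, n_starts=config.n_starts,
                            seed=config.seed + 7)
            wfit = fit_gmm(g, sub, wspec, outcome="weight")
            wassign = modal_assignment(wfit.posterior, wfit.subject_ids)
            med = class_median_curves(wassign, g, outcome="weight")
            ssd = select_reference(med, chart)
            kap, kci = cohens_kappa(wassign.class_index, assign.class_index,
                                    align=False)
            manifest[f"{sex}_kappa_weight_vs_wfl"] = [kap, *kci]
        else:
            med = class_median_curves(assign, g, outcome="weight")
            ssd = select_reference(med, chart)
        ssd.detail.to_csv(sdir / "ssd_detail.csv", index=False)
        (sdir / "reference.json").write_text(json.dumps({
            "ssd": {int(k): float(v) for k, v in ssd.ssd.items()},
            "reference_class": ssd.reference_class,
            "labels": {int(k): v for k, v in ssd.labels.items()},
        }, indent=1))
        labels = ssd.labels
        reference = ssd.reference_class
        assign.with_labels(labels).df.to_csv(sdir / "assignments.csv", index=False)

        # effect tables
        tables = []
        for el in TOXIC:
            c = doubling_contrast(el, pre.exposures.scale_sd[el])
            if el in terms or f"{el}_l2s" in terms:
                tables.append(rrr_onestep(fit, c, reference, labels))
            else:
                # refit with this element as the membership exposure
                spec_el = GMMSpec(K=report.chosen_K, spline=spline,
                                  membership_terms=(f"{el}_l2s",) + config.covariate_terms,
                                  n_starts=config.n_starts, seed=config.seed + 13)
                efit = fit_gmm(g, sub, spec_el)
                if efit.converged:
                    add_vcov(efit)
                tables.append(rrr_onestep(efit, c, reference, labels))
            tables.append(rrr_twostage(assign, sub.reset_index(), c,
                                       config.covariate_terms, reference, labels))
        for el in ESSENTIAL:
            for kind, col in (("tertile_low_vs_mid", f"{el}_tert_low"),
                              ("tertile_high_vs_mid", f"{el}_tert_high")):
                c = Contrast(kind=kind, element=el, term=col, delta=1.0)
                tables.append(rrr_twostage(assign, sub.reset_index(), c,
                                           config.covariate_terms, reference, labels))
        effects = pd.concat(tables, ignore_index=True)
        effects["sex"] = sex
        effects.to_csv(sdir / "effects.csv", index=False)

        # 18-month z-score sensitivity outcome (synthetic LMS chart if none)
        try:
            from .simulate import synthetic_wfl_chart
            zchart = ReferenceChart.from_frame(synthetic_wfl_chart(sex), sex)
            from .reference import zscores_at_visit
            z18 = zscores_at_visit(g, zchart, visit=18.0)
            if len(z18) > 30:
                zrows = []
                for el in TOXIC:
                    zrows.append(linear_z_regression(
                        z18, sub.reset_index(), (f"{el}_l2s",),
                        config.covariate_terms))
                pd.concat(zrows, ignore_index=True).assign(sex=sex).to_csv(
                    sdir / "zscore_effects.csv", index=False)
        except Exception as exc:
            logger.warning("%s: z-score stage skipped: %s", sex, exc)

        # BMI interaction screen (two-stage)
        irows = []
        for el in TOXIC:
            c = doubling_contrast(el, pre.exposures.scale_sd[el])
            irows.append(bmi_interaction_twostage(
                assign, sub.reset_index(), c, config.covariate_terms, reference))
        pd.concat(irows, ignore_index=True).assign(sex=sex).to_csv(
            sdir / "interactions.csv", index=False)

        # mixture analysis
        raw = cohort.exposures.set_index("subject_id").loc[ids, list(ELEMENTS)]
        qz = quantize(raw, q=config.qgc_q)
        aligned = assign.df.set_index("subject_id").loc[ids, "class_index"]
        covs = sub.loc[ids, list(config.covariate_terms)]
        try:
            mix = qgc_fit(qz, aligned.to_numpy(), covs, reference=reference,
                          B=config.qgc_B, seed=config.seed + 1000, labels=labels)
            mix.effects.assign(sex=sex).to_csv(sdir / "mixture_effects.csv", index=False)
            mix.weights.assign(sex=sex).to_csv(sdir / "mixture_weights.csv", index=False)
        except Exception as exc:
            logger.warning("%s: mixture stage failed: %s", sex, exc)
            manifest[f"{sex}_mixture_error"] = str(exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
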