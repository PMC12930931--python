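"""Synthetic mother-infant cohort generator with known latent structure.

Emulates the statistical structure of a prenatal-exposure / infant-growth
study: ~783 dyads, four latent weight-for-length trajectory classes with
quadratic-spline mean curves, a shared Gaussian random intercept, visit-level
measurement noise, correlated log-normal toenail element concentrations
(As, Hg, Pb, Cu, Mn, Se) with realistic detection limits, and the usual
adjustment covariates. Class membership follows a multinomial logit of the
standardized log2 exposures and covariates, so the true relative risk ratio
per doubling is available analytically for every generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .preprocess import ELEMENTS, VISIT_SCHEDULE, censor_at_lod
from .splines import SplineSpec, basis_matrix

__all__ = [
    "SimConfig", "CohortData", "generate_cohort", "default_calibration",
    "censor_at_lod", "length_curve", "synthetic_weight_chart",
    "synthetic_wfl_chart",
]

#: detection limits, ug/g, typical of toenail ICP-MS panels
DEFAULT_LODS = {
    "As": 0.023, "Hg": 0.031, "Pb": 0.009, "Cu": 0.105, "Mn": 0.038, "Se": 0.013,
}


@dataclass
class SimConfig:
    """Full description of one synthetic cohort's generating process.

    ``class_membership_coefs`` has one row per class (row 0 the logit
    reference, forced to zero) and one column per entry of
    ``membership_columns`` (an intercept plus any of the exposure columns,
    named ``<El>_l2s`` for standardized log2 concentration, and covariate
    columns). ``class_mean_coefs`` holds spline coefficients (g/cm) w.r.t.
    ``basis_matrix`` on the given knots.
    """

    n_subjects: int = 783
    sex_ratio: float = 0.494            # proportion male
    K_true: int = 4
    membership_columns: tuple[str, ...] = ("const", "Hg_l2s", "primiparous")
    class_membership_coefs: np.ndarray = None  # (K, len(columns))
    class_mean_coefs: np.ndarray = None        # (K, n_basis)
    knots: tuple[float, ...] = (3.5, 9.0)
    random_intercept_sd: float = 6.0    # g/cm
    residual_sd: float = 5.0            # g/cm
    visit_schedule: tuple[float, ...] = VISIT_SCHEDULE
    visit_jitter_sd: float = 0.25       # months
    missing_visit_prob: float = 0.08
    element_log_means: dict = None      # natural-log scale, ug/g
    element_log_sds: dict = None
    element_corr: np.ndarray = None     # log-scale correlation, element order
    lods: dict = field(default_factory=lambda: dict(DEFAULT_LODS))
    covariate_specs: dict = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_membership_coefs is not None:
            self.class_membership_coefs = np.asarray(self.class_membership_coefs, float)
        if self.class_mean_coefs is not None:
            self.class_mean_coefs = np.asarray(self.class_mean_coefs, float)
        if self.element_corr is not None:
            self.element_corr = np.asarray(self.element_corr, float)
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be a probability")
        if not 0 <= self.missing_visit_prob <= 1:
            raise ValueError("missing_visit_prob must be a probability")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be nonnegative")
        sched = np.asarray(self.visit_schedule)
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("visit_schedule must start at 0 and strictly increase")
        if self.element_corr is not None:
            C = self.element_corr
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("element_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("element_corr must be positive definite")
        if self.class_mean_coefs is not None:
            rows = [tuple(r) for r in np.round(self.class_mean_coefs, 10)]
            if len(set(rows)) != len(rows):
                raise ValueError("class mean curves must be distinct")

    @property
    def spline(self) -> SplineSpec:
        return SplineSpec(knots=tuple(self.knots))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("class_membership_coefs", "class_mean_coefs", "element_corr"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        for key in ("membership_columns", "knots", "visit_schedule"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("membership_columns", "knots", "visit_schedule"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortData:
    """Three linked tables plus the generating truth."""

    growth: pd.DataFrame       # subject_id, sex, age, weight, length, wfl
    exposures: pd.DataFrame    # subject_id, <El>, below_lod_<El>
    covariates: pd.DataFrame
    truth: pd.DataFrame | None = None   # subject_id, true_class, true_intercept

    def save(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.growth.to_csv(out / "growth.csv", index=False)
        self.exposures.to_csv(out / "exposures.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def load(cls, indir) -> "CohortData":
        from pathlib import Path
        p = Path(indir)
        truth = p / "truth.csv"
        return cls(
            growth=pd.read_csv(p / "growth.csv"),
            exposures=pd.read_csv(p / "exposures.csv"),
            covariates=pd.read_csv(p / "covariates.csv"),
            truth=pd.read_csv(truth) if truth.exists() else None,
        )


# ---------------------------------------------------------------------------
# pieces of the generating process


def length_curve(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Deterministic sex-specific median length (cm), ~50 -> ~82 over 0-18 mo.

    A saturating-exponential ("logistic-shaped") curve; male infants run
    about 1 cm longer. Length realism is secondary here — the analysis uses
    weight and weight-for-length — so no individual length variation is
    generated and weight is back-derived as wfl * length / 1000.
    """
    age = np.asarray(age, float)
    frac = (1.0 - np.exp(-0.16 * age)) / (1.0 - np.exp(-0.16 * 18.0))
    base = 50.0 + 32.0 * frac
    return base + np.where(np.asarray(sex) == "male", 0.5, -0.5)


_CAL_AGES = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 12.0, 15.0, 18.0])

#: per-class target weight-for-length (g/cm) at the nominal visits; classes
#: ordered slow / late-moderate / stable-moderate / rapid
_CAL_CURVES = {
    "stable_slow":     [68.5, 73, 78, 87, 100, 108, 114, 118, 120, 122],
    "late_moderate":   [66.5, 72, 77, 86, 100, 109, 120, 130, 136, 141],
    "stable_moderate": [69.5, 76, 83, 93, 109, 119, 128, 133, 137, 140],
    "rapid":           [64.0, 70, 77, 89, 107, 120, 133, 141, 146, 150],
}

#: class shares emulating observed group sizes 252/153/284/94 of 783
_CAL_SHARES = np.array([252, 153, 284, 94]) / 783.0

#: element medians (ug/g) and IQRs typical of toenail panels
_CAL_MEDIANS = {"As": 0.05, "Hg": 0.08, "Pb": 0.11, "Cu": 3.90, "Mn": 0.31, "Se": 1.00}
_CAL_IQRS = {
    "As": (0.04, 0.09), "Hg": (0.03, 0.14), "Pb": (0.055, 0.22),
    "Cu": (3.30, 4.70), "Mn": (0.16, 0.63), "Se": (0.91, 1.09),
}


def _curve_to_coefs(targets: np.ndarray, spline: SplineSpec) -> np.ndarray:
    X = basis_matrix(_CAL_AGES, spline)
    return np.linalg.lstsq(X, np.asarray(targets, float), rcond=None)[0]


def default_calibration(n_subjects: int = 783, seed: int = 0) -> SimConfig:
    """The default study-like generating configuration.

    Log-normal exposure parameters are set so medians and IQR spreads match
    typical toenail concentrations (median = exp(mu); sigma from the IQR of
    a log-normal, log(q75/q25) = 2 * 0.6745 * sigma); log-scale correlations
    lie in [0.1, 0.45] with the Cu-Mn pair weakest (0.12) and Mn-Pb
    strongest (0.41). Class shares approximate (0.32, 0.20, 0.36, 0.12) and
    a modest mercury effect pushes the late-moderate and rapid classes.
    """
    spline = SplineSpec(knots=(3.5, 9.0))
    beta = np.vstack([
        _curve_to_coefs(_CAL_CURVES[k], spline)
        for k in ("stable_slow", "late_moderate", "stable_moderate", "rapid")
    ])
    log_means = {el: float(np.log(_CAL_MEDIANS[el])) for el in ELEMENTS}
    log_sds = {
        el: float(np.log(_CAL_IQRS[el][1] / _CAL_IQRS[el][0]) / (2 * 0.6745))
        for el in ELEMENTS
    }
    C = np.full((6, 6), 0.25)
    np.fill_diagonal(C, 1.0)
    idx = {el: i for i, el in enumerate(ELEMENTS)}
    for a, b, r in [("Cu", "Mn", 0.12), ("Mn", "Pb", 0.41), ("As", "Hg", 0.30),
                    ("Pb", "Cu", 0.18), ("Hg", "Se", 0.35), ("As", "Pb", 0.22)]:
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    # membership: intercepts reproduce the target shares at covariate means;
    # Hg raises late-moderate/rapid odds; primiparity raises rapid odds
    gamma = np.zeros((4, 3))
    gamma[:, 0] = np.log(_CAL_SHARES / _CAL_SHARES[0])
    gamma[1, 1] = np.log(1.5)   # Hg_l2s on late-moderate, per SD of log2
    gamma[3, 1] = np.log(1.4)   # Hg_l2s on rapid
    gamma[3, 2] = np.log(1.8)   # primiparous on rapid
    # offset intercepts for the mean lift the nonzero terms induce, keeping
    # marginal shares near the targets: E[e^{gZ}] = e^{g^2/2} for Z~N(0,1),
    # E[e^{gX}] ~ 1 + p(e^g - 1) for X~Bern(p)
    gamma[1, 0] -= gamma[1, 1] ** 2 / 2
    gamma[3, 0] -= gamma[3, 1] ** 2 / 2 + np.log(1 + 0.43 * (1.8 - 1))
    covariate_specs = {
        "maternal_age": {"dist": "normal", "mean": 31.6, "sd": 4.5, "lo": 18, "hi": 45},
        "education": {"dist": "categorical", "probs": [0.10, 0.59, 0.31]},
        "married": {"dist": "bernoulli", "p": 0.895},
        "smoke_exposed": {"dist": "bernoulli", "p": 0.18},
        "fish_intake": {"dist": "categorical", "probs": [0.22, 0.63, 0.15]},
        "prepreg_bmi": {"dist": "normal", "mean": 25.8, "sd": 5.4, "lo": 15, "hi": 55},
        "primiparous": {"dist": "bernoulli", "p": 0.43},
    }
    return SimConfig(
        n_subjects=n_subjects,
        K_true=4,
        class_membership_coefs=gamma,
        class_mean_coefs=beta,
        element_log_means=log_means,
        element_log_sds=log_sds,
        element_corr=C,
        covariate_specs=covariate_specs,
        seed=seed,
    )


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    cols = {}
    for name, spec in cfg.covariate_specs.items():
        kind = spec["dist"]
        if kind == "normal":
            v = rng.normal(spec["mean"], spec["sd"], n)
            v = np.clip(v, spec.get("lo", -np.inf), spec.get("hi", np.inf))
        elif kind == "bernoulli":
            v = (rng.random(n) < spec["p"]).astype(int)
        elif kind == "categorical":
            v = rng.choice(len(spec["probs"]), size=n, p=spec["probs"])
        else:
            raise ValueError(f"unknown covariate distribution {kind}")
        cols[name] = v
    df = pd.DataFrame(cols)
    df["bmi_ge_25"] = (df["prepreg_bmi"] >= 25).astype(int)
    return df


def generate_cohort(config: SimConfig) -> CohortData:
    """Simulate one cohort from the latent-class growth model.

    Deterministic given the config seed. Steps: draw covariates; draw
    correlated log-normal exposures through a Gaussian copula; form the
    membership design (standardized log2 exposures + covariates); draw the
    true class from the multinomial logit; draw the random intercept; for
    each retained visit draw a jittered age (birth never jittered and never
    missing) and a weight-for-length value on the class spline curve plus
    intercept plus residual noise; back-derive weight from the deterministic
    length curve so weight/length reproduces the simulated g/cm value.
    """
    cfg = config
    cfg.validate()
    if cfg.element_corr is None or cfg.class_mean_coefs is None:
        raise ValueError("config missing calibration blocks; see default_calibration()")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    ids = np.array([f"S{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < cfg.sex_ratio, "male", "female")

    cov = _draw_covariates(cfg, rng)
    cov.insert(0, "subject_id", ids)
    cov.insert(1, "sex", sex)

    # exposures: Gaussian copula -> lognormal marginals
    L = np.linalg.cholesky(cfg.element_corr)
    Z = rng.standard_normal((n, len(ELEMENTS))) @ L.T
    raw = pd.DataFrame(
        {el: np.exp(cfg.element_log_means[el] + cfg.element_log_sds[el] * Z[:, i])
         for i, el in enumerate(ELEMENTS)},
        index=pd.Index(ids, name="subject_id"),
    )
    censored, flags = censor_at_lod(raw, cfg.lods)
    exposures = censored.reset_index()
    for el in ELEMENTS:
        exposures[f"below_lod_{el}"] = flags[el].to_numpy()

    # membership design on the analysis scale: log2 then / sample SD
    design_cols = {"const": np.ones(n)}
    for el in ELEMENTS:
        lv = np.log2(censored[el].to_numpy())
        # centred and scaled; centring leaves the per-doubling effect
        # exp(coef / SD_log2) untouched but keeps intercepts interpretable
        design_cols[f"{el}_l2s"] = (lv - lv.mean()) / np.std(lv, ddof=1)
    for c in cov.columns.drop(["subject_id", "sex"]):
        design_cols[c] = cov[c].to_numpy(dtype=float)
    Wm = np.column_stack([design_cols[c] for c in cfg.membership_columns])
    eta = Wm @ cfg.class_membership_coefs.T
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    true_class = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    b_i = rng.normal(0.0, cfg.random_intercept_sd, n)

    sched = np.asarray(cfg.visit_schedule, float)
    spline = cfg.spline
    rows = []
    for i in range(n):
        keep = rng.random(len(sched)) >= cfg.missing_visit_prob
        keep[0] = True  # birth record always abstracted
        ages = sched[keep].copy()
        jit = rng.normal(0.0, cfg.visit_jitter_sd, len(ages))
        jit[ages == 0.0] = 0.0
        ages = np.clip(ages + jit, 0.0, 18.0)
        Xi = basis_matrix(ages, spline)
        wfl = Xi @ cfg.class_mean_coefs[true_class[i]] + b_i[i]
        wfl = wfl + rng.normal(0.0, cfg.residual_sd, len(ages))
        rows.append(pd.DataFrame({
            "subject_id": ids[i], "sex": sex[i], "age": ages, "wfl": wfl,
        }))
    growth = pd.concat(rows, ignore_index=True)
    growth["length"] = length_curve(growth["age"], growth["sex"])
    growth["weight"] = growth["wfl"] * growth["length"] / 1000.0
    growth = growth[["subject_id", "sex", "age", "weight", "length", "wfl"]]

    truth = pd.DataFrame({
        "subject_id": ids, "true_class": true_class, "true_intercept": b_i,
    })
    for i, c in enumerate(cfg.membership_columns):
        if c != "const":
            truth[c] = Wm[:, i]
    return CohortData(growth=growth, exposures=exposures, covariates=cov, truth=truth)


# ---------------------------------------------------------------------------
# synthetic growth-standard charts (stand-ins for user-supplied chart files)


def synthetic_weight_chart(sex: str = "male") -> pd.DataFrame:
    """SYNTHETIC weight-for-age chart (kg by age in months) for tests/demos.

    Built from the slow-trajectory calibration curve times the deterministic
    length curve, so the slowest synthetic class tracks it closely — a
    stand-in for a real growth-standard chart, which users supply as CSV.
    Columns: sex, index_kind, index, L, M, S.
    """
    ages = _CAL_AGES
    wfl = np.asarray(_CAL_CURVES["stable_slow"], float)
    M = wfl * length_curve(ages, np.repeat(sex, len(ages))) / 1000.0
    return pd.DataFrame({
        "sex": sex, "index_kind": "age_months", "index": ages,
        "L": 1.0, "M": M, "S": 0.11,
    })


def synthetic_wfl_chart(sex: str = "male") -> pd.DataFrame:
    """SYNTHETIC weight-for-length-style LMS chart indexed by age (months).

    M follows the cohort-average calibration curve; used for z-score
    sensitivity outcomes in tests and demonstrations.
    """
    ages = _CAL_AGES
    curves = np.vstack([_CAL_CURVES[k] for k in _CAL_CURVES])
    M = _CAL_SHARES @ curves
    return pd.DataFrame({
        "sex": sex, "index_kind": "age_months", "index": ages,
        "L": 1.0, "M": M, "S": 0.09,
    })
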