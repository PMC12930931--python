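"""Exposure-trajectory association estimates.

One-step relative risk ratios (RRRs) read off the fitted membership
submodel of the growth mixture model — under the multinomial logit the
ratio-of-relative-risks definition

    RRR_j = [P(j | shifted exposure) / P(j | exposure)] /
            [P(ref | shifted exposure) / P(ref | exposure)]

reduces exactly to exp(delta * (gamma_j - gamma_ref)) for the shifted term,
independent of the covariate vector; the reduction is verified numerically
on every call. Two-stage comparators regress modal assignments with a
separate multinomial logistic model; agreement between assignment vectors
is quantified by Cohen's kappa; attained-size sensitivity analyses use OLS
on 18-month z-scores; effect modification by maternal weight status enters
through cross-product terms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import softmax
from scipy.stats import norm

from .gmm import FittedGMM, TrajectoryAssignment, gamma_index

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class Contrast:
    """An exposure contrast on the membership-model scale.

    ``delta`` is the change in the model term: for a doubling of a raw
    concentration entering as standardized log2, delta = 1 / scale_sd; for
    tertile indicator terms, delta = 1.
    """

    kind: str                  # doubling | tertile_low_vs_mid | tertile_high_vs_mid | quartile_shift
    element: str
    term: str                  # membership-model column the contrast shifts
    delta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta) or self.delta == 0:
            raise ValueError("delta must be finite and nonzero")


def doubling_contrast(element: str, scale_sd: float) -> Contrast:
    """Contrast for a doubling of concentration of a log2-scaled term."""
    return Contrast(kind="doubling", element=element,
                    term=f"{element}_l2s", delta=1.0 / scale_sd)


def _effect_row(class_k, contrast, est, lo, hi, method, converged=True, **extra):
    return {
        "class": class_k, "element": contrast.element, "contrast": contrast.kind,
        "estimate": est, "lo95": lo, "hi95": hi, "method": method,
        "converged": converged, **extra,
    }


def _verify_probability_ratio(
    fit: FittedGMM, contrast: Contrast, reference: int, n_grid: int = 8,
    rng_seed: int = 0, atol: float = 1e-10,
) -> None:
    """Check exp(gamma * delta) equals the displayed probability-ratio RRR.

    Evaluates the ratio of predicted membership probabilities at the base
    and shifted exposure for random covariate vectors; the identity is exact
    under the logit link, so disagreement indicates an implementation bug.
    """
    terms = ["const", *fit.spec.membership_terms]
    j = terms.index(contrast.term)
    rng = np.random.default_rng(rng_seed)
    W = rng.normal(0, 1, (n_grid, len(terms)))
    W[:, 0] = 1.0
    Wshift = W.copy()
    Wshift[:, j] += contrast.delta
    P = softmax(W @ fit.gamma.T, axis=1)
    Ps = softmax(Wshift @ fit.gamma.T, axis=1)
    gd = fit.gamma_vs_reference(reference)[:, j]
    for k in range(fit.K):
        if k == reference:
            continue
        ratio = (Ps[:, k] / P[:, k]) / (Ps[:, reference] / P[:, reference])
        expected = np.exp(contrast.delta * gd[k])
        err = np.max(np.abs(ratio - expected) / expected)
        if err > atol:
            raise AssertionError(
                f"probability-ratio identity violated for class {k}: {err:.2e}")


def rrr_onestep(
    fit: FittedGMM, contrast: Contrast, reference: int = 0,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """RRR with 95% Wald CI per non-reference class from the fitted GMM.

    Point estimate exp(delta * (gamma_j - gamma_ref)) for the contrast term;
    the SE comes from the observed-information covariance of the free
    membership coefficients (delta method on the log scale). Non-converged
    fits yield flagged rows without estimates.
    """
    if contrast.term not in fit.spec.membership_terms:
        raise ValueError(f"term {contrast.term!r} not in the membership submodel")
    rows = []
    if not fit.converged:
        for k in range(fit.K):
            if k == reference:
                continue
            rows.append(_effect_row(k, contrast, np.nan, np.nan, np.nan,
                                    "one_step", converged=False))
        return _finish(rows, labels)

    _verify_probability_ratio(fit, contrast, reference)
    if fit.vcov is None:
        raise ValueError("fit lacks vcov; call add_vcov first")
    gd = fit.gamma_vs_reference(reference)
    terms = ["const", *fit.spec.membership_terms]
    j = terms.index(contrast.term)
    for k in range(fit.K):
        if k == reference:
            continue
        logrrr = contrast.delta * gd[k, j]
        var = 0.0
        if k >= 1:
            ik = gamma_index(fit, k, contrast.term)
            var += fit.vcov[ik, ik]
        if reference >= 1:
            ir = gamma_index(fit, reference, contrast.term)
            var += fit.vcov[ir, ir]
            if k >= 1:
                var -= 2 * fit.vcov[ik, ir]
        se = abs(contrast.delta) * np.sqrt(max(var, 0.0))
        rows.append(_effect_row(
            k, contrast, float(np.exp(logrrr)),
            float(np.exp(logrrr - Z95 * se)), float(np.exp(logrrr + Z95 * se)),
            "one_step",
        ))
    return _finish(rows, labels)


def _finish(rows, labels):
    df = pd.DataFrame(rows)
    if labels:
        df.insert(1, "label", df["class"].map(labels))
    return df


# ---------------------------------------------------------------------------
# two-stage multinomial comparator


def fit_multinomial(
    endog: np.ndarray, exog: pd.DataFrame, maxiter: int = 200
) -> sm.MNLogit:
    """MNLogit wrapper; category 0 of ``endog`` is the base outcome."""
    model = sm.MNLogit(endog, exog.to_numpy(dtype=float))
    res = model.fit(method="newton", maxiter=maxiter, disp=0, full_output=True)
    return res


def rrr_twostage(
    assignments: TrajectoryAssignment,
    subjects: pd.DataFrame,
    contrast: Contrast,
    covariate_terms: tuple[str, ...],
    reference: int = 0,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """RRR from a separate multinomial logistic regression on modal classes.

    Ignores classification uncertainty by construction. The outcome is the
    modal class relabelled so the reference class is the model base; exog is
    an intercept, the contrast term, and the covariates; Wald CIs.
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    df = assignments.df[["subject_id", "class_index"]].merge(
        sub[list(dict.fromkeys([contrast.term, *covariate_terms]))],
        left_on="subject_id", right_index=True,
    )
    K = int(assignments.df["class_index"].max()) + 1
    order = [reference] + [k for k in range(K) if k != reference]
    remap = {orig: new for new, orig in enumerate(order)}
    endog = df["class_index"].map(remap).to_numpy()
    cols = [contrast.term, *covariate_terms]
    exog = sm.add_constant(df[cols], has_constant="add")
    rows = []
    try:
        res = fit_multinomial(endog, exog)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:        # separation / singularities
        logger.warning("two-stage multinomial failed: %s", exc)
        res, converged = None, False
    term_pos = list(exog.columns).index(contrast.term)
    for new_idx in range(1, K):
        orig = order[new_idx]
        if res is None or not converged:
            rows.append(_effect_row(orig, contrast, np.nan, np.nan, np.nan,
                                    "two_stage", converged=False))
            continue
        # params is (k_exog, K-1): column = non-base outcome category
        coef = np.asarray(res.params)[term_pos, new_idx - 1]
        se = np.asarray(res.bse)[term_pos, new_idx - 1]
        est = np.exp(contrast.delta * coef)
        halfw = Z95 * abs(contrast.delta) * se
        rows.append(_effect_row(
            orig, contrast, float(est),
            float(np.exp(contrast.delta * coef - halfw)),
            float(np.exp(contrast.delta * coef + halfw)),
            "two_stage",
        ))
    return _finish(rows, labels)


# ---------------------------------------------------------------------------
# agreement


def align_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Permute the categories of ``b`` to maximize diagonal agreement with ``a``."""
    cats = sorted(set(a) | set(b))
    best_perm, best_agree = None, -1
    for perm in itertools.permutations(cats):
        mapping = dict(zip(cats, perm))
        agree = int(np.sum(a == np.vectorize(mapping.get)(b)))
        if agree > best_agree:
            best_agree, best_perm = agree, mapping
    return np.vectorize(best_perm.get)(b)


def cohens_kappa(
    a: np.ndarray, b: np.ndarray, align: bool = False
) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) with a large-sample 95% CI.

    ``align=True`` first permutes the labels of ``b`` to best match ``a``
    (latent-class labels are arbitrary). Returns (kappa, (lo, hi)); a
    single observed category makes kappa undefined (NaN).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("assignment vectors differ in length")
    if align:
        b = align_labels(a, b)
    cats = sorted(set(a) | set(b))
    if len(cats) < 2:
        return float("nan"), (float("nan"), float("nan"))
    n = len(a)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p = table / n
    po = np.trace(p)
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe >= 1.0:
        return float("nan"), (float("nan"), float("nan"))
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return float(kappa), (float(kappa - Z95 * se), float(kappa + Z95 * se))


# ---------------------------------------------------------------------------
# 18-month z-score linear models


def linear_z_regression(
    z: pd.Series,
    subjects: pd.DataFrame,
    exposure_terms: tuple[str, ...],
    covariate_terms: tuple[str, ...],
) -> pd.DataFrame:
    """OLS of an attained z-score on exposure terms plus covariates.

    One row per exposure term with the coefficient and its Wald 95% CI.
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    cols = list(dict.fromkeys([*exposure_terms, *covariate_terms]))
    df = sub.loc[sub.index.intersection(z.index), cols].copy()
    df["_z"] = z.reindex(df.index)
    df = df.dropna()
    X = sm.add_constant(df[cols], has_constant="add")
    if len(df) <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    res = sm.OLS(df["_z"], X).fit()
    ci = res.conf_int()
    rows = [{
        "term": t, "estimate": float(res.params[t]),
        "lo95": float(ci.loc[t, 0]), "hi95": float(ci.loc[t, 1]),
        "p": float(res.pvalues[t]), "method": "linear_z", "n": int(len(df)),
    } for t in exposure_terms]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BMI effect modification


def add_interaction_column(
    subjects: pd.DataFrame, term: str, flag: str = "bmi_ge_25"
) -> tuple[pd.DataFrame, str]:
    """Append an element x weight-status cross-product column.

    The returned column name can be added to a GMMSpec's membership terms
    for a one-step interaction fit, or used in two-stage models.
    """
    out = subjects.copy()
    name = f"{term}_x_{flag}"
    out[name] = out[term] * out[flag]
    return out, name


def bmi_interaction_twostage(
    assignments: TrajectoryAssignment,
    subjects: pd.DataFrame,
    contrast: Contrast,
    covariate_terms: tuple[str, ...],
    reference: int = 0,
    bmi_flag: str = "bmi_ge_25",
) -> pd.DataFrame:
    """Wald test of an element x weight-status cross-product per class.

    Adds ``term * bmi_flag`` to the two-stage multinomial model and reports
    the interaction coefficient, CI, and p-value per non-reference class.
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    sub = sub.copy()
    inter = f"{contrast.term}_x_{bmi_flag}"
    sub[inter] = sub[contrast.term] * sub[bmi_flag]
    covs = tuple(dict.fromkeys([*covariate_terms, bmi_flag]))
    df = assignments.df[["subject_id", "class_index"]].merge(
        sub[list(dict.fromkeys([contrast.term, inter, *covs]))],
        left_on="subject_id", right_index=True,
    )
    K = int(assignments.df["class_index"].max()) + 1
    order = [reference] + [k for k in range(K) if k != reference]
    endog = df["class_index"].map({o: i for i, o in enumerate(order)}).to_numpy()
    cols = [contrast.term, inter, *covs]
    exog = sm.add_constant(df[cols], has_constant="add")
    rows = []
    try:
        res = fit_multinomial(endog, exog)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:
        logger.warning("interaction model failed: %s", exc)
        res, converged = None, False
    pos = list(exog.columns).index(inter)
    for new_idx in range(1, K):
        orig = order[new_idx]
        if res is None or not converged:
            rows.append(_effect_row(orig, contrast, np.nan, np.nan, np.nan,
                                    "interaction", converged=False, p=np.nan))
            continue
        coef = np.asarray(res.params)[pos, new_idx - 1]
        se = np.asarray(res.bse)[pos, new_idx - 1]
        z = coef / se if se > 0 else np.nan
        rows.append(_effect_row(
            orig, contrast, float(coef),
            float(coef - Z95 * se), float(coef + Z95 * se),
            "interaction", p=float(2 * norm.sf(abs(z))),
        ))
    return pd.DataFrame(rows)
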