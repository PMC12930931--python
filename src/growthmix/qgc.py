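"""Quantile-based g-computation for the six-element mixture.

Each exposure is scored by its sample quantile (quartiles by default). A
conditional multinomial-logit model of modal trajectory class on all scores
plus covariates is fit; g-computation then sets every score to a common
value s, averages the predicted class probabilities over subjects to get
the marginal risk r_j(s), and a log-linear marginal structural model
log r_j(s) = a_j + psi_j * s summarizes the joint effect. exp(psi_j) is the
risk ratio for simultaneously raising every exposure by one quantile;
signed weights decompose psi into per-element contributions summing to one
in each direction. Confidence intervals come from a nonparametric bootstrap
over subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class QuantizedExposures:
    """Integer quantile scores 0..q-1 per element, with the cut points used."""

    scores: pd.DataFrame
    q: int
    cut_points: dict[str, np.ndarray]
    degenerate: tuple[str, ...] = ()


def quantize(exposures: pd.DataFrame, q: int = 4) -> QuantizedExposures:
    """Score each element column by sample quantile membership.

    Cut points are ``np.quantile`` at i/q; a value scores s when it exceeds
    s of the cut points. Ties at a cut point are resolved by stable rank so
    group sizes stay as balanced as the tie structure allows. Columns with a
    single distinct value are flagged degenerate (all scores zero).
    """
    n = len(exposures)
    if q > n:
        raise ValueError(f"q={q} exceeds sample size {n}")
    scores = pd.DataFrame(index=exposures.index)
    cuts: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    probs = np.arange(1, q) / q
    for col in exposures.columns:
        v = exposures[col].to_numpy(dtype=float)
        cut = np.quantile(v, probs)
        cuts[col] = cut
        if np.unique(v).size == 1:
            degenerate.append(col)
            scores[col] = 0
            continue
        # strict comparison: values equal to a cut point score below it,
        # which together with stable sample quantiles makes ties deterministic
        s = (v[:, None] > cut[None, :]).sum(axis=1)
        scores[col] = s
    if degenerate:
        logger.warning("degenerate (constant) exposure columns: %s", degenerate)
    return QuantizedExposures(scores=scores, q=q, cut_points=cuts,
                              degenerate=tuple(degenerate))


@dataclass
class MixtureResult:
    """Joint mixture effect per non-reference class with signed weights."""

    effects: pd.DataFrame    # class, rr, lo95, hi95, psi, converged
    weights: pd.DataFrame    # class, element, weight, direction
    B: int
    q: int
    labels: dict[int, str] | None = None


def _conditional_fit(endog, exog, maxiter=200):
    import warnings as _warnings
    model = sm.MNLogit(endog, exog)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=maxiter, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(method="bfgs", maxiter=5 * maxiter, disp=0)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("conditional multinomial model did not converge")
    return res


def _psi_from_fit(res, exog_df, score_cols, K, q):
    """g-computation: marginal risks at common score s, then log-linear slope."""
    n = len(exog_df)
    risks = np.zeros((q, K))
    X = exog_df.copy()
    for s in range(q):
        X[list(score_cols)] = float(s)
        P = res.predict(X.to_numpy(dtype=float))      # (n, K)
        risks[s] = np.asarray(P).mean(axis=0)
    svec = np.arange(q, dtype=float)
    Sx = np.column_stack([np.ones(q), svec])
    psis = np.empty(K)
    for jcls in range(K):
        logr = np.log(np.maximum(risks[:, jcls], 1e-300))
        psis[jcls] = np.linalg.lstsq(Sx, logr, rcond=None)[0][1]
    return psis, risks


def qgc_fit(
    quantized: QuantizedExposures,
    assignments: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    reference: int = 0,
    B: int = 500,
    seed: int = 0,
    labels: dict[int, str] | None = None,
) -> MixtureResult:
    """Joint mixture effect on trajectory membership via g-computation.

    ``assignments`` are modal class indices aligned with the score rows;
    ``covariates`` the adjustment columns (same index). The reference class
    becomes the multinomial base. Per non-reference class j the result has
    RR_j = exp(psi_j) for a simultaneous one-quantile increase of all
    elements, a percentile bootstrap CI over ``B`` subject resamples, and
    the conditional-model coefficients converted to signed weights
    normalized to unit sum within each direction.
    """
    scores = quantized.scores.drop(columns=list(quantized.degenerate))
    if scores.shape[1] == 0:
        raise ValueError("no non-degenerate exposure columns")
    score_cols = list(scores.columns)
    y = np.asarray(assignments)
    K = int(y.max()) + 1
    order = [reference] + [k for k in range(K) if k != reference]
    remap = {orig: new for new, orig in enumerate(order)}
    endog = np.vectorize(remap.get)(y)
    exog = pd.concat([scores.reset_index(drop=True),
                      covariates.reset_index(drop=True)], axis=1)
    exog.insert(0, "const", 1.0)

    res = _conditional_fit(endog, exog.to_numpy(dtype=float))
    psis, _ = _psi_from_fit(res, exog, score_cols, K, quantized.q)

    # weights from the conditional score coefficients, per class, per direction
    params = np.asarray(res.params)       # (k_exog, K-1)
    cols = list(exog.columns)
    wrows = []
    for new_idx in range(1, K):
        coefs = {el: params[cols.index(el), new_idx - 1] for el in score_cols}
        pos_sum = sum(c for c in coefs.values() if c > 0)
        neg_sum = sum(-c for c in coefs.values() if c < 0)
        for el, c in coefs.items():
            if c > 0:
                wrows.append({"class": order[new_idx], "element": el,
                              "direction": "positive", "weight": c / pos_sum})
            elif c < 0:
                wrows.append({"class": order[new_idx], "element": el,
                              "direction": "negative", "weight": -c / neg_sum})
    weights = pd.DataFrame(wrows)

    # nonparametric bootstrap over subjects
    rng = np.random.default_rng(seed)
    n = len(endog)
    boot = np.full((B, K), np.nan)
    n_fail = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            rb = _conditional_fit(endog[idx], exog.to_numpy(dtype=float)[idx])
            boot[b], _ = _psi_from_fit(rb, exog.iloc[idx].reset_index(drop=True),
                                       score_cols, K, quantized.q)
        except Exception:
            n_fail += 1
    if n_fail:
        logger.warning("bootstrap: %d/%d resamples failed", n_fail, B)

    erows = []
    for new_idx in range(1, K):
        draws = boot[:, new_idx]
        draws = draws[np.isfinite(draws)]
        lo, hi = (np.percentile(draws, [2.5, 97.5]) if draws.size
                  else (np.nan, np.nan))
        erows.append({
            "class": order[new_idx], "psi": float(psis[new_idx]),
            "rr": float(np.exp(psis[new_idx])),
            "lo95": float(np.exp(lo)), "hi95": float(np.exp(hi)),
            "n_boot_ok": int(draws.size), "converged": True,
        })
    effects = pd.DataFrame(erows).sort_values("class").reset_index(drop=True)
    if labels:
        effects.insert(1, "label", effects["class"].map(labels))
        if not weights.empty:
            weights.insert(1, "label", weights["class"].map(labels))
    return MixtureResult(effects=effects, weights=weights, B=B, q=quantized.q,
                         labels=labels)
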