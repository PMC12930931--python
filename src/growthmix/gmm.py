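"""Latent-class growth mixture model with covariate-dependent membership.

The model: subject i with outcome vector y_i (weight-for-length, g/cm) at
ages t_i and spline design X_i belongs to latent class k with probability

    pi_ik = softmax_k( w_i' gamma_k ),   gamma_1 = 0 (reference row),

where w_i = (1, membership terms). Conditional on class k,

    y_i | k  ~  N( X_i beta_k ,  sigma_b^2 J + sigma_e^2 I ),

i.e. class-specific spline mean curves with a shared random intercept
(variance sigma_b^2) and homoscedastic residuals (variance sigma_e^2); both
variance components may optionally be class-specific.

Estimation is maximum likelihood via EM (responsibility-weighted least
squares for the curves, a weighted multinomial-logit Newton step for the
membership coefficients, closed-form variance updates through the posterior
moments of the random intercept) with an optional quasi-Newton polish, the
best of several initializations retained. The observed information is
obtained by central finite differences of the log-likelihood, giving Wald
covariance for downstream relative-risk-ratio inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .splines import SplineSpec, basis_matrix

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# data container


@dataclass
class _FitData:
    """Cohort arrays sorted by subject, with segment pointers for reductions."""

    y: np.ndarray          # (N,) outcomes
    X: np.ndarray          # (N, p) spline design
    subj: np.ndarray       # (N,) subject index 0..n-1, sorted non-decreasing
    ptr: np.ndarray        # (n,) segment start offsets for np.add.reduceat
    n_i: np.ndarray        # (n,) observation counts per subject
    W: np.ndarray          # (n, 1+m) membership design, first column constant
    subject_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.n_i)

    @property
    def N(self) -> int:
        return len(self.y)


def build_fit_data(
    growth: pd.DataFrame,
    subjects: pd.DataFrame,
    spline: SplineSpec,
    membership_terms: Sequence[str],
    outcome: str = "wfl",
) -> _FitData:
    """Assemble sorted arrays from the long growth table and subject table.

    ``subjects`` must be indexed (or indexable) by subject_id and contain all
    membership-term columns; every growth subject must appear in it.
    """
    g = growth.sort_values(["subject_id", "age"], kind="stable").reset_index(drop=True)
    ids = g["subject_id"].unique()
    id_index = {s: i for i, s in enumerate(ids)}
    subj = g["subject_id"].map(id_index).to_numpy()
    y = g[outcome].to_numpy(dtype=float)
    X = basis_matrix(g["age"].to_numpy(dtype=float), spline)
    n_i = np.bincount(subj, minlength=len(ids))
    ptr = np.concatenate([[0], np.cumsum(n_i)[:-1]])
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    missing = set(ids) - set(sub.index)
    if missing:
        raise ValueError(f"{len(missing)} growth subjects missing from subject table")
    Wterms = sub.loc[ids, list(membership_terms)].to_numpy(dtype=float)
    if not np.all(np.isfinite(Wterms)):
        raise ValueError("non-finite membership terms")
    W = np.column_stack([np.ones(len(ids)), Wterms])
    return _FitData(y=y, X=X, subj=subj, ptr=ptr, n_i=n_i, W=W, subject_ids=ids)


# ---------------------------------------------------------------------------
# specs and fitted objects


@dataclass
class GMMSpec:
    """Configuration of one growth-mixture fit."""

    K: int
    spline: SplineSpec = field(default_factory=SplineSpec)
    membership_terms: tuple[str, ...] = ()
    class_specific_intercept_sd: bool = False
    class_specific_residual_sd: bool = False
    n_starts: int = 20
    max_iter: int = 500
    tol: float = 1e-8
    param_tol: float = 1e-5
    polish: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FittedGMM:
    """All parameters of a fitted K-class model plus inference byproducts.

    ``gamma`` is stored as a full (K, 1+m) matrix whose first row is zero
    (reference class of the logit parameterization after canonical ordering
    of classes by their fitted mean curve at 18 months, ascending).
    """

    spec: GMMSpec
    beta: np.ndarray            # (K, p)
    gamma: np.ndarray           # (K, 1+m), row 0 == 0
    sigma_b: np.ndarray         # scalar array () or (K,)
    sigma_e: np.ndarray
    loglik: float
    posterior: np.ndarray       # (n, K)
    converged: bool
    n_subjects: int
    n_obs: int
    subject_ids: np.ndarray
    loglik_trace: np.ndarray
    vcov: np.ndarray | None = None
    param_names: list[str] | None = None

    @property
    def K(self) -> int:
        return self.spec.K

    @property
    def n_params(self) -> int:
        K, p = self.beta.shape
        m1 = self.gamma.shape[1]
        nb = K * p + (K - 1) * m1
        nb += K if self.spec.class_specific_intercept_sd else 1
        nb += K if self.spec.class_specific_residual_sd else 1
        return nb

    def mean_curve(self, ages: np.ndarray) -> np.ndarray:
        """(len(ages), K) fitted class mean curves."""
        return basis_matrix(np.asarray(ages, float), self.spec.spline) @ self.beta.T

    def class_shares(self) -> np.ndarray:
        """Modal-assignment shares per class."""
        modal = self.posterior.argmax(axis=1)
        return np.bincount(modal, minlength=self.K) / self.n_subjects

    def gamma_vs_reference(self, reference: int) -> np.ndarray:
        """Membership logit coefficients re-expressed against ``reference``."""
        return self.gamma - self.gamma[reference]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "knots": list(self.spec.spline.knots),
            "membership_terms": list(self.spec.membership_terms),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "sigma_b": np.atleast_1d(self.sigma_b).tolist(),
            "sigma_e": np.atleast_1d(self.sigma_e).tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": bic(self),
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "param_names": self.param_names,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# likelihood pieces


def subject_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta_k: np.ndarray,
    sigma_b: float,
    sigma_e: float,
) -> float:
    """Gaussian log-density of one subject's outcome vector under class k.

    Covariance is sigma_b^2 * J + sigma_e^2 * I (J the all-ones matrix);
    evaluated via the rank-one Woodbury/Sherman-Morrison form, numerically
    stable for sigma_b -> 0 and long visit sequences alike.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite design")
    n = len(y)
    e = y - X @ beta_k
    se2 = sigma_e**2
    sb2 = sigma_b**2
    denom = se2 + n * sb2
    quad = e @ e / se2 - sb2 * e.sum() ** 2 / (se2 * denom)
    logdet = (n - 1) * np.log(se2) + np.log(denom)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _class_logdens(
    data: _FitData, beta: np.ndarray, sigma_b: np.ndarray, sigma_e: np.ndarray
) -> np.ndarray:
    """(n, K) matrix of per-subject, per-class Gaussian log-densities."""
    R = data.y[:, None] - data.X @ beta.T                 # (N, K)
    SSR = np.add.reduceat(R * R, data.ptr, axis=0)        # (n, K)
    S = np.add.reduceat(R, data.ptr, axis=0)
    se2 = np.atleast_1d(sigma_e) ** 2                     # (1,) or (K,)
    sb2 = np.atleast_1d(sigma_b) ** 2
    ncol = data.n_i[:, None].astype(float)
    denom = se2 + ncol * sb2
    quad = SSR / se2 - sb2 * S * S / (se2 * denom)
    logdet = (ncol - 1) * np.log(se2) + np.log(denom)
    return -0.5 * (ncol * _LOG2PI + logdet + quad)


def _log_pi(W: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    eta = W @ gamma.T                                      # (n, K)
    return eta - logsumexp(eta, axis=1, keepdims=True)


def _mixture_loglik(
    data: _FitData,
    beta: np.ndarray,
    gamma: np.ndarray,
    sigma_b: np.ndarray,
    sigma_e: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Observed-data log-likelihood and per-subject joint log p(y, k)."""
    logf = _class_logdens(data, beta, sigma_b, sigma_e)
    logjoint = _log_pi(data.W, gamma) + logf
    ll_i = logsumexp(logjoint, axis=1)
    return float(ll_i.sum()), logjoint - ll_i[:, None]


def _mixture_grad(
    data: _FitData,
    beta: np.ndarray,
    gamma: np.ndarray,
    sigma_b: float,
    sigma_e: float,
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its analytic gradient (shared variance components).

    Uses Fisher's identity: the observed-data score is the posterior-
    weighted complete-data score. Gradient ordering matches the packed
    parameter vector (beta, free gamma rows, log sigma_b, log sigma_e).
    """
    K, p = beta.shape
    ll, logpost = _mixture_loglik(data, beta, gamma,
                                  np.asarray(sigma_b), np.asarray(sigma_e))
    r = np.exp(logpost)                                  # (n, K)
    se2, sb2 = sigma_e**2, sigma_b**2
    ncol = data.n_i[:, None].astype(float)
    denom = se2 + ncol * sb2                             # (n, 1)
    R = data.y[:, None] - data.X @ beta.T                # (N, K)
    S = np.add.reduceat(R, data.ptr, axis=0)             # (n, K)
    SSR = np.add.reduceat(R * R, data.ptr, axis=0)
    sx = np.add.reduceat(data.X, data.ptr, axis=0)       # (n, p)

    r_obs = r[data.subj]
    g_beta = np.empty((K, p))
    for k in range(K):
        term1 = data.X.T @ (r_obs[:, k] * R[:, k]) / se2
        coef = r[:, k] * sb2 * S[:, k] / (se2 * denom[:, 0])
        g_beta[k] = term1 - sx.T @ coef

    # variance components via v = sb^2, w = se^2
    dlogf_dv = -0.5 * (ncol / denom - (S / denom) ** 2)
    dlogf_dw = -0.5 * ((ncol - 1) / se2 + 1 / denom - SSR / se2**2
                       + sb2 * S * S * (denom + se2) / (se2**2 * denom**2))
    g_logsb = float((r * dlogf_dv).sum() * 2 * sb2)      # d/d log sigma_b
    g_logse = float((r * dlogf_dw).sum() * 2 * se2)

    P = np.exp(_log_pi(data.W, gamma))
    g_gamma = ((r - P)[:, 1:].T @ data.W)                # (K-1, 1+m)

    grad = np.concatenate([g_beta.ravel(), g_gamma.ravel(),
                           [g_logsb, g_logse]])
    return ll, grad


# ---------------------------------------------------------------------------
# weighted multinomial logit (Newton), reused as the two-stage oracle


def weighted_multinomial_fit(
    W: np.ndarray,
    R: np.ndarray,
    gamma0: np.ndarray | None = None,
    max_newton: int = 50,
    tol: float = 1e-10,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Maximize sum_i sum_k R_ik log softmax_k(W_i' gamma_k) over gamma.

    ``R`` holds nonnegative weights (soft responsibilities or one-hot
    labels) with rows summing to one. Row 0 of gamma is pinned at zero.
    Newton iterations with step-halving; returns the full (K, m) matrix.
    """
    n, m = W.shape
    K = R.shape[1]
    gamma = np.zeros((K, m)) if gamma0 is None else gamma0.copy()
    gamma -= gamma[0]

    def obj(g):
        return float((R * _log_pi(W, g)).sum())

    f = obj(gamma)
    free = K - 1
    if free == 0:
        return gamma
    for _ in range(max_newton):
        P = np.exp(_log_pi(W, gamma))                      # (n, K)
        G = W.T @ (R[:, 1:] - P[:, 1:])                    # (m, K-1)
        grad = G.T.ravel()                                 # order: class-major
        H = np.empty((free * m, free * m))
        for a in range(free):
            for b in range(a, free):
                pa, pb = P[:, a + 1], P[:, b + 1]
                w = pa * ((a == b) - pb)
                blk = -(W.T * w) @ W
                H[a * m:(a + 1) * m, b * m:(b + 1) * m] = blk
                H[b * m:(b + 1) * m, a * m:(a + 1) * m] = blk
        try:
            step = np.linalg.solve(H - ridge * np.eye(free * m), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H - ridge * np.eye(free * m), grad, rcond=None)[0]
        step = -step.reshape(free, m)
        t = 1.0
        for _ in range(30):
            cand = gamma.copy()
            cand[1:] += t * step
            fc = obj(cand)
            if fc >= f:
                break
            t *= 0.5
        else:
            return gamma
        if fc - f < tol * (1 + abs(f)):
            gamma = cand
            break
        gamma, f = cand, fc
    return gamma


# ---------------------------------------------------------------------------
# EM


def _pack(beta, gamma, sigma_b, sigma_e):
    return np.concatenate([
        beta.ravel(), gamma[1:].ravel(),
        np.log(np.atleast_1d(sigma_b)), np.log(np.atleast_1d(sigma_e)),
    ])


def _unpack(theta, K, p, m1, nb, ne):
    i = K * p
    beta = theta[:i].reshape(K, p)
    j = i + (K - 1) * m1
    gamma = np.vstack([np.zeros(m1), theta[i:j].reshape(K - 1, m1)])
    sb = np.exp(theta[j:j + nb])
    se = np.exp(theta[j + nb:j + nb + ne])
    if nb == 1:
        sb = sb[0]
    if ne == 1:
        se = se[0]
    return beta, gamma, np.asarray(sb), np.asarray(se)


def _em_once(
    data: _FitData,
    spec: GMMSpec,
    beta: np.ndarray,
    gamma: np.ndarray,
    sigma_b: np.ndarray,
    sigma_e: np.ndarray,
) -> tuple:
    """Run EM from one starting point; returns params, trace, converged flag."""
    K, p = beta.shape
    trace = []
    prev_ll = -np.inf
    prev_theta = _pack(beta, gamma, sigma_b, sigma_e)
    converged = False
    for it in range(spec.max_iter):
        ll, logpost = _mixture_loglik(data, beta, gamma, sigma_b, sigma_e)
        trace.append(ll)
        r = np.exp(logpost)                               # (n, K)

        # posterior moments of the random intercept given class
        se2 = np.atleast_1d(sigma_e) ** 2
        sb2 = np.atleast_1d(sigma_b) ** 2
        ncol = data.n_i[:, None].astype(float)
        denom = se2 + ncol * sb2                           # (n, K)
        R = data.y[:, None] - data.X @ beta.T
        S = np.add.reduceat(R, data.ptr, axis=0)
        m_post = sb2 * S / denom                           # (n, K)
        v_post = np.broadcast_to(sb2 * se2 / denom, m_post.shape)

        # M-step: class curves by responsibility-weighted OLS of y - E[b]
        r_obs = r[data.subj]                               # (N, K)
        m_obs = m_post[data.subj]
        new_beta = np.empty_like(beta)
        for k in range(K):
            w = r_obs[:, k]
            Xw = data.X * w[:, None]
            A = Xw.T @ data.X
            bvec = Xw.T @ (data.y - m_obs[:, k])
            try:
                new_beta[k] = np.linalg.solve(A, bvec)
            except np.linalg.LinAlgError:
                new_beta[k] = np.linalg.lstsq(A, bvec, rcond=None)[0]
        beta = new_beta

        # variance updates (use updated beta, fixed posterior moments)
        R = data.y[:, None] - data.X @ beta.T
        resid2 = (R - m_obs) ** 2
        nv = data.n_i[:, None] * v_post
        if spec.class_specific_residual_sd:
            num = (r_obs * resid2).sum(axis=0) + (r * nv).sum(axis=0)
            sigma_e = np.sqrt(num / (r_obs.sum(axis=0) + 1e-300))
        else:
            num = (r_obs * resid2).sum() + (r * nv).sum()
            sigma_e = np.asarray(np.sqrt(num / data.N))
        mb = m_post**2 + v_post
        if spec.class_specific_intercept_sd:
            sigma_b = np.sqrt((r * mb).sum(axis=0) / (r.sum(axis=0) + 1e-300))
        else:
            sigma_b = np.asarray(np.sqrt((r * mb).sum() / data.n))
        sigma_b = np.maximum(sigma_b, 1e-6)
        sigma_e = np.maximum(sigma_e, 1e-6)

        # membership coefficients: a few Q-increasing Newton steps
        if K > 1 and it % 1 == 0:
            gamma = weighted_multinomial_fit(data.W, r, gamma0=gamma, max_newton=3)

        theta = _pack(beta, gamma, sigma_b, sigma_e)
        if it > 0:
            rel = abs(ll - prev_ll) / (1 + abs(ll))
            dpar = np.max(np.abs(theta - prev_theta))
            if rel < spec.tol and dpar < spec.param_tol:
                converged = True
                break
        prev_ll, prev_theta = ll, theta
    ll, _ = _mixture_loglik(data, beta, gamma, sigma_b, sigma_e)
    trace.append(ll)
    return beta, gamma, sigma_b, sigma_e, np.array(trace), converged


def _initial_params(
    data: _FitData, spec: GMMSpec, rng: np.random.Generator, jitter: float
) -> tuple:
    """k-means on ridge-regularized subject-level spline coefficients."""
    K, p = spec.K, data.X.shape[1]
    coefs = np.empty((data.n, p))
    lam = 1e-2
    ends = np.concatenate([data.ptr[1:], [data.N]])
    for i, (a, b) in enumerate(zip(data.ptr, ends)):
        Xi, yi = data.X[a:b], data.y[a:b]
        coefs[i] = np.linalg.solve(Xi.T @ Xi + lam * np.eye(p), Xi.T @ yi)
    if K == 1:
        labels = np.zeros(data.n, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(coefs)
    beta = np.empty((K, p))
    resid_all = []
    for k in range(K):
        mask = labels == k
        if mask.sum() == 0:
            beta[k] = coefs[rng.integers(data.n)]
            continue
        obs = np.isin(data.subj, np.where(mask)[0])
        Xk, yk = data.X[obs], data.y[obs]
        beta[k] = np.linalg.solve(Xk.T @ Xk + lam * np.eye(p), Xk.T @ yk)
        resid_all.append(yk - Xk @ beta[k])
    resid = np.concatenate(resid_all) if resid_all else data.y - data.y.mean()
    tot = max(float(np.std(resid)), 1e-3)
    sigma_e = np.asarray(tot * 0.8)
    sigma_b = np.asarray(tot * 0.6)
    if spec.class_specific_residual_sd:
        sigma_e = np.full(K, float(sigma_e))
    if spec.class_specific_intercept_sd:
        sigma_b = np.full(K, float(sigma_b))
    shares = np.bincount(labels, minlength=K) / data.n
    shares = np.clip(shares, 1e-3, None)
    gamma = np.zeros((K, data.W.shape[1]))
    gamma[:, 0] = np.log(shares) - np.log(shares[0])
    if jitter > 0:
        scale = np.std(coefs, axis=0) + 1e-6
        beta = beta + rng.normal(0, jitter, beta.shape) * scale
    return beta, gamma, sigma_b, sigma_e


def fit_gmm(
    growth: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: GMMSpec,
    outcome: str = "wfl",
    compute_vcov: bool = False,
) -> FittedGMM:
    """Fit the K-class growth mixture model by maximum likelihood.

    Runs EM from ``spec.n_starts`` initializations (k-means partition of
    subject-level spline coefficients, jittered after the first start),
    keeps the best final log-likelihood, optionally polishes with L-BFGS,
    and canonically orders classes by fitted mean outcome at 18 months
    (ascending) so labels are reproducible across runs.
    """
    data = build_fit_data(growth, subjects, spec.spline, spec.membership_terms, outcome)
    if spec.K > data.n:
        raise ValueError(f"K={spec.K} exceeds number of subjects {data.n}")
    rng = np.random.default_rng(spec.seed)
    best = None
    for s in range(spec.n_starts):
        init = _initial_params(data, spec, rng, jitter=0.0 if s == 0 else 0.3)
        out = _em_once(data, spec, *init)
        ll = out[4][-1]
        if best is None or ll > best[4][-1]:
            best = out
    beta, gamma, sigma_b, sigma_e, trace, converged = best

    if spec.polish:
        K, p = beta.shape
        m1 = gamma.shape[1]
        nb = K if spec.class_specific_intercept_sd else 1
        ne = K if spec.class_specific_residual_sd else 1
        shared = nb == 1 and ne == 1

        def neg(theta):
            b, g, sb, se = _unpack(theta, K, p, m1, nb, ne)
            if shared:
                ll, grad = _mixture_grad(data, b, g, float(sb), float(se))
                return -ll, -grad
            ll, _ = _mixture_loglik(data, b, g, sb, se)
            return -ll

        theta0 = _pack(beta, gamma, sigma_b, sigma_e)
        res = minimize(neg, theta0, method="L-BFGS-B", jac=shared,
                       options={"maxiter": 200, "ftol": 1e-13, "gtol": 1e-4})
        if -res.fun > trace[-1]:
            beta, gamma, sigma_b, sigma_e = _unpack(res.x, K, p, m1, nb, ne)
            trace = np.append(trace, -res.fun)
        # a quasi-Newton termination at a (near-)stationary point certifies
        # convergence even when EM's own strict tolerance was not yet met
        if shared and res.jac is not None:
            if res.success or float(np.max(np.abs(res.jac))) < 1e-2:
                converged = True
        elif res.success:
            converged = True

    # canonical ordering by mean curve at 18 months
    end = float(spec.spline.boundary[1])
    vals = (basis_matrix(np.array([end]), spec.spline) @ beta.T).ravel()
    order = np.argsort(vals, kind="stable")
    beta = beta[order]
    gamma = gamma[order] - gamma[order[0]]
    if spec.class_specific_intercept_sd:
        sigma_b = np.atleast_1d(sigma_b)[order]
    else:
        sigma_b = np.float64(sigma_b)
    if spec.class_specific_residual_sd:
        sigma_e = np.atleast_1d(sigma_e)[order]
    else:
        sigma_e = np.float64(sigma_e)

    ll, logpost = _mixture_loglik(data, beta, gamma, sigma_b, sigma_e)
    fit = FittedGMM(
        spec=spec, beta=beta, gamma=gamma,
        sigma_b=np.asarray(sigma_b), sigma_e=np.asarray(sigma_e),
        loglik=ll, posterior=np.exp(logpost), converged=converged,
        n_subjects=data.n, n_obs=data.N, subject_ids=data.subject_ids,
        loglik_trace=trace,
    )
    if compute_vcov:
        add_vcov(fit, data)
    fit._data = data  # cached for downstream inference  # type: ignore[attr-defined]
    return fit


def add_vcov(fit: FittedGMM, data: _FitData | None = None) -> FittedGMM:
    """Attach the inverse observed-information covariance to a fit.

    The Hessian of the observed-data log-likelihood is computed by central
    second differences in the natural parameterization (curve coefficients,
    free membership logits, SDs) at the optimum, then inverted (pseudo-
    inverse fallback when near-singular).
    """
    if data is None:
        data = fit._data  # type: ignore[attr-defined]
    K, p = fit.beta.shape
    m1 = fit.gamma.shape[1]
    sb = np.atleast_1d(fit.sigma_b)
    se = np.atleast_1d(fit.sigma_e)
    theta = np.concatenate([fit.beta.ravel(), fit.gamma[1:].ravel(), sb, se])
    nb, ne = len(sb), len(se)

    def ll_of(th):
        beta = th[:K * p].reshape(K, p)
        j = K * p + (K - 1) * m1
        gamma = np.vstack([np.zeros(m1), th[K * p:j].reshape(K - 1, m1)])
        sb_ = th[j:j + nb]
        se_ = th[j + nb:j + nb + ne]
        return _mixture_loglik(data, beta, gamma,
                               sb_ if nb > 1 else sb_[0],
                               se_ if ne > 1 else se_[0])[0]

    d = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((d, d))
    f0 = ll_of(theta)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        fp[i] = ll_of(theta + ei)
        fm[i] = ll_of(theta - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = ll_of(theta + ei + ej)
            fmm = ll_of(theta - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    info = -H
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    names = [f"beta[{k}][{j}]" for k in range(K) for j in range(p)]
    term_names = ["const", *fit.spec.membership_terms]
    names += [f"gamma[{k}][{t}]" for k in range(1, K) for t in term_names]
    names += [f"sigma_b[{k}]" for k in range(nb)] if nb > 1 else ["sigma_b"]
    names += [f"sigma_e[{k}]" for k in range(ne)] if ne > 1 else ["sigma_e"]
    fit.vcov = vcov
    fit.param_names = names
    return fit


def gamma_index(fit: FittedGMM, class_k: int, term: str) -> int:
    """Position of gamma[class_k][term] in the free-parameter vector."""
    if class_k < 1 or class_k >= fit.K:
        raise ValueError("gamma rows exist for classes 1..K-1 only")
    term_names = ["const", *fit.spec.membership_terms]
    K, p = fit.beta.shape
    return K * p + (class_k - 1) * len(term_names) + term_names.index(term)


# ---------------------------------------------------------------------------
# posteriors, information criteria, model selection


def posterior_probabilities(
    fit: FittedGMM, growth: pd.DataFrame, subjects: pd.DataFrame,
    outcome: str = "wfl",
) -> np.ndarray:
    """p_ik = pi_ik f_ik / sum_l pi_il f_il for (possibly new) cohort data."""
    data = build_fit_data(growth, subjects, fit.spec.spline,
                          fit.spec.membership_terms, outcome)
    _, logpost = _mixture_loglik(data, fit.beta, fit.gamma,
                                 fit.sigma_b, fit.sigma_e)
    return np.exp(logpost)


def bic(fit: FittedGMM) -> float:
    """-2 loglik + n_params * log(n_subjects)."""
    return -2.0 * fit.loglik + fit.n_params * np.log(fit.n_subjects)


@dataclass
class TrajectoryAssignment:
    """Modal class labels with posterior probabilities per subject."""

    df: pd.DataFrame       # subject_id, class_index, max_posterior, p_0..p_{K-1}
    labels: dict[int, str] | None = None
    n_ties: int = 0

    @property
    def class_index(self) -> np.ndarray:
        return self.df["class_index"].to_numpy()

    def with_labels(self, labels: dict[int, str]) -> "TrajectoryAssignment":
        out = self.df.copy()
        out["label"] = out["class_index"].map(labels)
        return TrajectoryAssignment(df=out, labels=labels, n_ties=self.n_ties)


def modal_assignment(
    posterior: np.ndarray, subject_ids: np.ndarray
) -> TrajectoryAssignment:
    """Assign each subject to its highest-posterior class.

    Ties are broken toward the lower class index and counted.
    """
    posterior = np.asarray(posterior, float)
    modal = posterior.argmax(axis=1)   # argmax takes first max -> lower index
    mx = posterior.max(axis=1)
    n_ties = int(((posterior == mx[:, None]).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("modal_assignment: %d posterior ties broken to lower index", n_ties)
    df = pd.DataFrame({
        "subject_id": subject_ids, "class_index": modal, "max_posterior": mx,
    })
    for k in range(posterior.shape[1]):
        df[f"p_{k}"] = posterior[:, k]
    return TrajectoryAssignment(df=df, n_ties=n_ties)


@dataclass
class SelectionReport:
    """Class-number selection audit across a sweep of K."""

    table: pd.DataFrame    # per K: bic, min_share, min_frac_conf, converged, rejected, reason
    chosen_K: int | None


def select_model(
    fits: dict[int, FittedGMM],
    min_share: float = 0.05,
    posterior_threshold: float = 0.7,
    min_confident_frac: float = 0.8,
) -> SelectionReport:
    """Apply the class-number rules to a sweep of fitted models.

    Rules: drop non-converged fits; drop fits where any modal class holds
    under ``min_share`` of subjects; require that in every class more than
    ``min_confident_frac`` of its modally assigned members have maximum
    posterior above ``posterior_threshold``; among survivors pick lowest BIC.
    """
    rows = []
    for K in sorted(fits):
        fit = fits[K]
        shares = fit.class_shares()
        modal = fit.posterior.argmax(axis=1)
        mx = fit.posterior.max(axis=1)
        fracs = []
        for k in range(fit.K):
            members = modal == k
            fracs.append(float((mx[members] > posterior_threshold).mean())
                         if members.any() else 0.0)
        reasons = []
        if not fit.converged:
            reasons.append("not_converged")
        if shares.min() < min_share:
            reasons.append(f"class_share_below_{min_share:g}")
        if min(fracs) <= min_confident_frac:
            reasons.append("posterior_confidence_below_0.8")
        rows.append({
            "K": K, "bic": bic(fit), "loglik": fit.loglik,
            "n_params": fit.n_params, "min_share": float(shares.min()),
            "min_confident_frac": min(fracs), "converged": fit.converged,
            "rejected": bool(reasons), "reason": ";".join(reasons),
        })
    table = pd.DataFrame(rows)
    ok = table[~table["rejected"]]
    chosen = None if ok.empty else int(ok.loc[ok["bic"].idxmin(), "K"])
    return SelectionReport(table=table, chosen_K=chosen)
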