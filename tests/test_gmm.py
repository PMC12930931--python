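"""Mixture likelihood, EM fitting, model selection, and assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import growthmix as gm
from growthmix.gmm import (
    GMMSpec, bic, build_fit_data, fit_gmm, modal_assignment,
    posterior_probabilities, select_model, subject_loglik,
    weighted_multinomial_fit, _mixture_grad, _mixture_loglik, _pack, _unpack,
)
from growthmix.splines import SplineSpec, basis_matrix
from conftest import make_separated_cohort, random_subject


# ---------------------------------------------------------------------------
# subject-level likelihood


def test_subject_loglik_matches_dense_mvn():
    """Woodbury evaluation equals explicit covariance inversion."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        y, X, beta = random_subject(rng)
        sb, se = rng.uniform(0.5, 8), rng.uniform(0.5, 8)
        n = len(y)
        cov = sb**2 * np.ones((n, n)) + se**2 * np.eye(n)
        dense = stats.multivariate_normal.logpdf(y, X @ beta, cov)
        assert subject_loglik(y, X, beta, sb, se) == pytest.approx(dense, abs=1e-8)


def test_subject_loglik_independence_limit():
    rng = np.random.default_rng(1)
    y, X, beta = random_subject(rng, n_obs=5)
    se = 2.0
    ll = subject_loglik(y, X, beta, 1e-9, se)
    indep = stats.norm.logpdf(y, X @ beta, se).sum()
    assert ll == pytest.approx(indep, abs=1e-6)


def test_subject_loglik_single_observation():
    rng = np.random.default_rng(2)
    y, X, beta = random_subject(rng, n_obs=1)
    sb, se = 3.0, 4.0
    expected = stats.norm.logpdf(y[0], (X @ beta)[0], np.hypot(sb, se))
    assert subject_loglik(y, X, beta, sb, se) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# one-class equivalence with a GLS mixed-model oracle


def _gls_oracle(y, X, ptr, n_i):
    """Closed-form profile fit of the one-class random-intercept model."""
    ends = np.concatenate([ptr[1:], [len(y)]])

    def beta_gls(sb2, se2):
        A = np.zeros((X.shape[1],) * 2)
        b = np.zeros(X.shape[1])
        for a, e, ni in zip(ptr, ends, n_i):
            Xi, yi = X[a:e], y[a:e]
            Vinv = (np.eye(ni) - sb2 / (se2 + ni * sb2) * np.ones((ni, ni))) / se2
            A += Xi.T @ Vinv @ Xi
            b += Xi.T @ Vinv @ yi
        return np.linalg.solve(A, b)

    def negll(logs):
        sb2, se2 = np.exp(2 * logs)
        beta = beta_gls(sb2, se2)
        ll = 0.0
        for a, e, ni in zip(ptr, ends, n_i):
            cov = sb2 * np.ones((ni, ni)) + se2 * np.eye(ni)
            ll += stats.multivariate_normal.logpdf(y[a:e], X[a:e] @ beta, cov)
        return -ll

    res = optimize.minimize(negll, np.log([3.0, 3.0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    sb2, se2 = np.exp(2 * res.x)
    return beta_gls(sb2, se2), np.sqrt(sb2), np.sqrt(se2), -res.fun


def test_one_class_matches_gls_oracle():
    _, _, growth, subjects = make_separated_cohort(n=300, seed=3, K=1)
    spec = GMMSpec(K=1, membership_terms=(), n_starts=1, seed=0)
    fit = gm.fit_gmm(growth, subjects, spec)
    data = build_fit_data(growth, subjects, spec.spline, ())
    beta_o, sb_o, se_o, ll_o = _gls_oracle(data.y, data.X, data.ptr, data.n_i)
    assert np.allclose(fit.beta[0], beta_o, atol=1e-5)
    assert fit.loglik == pytest.approx(ll_o, abs=1e-4)
    assert float(fit.sigma_b) == pytest.approx(sb_o, abs=1e-4)
    assert float(fit.sigma_e) == pytest.approx(se_o, abs=1e-4)


# ---------------------------------------------------------------------------
# EM behaviour


def test_em_loglik_monotone(separated_fit):
    trace = separated_fit["fit"].loglik_trace
    assert np.all(np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1])))


def test_fit_recovers_well_separated_classes(separated_fit):
    cfg = separated_fit["cfg"]
    fit = separated_fit["fit"]
    cohort = separated_fit["cohort"]
    assert fit.converged
    tr = cohort.truth.set_index("subject_id").loc[fit.subject_ids]
    modal = fit.posterior.argmax(axis=1)
    agree = (modal == tr["true_class"].to_numpy()).mean()
    assert agree > 0.9
    # curves within 1 g/cm of truth at the visits (canonical order = truth order)
    ages = np.array(cfg.visit_schedule)
    X = basis_matrix(ages, cfg.spline)
    assert np.max(np.abs(X @ fit.beta.T - X @ cfg.class_mean_coefs.T)) < 1.5


def test_symmetric_two_class_shares():
    """No membership terms, symmetric two-class data -> shares near 1/2."""
    gamma = np.zeros((2, 1))
    _, _, growth, subjects = make_separated_cohort(
        n=600, seed=5, K=2, gamma=gamma, columns=("const",))
    spec = GMMSpec(K=2, membership_terms=(), n_starts=2, seed=2)
    fit = gm.fit_gmm(growth, subjects, spec)
    assert abs(fit.class_shares()[0] - 0.5) < 0.06


def test_no_terms_matches_unconditional_mixture_oracle():
    """With constant mixing the fit equals a directly optimized mixture."""
    _, _, growth, subjects = make_separated_cohort(
        n=80, seed=6, K=2, gamma=np.array([[0.0], [0.4]]), columns=("const",))
    spec = GMMSpec(K=2, membership_terms=(), n_starts=2, seed=1)
    fit = gm.fit_gmm(growth, subjects, spec)

    data = build_fit_data(growth, subjects, spec.spline, ())
    p = data.X.shape[1]
    ends = np.concatenate([data.ptr[1:], [data.N]])

    def dense_negll(theta):
        b = theta[:2 * p].reshape(2, p)
        mix_logit, lsb, lse = theta[2 * p], theta[2 * p + 1], theta[2 * p + 2]
        pi1 = 1 / (1 + np.exp(-mix_logit))
        sb, se = np.exp(lsb), np.exp(lse)
        ll = 0.0
        for a, e, ni in zip(data.ptr, ends, data.n_i):
            cov = sb**2 * np.ones((ni, ni)) + se**2 * np.eye(ni)
            lks = [stats.multivariate_normal.logpdf(data.y[a:e], data.X[a:e] @ b[k], cov)
                   for k in range(2)]
            m = max(lks)
            ll += m + np.log((1 - pi1) * np.exp(lks[0] - m) + pi1 * np.exp(lks[1] - m))
        return -ll

    theta0 = np.concatenate([fit.beta.ravel() + 0.05,
                             [fit.gamma[1, 0] + 0.05],
                             np.log([float(fit.sigma_b), float(fit.sigma_e)]) + 0.02])
    res = optimize.minimize(dense_negll, theta0, method="L-BFGS-B")
    # the EM fit should attain at least the oracle's optimum
    assert fit.loglik >= -res.fun - 1e-3
    assert np.allclose(np.sort(fit.beta[:, 0]), np.sort(res.x[:2 * p].reshape(2, p)[:, 0]),
                       atol=0.2)


def test_analytic_score_matches_central_differences():
    """Fisher-identity gradient of the mixture log-likelihood vs numeric."""
    cfg, _, growth, subjects = make_separated_cohort(n=80, seed=13, K=2)
    data = build_fit_data(growth, subjects, cfg.spline, ("Hg_l2s",))
    rng = np.random.default_rng(5)
    beta = cfg.class_mean_coefs + rng.normal(0, 0.5, (2, 5))
    gamma = np.vstack([np.zeros(2), rng.normal(0, 0.3, (1, 2))])
    sb, se = 3.3, 5.2
    _, grad = _mixture_grad(data, beta, gamma, sb, se)
    theta = _pack(beta, gamma, np.asarray(sb), np.asarray(se))

    def f(th):
        b, g, s1, s2 = _unpack(th, 2, 5, 2, 1, 1)
        return _mixture_loglik(data, b, g, s1, s2)[0]

    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        num = (f(theta + e) - f(theta - e)) / 2e-6
        assert grad[i] == pytest.approx(num, abs=1e-4, rel=1e-5)


# ---------------------------------------------------------------------------
# posteriors


def test_posteriors_match_brute_force(separated_fit):
    fit = separated_fit["fit"]
    growth, subjects = separated_fit["growth"], separated_fit["subjects"]
    post = posterior_probabilities(fit, growth, subjects)
    data = build_fit_data(growth, subjects, fit.spec.spline,
                          fit.spec.membership_terms)
    # brute force from subject_loglik for 10 subjects
    W = data.W
    eta = W @ fit.gamma.T
    pi = np.exp(eta - eta.max(1, keepdims=True))
    pi /= pi.sum(1, keepdims=True)
    ends = np.concatenate([data.ptr[1:], [data.N]])
    for i in range(10):
        a, e = data.ptr[i], ends[i]
        lks = np.array([subject_loglik(data.y[a:e], data.X[a:e], fit.beta[k],
                                       float(np.atleast_1d(fit.sigma_b)[0]),
                                       float(np.atleast_1d(fit.sigma_e)[0]))
                        for k in range(fit.K)])
        joint = pi[i] * np.exp(lks - lks.max())
        assert np.allclose(post[i], joint / joint.sum(), atol=1e-8)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)


def test_identical_classes_posterior_equals_prior():
    _, _, growth, subjects = make_separated_cohort(
        n=60, seed=7, K=1, columns=("const",))
    spec1 = GMMSpec(K=1, membership_terms=(), n_starts=1, seed=0)
    fit1 = gm.fit_gmm(growth, subjects, spec1)
    # duplicate the single class, fix unequal mixing via gamma
    fit1.beta = np.vstack([fit1.beta[0], fit1.beta[0]])
    fit1.gamma = np.array([[0.0], [0.7]])
    fit1.spec = GMMSpec(K=2, membership_terms=(), n_starts=1, seed=0)
    post = posterior_probabilities(fit1, growth, subjects)
    pi1 = 1 / (1 + np.exp(-0.7))
    assert np.allclose(post[:, 1], pi1, atol=1e-10)


# ---------------------------------------------------------------------------
# BIC and selection rules


def test_bic_formula():
    class Dummy:
        loglik = 0.0
        n_params = 5
        n_subjects = 100
    assert bic(Dummy()) == pytest.approx(5 * np.log(100), abs=1e-10)


def test_bic_ordering_on_nested_fits(separated_fit):
    growth, subjects = separated_fit["growth"], separated_fit["subjects"]
    fits = {}
    for K in (1, 2, 3):
        spec = GMMSpec(K=K, membership_terms=("Hg_l2s",), n_starts=2, seed=3)
        fits[K] = gm.fit_gmm(growth, subjects, spec)
    # hand-computed BIC from loglik and counts
    for K, fit in fits.items():
        hand = -2 * fit.loglik + fit.n_params * np.log(fit.n_subjects)
        assert bic(fit) == pytest.approx(hand, rel=1e-12)
    # the generating K=3 should beat underfit K=1
    assert bic(fits[3]) < bic(fits[1])


def test_select_model_rules():
    class Fake:
        def __init__(self, K, ll, n_params, post, converged=True):
            self.K = K
            self.loglik = ll
            self.n_params = n_params
            self.posterior = post
            self.converged = converged
            self.n_subjects = post.shape[0]

        def class_shares(self):
            modal = self.posterior.argmax(1)
            return np.bincount(modal, minlength=self.K) / self.n_subjects

    n = 100
    conf = np.full((n, 2), 0.05)
    conf[:50, 0], conf[50:, 1] = 0.95, 0.95
    good2 = Fake(2, -100.0, 5, conf)
    # small class: 3 subjects in class 1
    post3 = np.full((n, 3), 0.02)
    post3[:50, 0] = 0.96
    post3[50:97, 2] = 0.96
    post3[97:, 1] = 0.96
    small3 = Fake(3, -80.0, 8, post3)
    bad_conv = Fake(4, -50.0, 11, conf := np.tile([0.9, 0.1], (n, 2))[:, :4] if False else post3,
                    converged=False)
    report = select_model({2: good2, 3: small3, 4: bad_conv})
    assert report.chosen_K == 2
    t = report.table.set_index("K")
    assert "class_share" in t.loc[3, "reason"]
    assert "not_converged" in t.loc[4, "reason"]


def test_select_model_low_confidence_rejected():
    n = 200
    post = np.full((n, 2), 0.5)
    post[:, 0] += 0.05
    post[:, 1] -= 0.05

    class Fuzzy:
        K = 2
        loglik = -10.0
        n_params = 5
        posterior = post
        converged = True
        n_subjects = n

        def class_shares(self):
            return np.array([1.0, 0.0])

    report = select_model({2: Fuzzy()})
    assert report.chosen_K is None
    assert not report.table["converged"].empty


# ---------------------------------------------------------------------------
# modal assignment


def test_modal_assignment_examples():
    post = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]])
    out = modal_assignment(post, np.array(["a", "b"]))
    assert out.df["class_index"].tolist() == [1, 0]  # tie -> lower index
    assert out.n_ties == 1


def test_modal_assignment_matches_argmax_oracle():
    rng = np.random.default_rng(3)
    post = rng.dirichlet(np.ones(4), size=200)
    out = modal_assignment(post, np.arange(200))
    assert np.array_equal(out.class_index, post.argmax(axis=1))


# ---------------------------------------------------------------------------
# weighted multinomial Newton solver (internal oracle used elsewhere)


def test_weighted_multinomial_matches_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(4)
    n = 400
    W = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
    gamma = np.array([[0, 0], [0.3, 0.8], [-0.4, -0.6]], float)
    eta = W @ gamma.T
    p = np.exp(eta - eta.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    y = (p.cumsum(1) < rng.random((n, 1))).sum(1)
    R = np.eye(3)[y]
    ours = weighted_multinomial_fit(W, R)
    ref = sm.MNLogit(y, W).fit(disp=0)
    assert np.allclose(ours[1:].T, np.asarray(ref.params), atol=1e-6)


# ---------------------------------------------------------------------------
# errors


def test_k_exceeding_subjects_raises():
    _, _, growth, subjects = make_separated_cohort(n=30, seed=8, K=1)
    ids = growth["subject_id"].unique()[:3]
    g3 = growth[growth["subject_id"].isin(ids)]
    spec = GMMSpec(K=5, membership_terms=(), n_starts=1, seed=0)
    with pytest.raises(ValueError):
        gm.fit_gmm(g3, subjects, spec)
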