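import numpy as np
import pandas as pd
import pytest

import growthmix as gm
from growthmix.pipeline import prepare_analysis


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, n=400, with analysis tables prebuilt."""
    cfg = gm.default_calibration(n_subjects=400, seed=11)
    cohort = gm.generate_cohort(cfg)
    growth, subjects, pre = prepare_analysis(cohort)
    return {"cfg": cfg, "cohort": cohort, "growth": growth,
            "subjects": subjects, "pre": pre}


@pytest.fixture(scope="session")
def separated_fit():
    """A 3-class fit on well-separated synthetic data, shared across tests."""
    cfg, cohort, growth, subjects = make_separated_cohort(n=500, seed=21)
    spec = gm.GMMSpec(K=3, spline=cfg.spline,
                      membership_terms=("Hg_l2s",), n_starts=2, seed=1)
    fit = gm.fit_gmm(growth, subjects, spec, compute_vcov=True)
    return {"cfg": cfg, "cohort": cohort, "growth": growth,
            "subjects": subjects, "fit": fit}


def make_separated_cohort(n=500, seed=0, K=3, gamma=None, sep=2.5,
                          residual_sd=5.0, intercept_sd=4.0,
                          missing=0.05, columns=("const", "Hg_l2s")):
    """Cohort with K well-separated classes (curves ``sep`` residual SDs
    apart at every age) and a simple membership model."""
    base = np.array([66.0, 72, 78, 88, 103, 112, 120, 125, 128, 131])
    curves = np.vstack([base + k * sep * residual_sd for k in range(K)])
    from growthmix.simulate import _curve_to_coefs, SimConfig
    from growthmix.splines import SplineSpec
    spline = SplineSpec(knots=(3.5, 9.0))
    beta = np.vstack([_curve_to_coefs(c, spline) for c in curves])
    if gamma is None:
        gamma = np.zeros((K, len(columns)))
        gamma[1:, 0] = 0.2
        if "Hg_l2s" in columns:
            j = columns.index("Hg_l2s")
            gamma[1:, j] = np.linspace(0.4, 0.8, K - 1)
    cfg = gm.default_calibration(n_subjects=n, seed=seed)
    cfg.K_true = K
    cfg.membership_columns = tuple(columns)
    cfg.class_membership_coefs = np.asarray(gamma, float)
    cfg.class_mean_coefs = beta
    cfg.residual_sd = residual_sd
    cfg.random_intercept_sd = intercept_sd
    cfg.missing_visit_prob = missing
    cohort = gm.generate_cohort(cfg)
    growth, subjects, _ = prepare_analysis(cohort)
    return cfg, cohort, growth, subjects


def random_subject(rng, p=5, n_obs=None):
    """One random subject's (y, X) with a quadratic-spline design."""
    from growthmix.splines import SplineSpec, basis_matrix
    spline = SplineSpec(knots=(3.5, 9.0))
    n_obs = n_obs or int(rng.integers(1, 9))
    ages = np.sort(rng.uniform(0, 18, n_obs))
    X = basis_matrix(ages, spline)
    beta = rng.normal(0, 2, X.shape[1])
    y = X @ beta + rng.normal(0, 3, n_obs)
    return y, X, beta
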