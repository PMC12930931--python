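"""RRR estimation (one-step and two-stage), kappa, z-score models,
and effect-modification terms."""

import numpy as np
import pandas as pd
import pytest

import growthmix as gm
from growthmix.effects import (
    Contrast, align_labels, bmi_interaction_twostage, cohens_kappa,
    doubling_contrast, linear_z_regression, rrr_onestep, rrr_twostage,
)
from growthmix.gmm import (
    GMMSpec, TrajectoryAssignment, modal_assignment, weighted_multinomial_fit,
)
from conftest import make_separated_cohort


# ---------------------------------------------------------------------------
# one-step RRR


def test_rrr_identity_and_zero_coefficient(separated_fit):
    fit = separated_fit["fit"]
    c = Contrast(kind="doubling", element="Hg", term="Hg_l2s", delta=0.8)
    rows = rrr_onestep(fit, c, reference=0)
    # internal identity check ran (would raise); estimates exponentiate gamma
    gd = fit.gamma_vs_reference(0)
    terms = ["const", *fit.spec.membership_terms]
    j = terms.index("Hg_l2s")
    for _, r in rows.iterrows():
        assert r["estimate"] == pytest.approx(np.exp(0.8 * gd[int(r["class"]), j]))
        assert r["lo95"] <= r["estimate"] <= r["hi95"]


def test_rrr_gamma_log2_gives_rrr_two(separated_fit):
    """gamma = ln 2, delta = 1 -> RRR exactly 2, verified against the
    probability-ratio definition at arbitrary covariate vectors."""
    fit = separated_fit["fit"]
    saved = fit.gamma.copy()
    try:
        fit.gamma = fit.gamma.copy()
        terms = ["const", *fit.spec.membership_terms]
        j = terms.index("Hg_l2s")
        fit.gamma[1, j] = np.log(2.0)
        c = Contrast(kind="doubling", element="Hg", term="Hg_l2s", delta=1.0)
        rows = rrr_onestep(fit, c, reference=0)
        est = rows.set_index("class").loc[1, "estimate"]
        assert est == pytest.approx(2.0, abs=1e-10)
    finally:
        fit.gamma = saved


def test_rrr_nonreference_base_uses_gamma_difference(separated_fit):
    fit = separated_fit["fit"]
    c = Contrast(kind="doubling", element="Hg", term="Hg_l2s", delta=1.0)
    rows = rrr_onestep(fit, c, reference=2)
    gd = fit.gamma_vs_reference(2)
    terms = ["const", *fit.spec.membership_terms]
    j = terms.index("Hg_l2s")
    got = rows.set_index("class")["estimate"]
    for k in (0, 1):
        assert got[k] == pytest.approx(np.exp(gd[k, j]))


def test_rrr_invariant_to_standardization_constant(separated_fit):
    """Doubling RRR does not depend on the scaling SD used in preprocessing."""
    fit = separated_fit["fit"]
    # same underlying log2 effect expressed under two scalings
    rows_a = rrr_onestep(fit, doubling_contrast("Hg", scale_sd=1.0), reference=0)
    gd = fit.gamma_vs_reference(0)
    terms = ["const", *fit.spec.membership_terms]
    j = terms.index("Hg_l2s")
    # rescaling the column by c multiplies gamma by c and divides delta by c
    for c_scale in (0.5, 2.0):
        fit2 = separated_fit["fit"]
        saved = fit2.gamma.copy()
        try:
            fit2.gamma = fit2.gamma.copy()
            fit2.gamma[:, j] = saved[:, j] / c_scale
            # vcov entry scales too; only check the point estimate
            rows_b = rrr_onestep(fit2, doubling_contrast("Hg", scale_sd=1 / c_scale),
                                 reference=0)
            assert np.allclose(rows_b["estimate"], rows_a["estimate"], rtol=1e-10)
        finally:
            fit2.gamma = saved


def test_rrr_nonconverged_fit_flagged(separated_fit):
    import copy
    fit = copy.copy(separated_fit["fit"])
    fit.converged = False
    rows = rrr_onestep(fit, Contrast("doubling", "Hg", "Hg_l2s", 1.0), reference=0)
    assert (~rows["converged"]).all()
    assert rows["estimate"].isna().all()


def test_rrr_missing_term_raises(separated_fit):
    with pytest.raises(ValueError):
        rrr_onestep(separated_fit["fit"],
                    Contrast("doubling", "Pb", "Pb_l2s", 1.0), reference=0)


# ---------------------------------------------------------------------------
# two-stage comparator


def _toy_assignment_data(seed=0, n=200, K=3, coef=0.9):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    gamma = np.zeros((K, 3))
    gamma[1:, 0] = -0.3
    gamma[1:, 1] = np.linspace(coef, coef / 2, K - 1)
    gamma[1:, 2] = 0.2
    W = np.column_stack([np.ones(n), x, z])
    eta = W @ gamma.T
    p = np.exp(eta - eta.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    y = (p.cumsum(1) < rng.random((n, 1))).sum(1)
    subjects = pd.DataFrame({"subject_id": np.arange(n), "expo": x, "cov1": z})
    df = pd.DataFrame({"subject_id": np.arange(n), "class_index": y,
                       "max_posterior": 1.0})
    return TrajectoryAssignment(df=df), subjects, W, y


def test_twostage_matches_internal_newton_oracle():
    assign, subjects, W, y = _toy_assignment_data()
    c = Contrast(kind="doubling", element="E", term="expo", delta=1.0)
    rows = rrr_twostage(assign, subjects, c, ("cov1",), reference=0)
    R = np.eye(3)[y]
    oracle = weighted_multinomial_fit(W, R, max_newton=200)
    got = np.log(rows.set_index("class")["estimate"])
    for k in (1, 2):
        assert got[k] == pytest.approx(oracle[k, 1], abs=1e-6)


def test_twostage_null_data_rrr_near_one():
    assign, subjects, _, _ = _toy_assignment_data(seed=3, n=3000, coef=0.0)
    c = Contrast(kind="doubling", element="E", term="expo", delta=1.0)
    rows = rrr_twostage(assign, subjects, c, ("cov1",), reference=0)
    assert np.allclose(rows["estimate"], 1.0, atol=0.15)
    for _, r in rows.iterrows():
        assert r["lo95"] < 1.0 < r["hi95"]


def test_tertile_label_swap_symmetry():
    """Swapping low/high tertile indicator columns swaps their RRRs."""
    rng = np.random.default_rng(5)
    n = 400
    tert = rng.integers(0, 3, n)
    low = (tert == 0).astype(float)
    high = (tert == 2).astype(float)
    eta = 0.8 * low - 0.5 * high
    p1 = 1 / (1 + np.exp(-(-0.4 + eta)))
    y = (rng.random(n) < p1).astype(int)
    subjects = pd.DataFrame({"subject_id": np.arange(n), "low": low,
                             "high": high, "cov1": rng.normal(size=n)})
    assign = TrajectoryAssignment(df=pd.DataFrame(
        {"subject_id": np.arange(n), "class_index": y, "max_posterior": 1.0}))
    c_lo = Contrast("tertile_low_vs_mid", "Mn", "low", 1.0)
    c_hi = Contrast("tertile_high_vs_mid", "Mn", "high", 1.0)
    r1 = rrr_twostage(assign, subjects, c_lo, ("high", "cov1"), reference=0)
    swapped = subjects.rename(columns={"low": "high", "high": "low"})
    r2 = rrr_twostage(assign, swapped, c_hi, ("low", "cov1"), reference=0)
    assert r1["estimate"].iloc[0] == pytest.approx(r2["estimate"].iloc[0], rel=1e-8)


# ---------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_identical_is_one():
    a = np.array([0, 1, 2, 1, 0, 2] * 10)
    k, _ = cohens_kappa(a, a)
    assert k == pytest.approx(1.0)


def test_kappa_hand_computed_2x2():
    """Table ((45,5),(5,45)) -> kappa = 0.8 exactly."""
    a = np.repeat([0, 0, 1, 1], [45, 5, 5, 45])
    b = np.repeat([0, 1, 0, 1], [45, 5, 5, 45])
    k, (lo, hi) = cohens_kappa(a, b)
    assert k == pytest.approx(0.8, abs=1e-12)
    assert lo < 0.8 < hi


def test_kappa_independent_near_zero():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 4, 10000)
    b = rng.integers(0, 4, 10000)
    k, _ = cohens_kappa(a, b)
    assert abs(k) < 0.05


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score
    rng = np.random.default_rng(1)
    a = rng.integers(0, 3, 500)
    b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 3, 500))
    k, _ = cohens_kappa(a, b)
    assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_alignment_fixes_permuted_labels():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, 300)
    b = (a + 1) % 3  # perfect agreement under a relabeling
    k_raw, _ = cohens_kappa(a, b)
    k_aligned, _ = cohens_kappa(a, b, align=True)
    assert k_raw < 0.1
    assert k_aligned == pytest.approx(1.0)
    assert np.array_equal(align_labels(a, b), a)


def test_kappa_single_category_undefined():
    k, _ = cohens_kappa(np.zeros(10), np.zeros(10))
    assert np.isnan(k)


# ---------------------------------------------------------------------------
# linear z-score regressions


def test_linear_z_matches_normal_equations():
    rng = np.random.default_rng(3)
    n = 150
    subjects = pd.DataFrame({
        "subject_id": np.arange(n),
        "expo": rng.normal(0, 1, n),
        "cov1": rng.normal(0, 1, n),
    })
    z = pd.Series(0.3 * subjects["expo"].to_numpy() + rng.normal(0, 1, n),
                  index=pd.Index(np.arange(n), name="subject_id"))
    rows = linear_z_regression(z, subjects, ("expo",), ("cov1",))
    X = np.column_stack([np.ones(n), subjects["expo"], subjects["cov1"]])
    beta = np.linalg.solve(X.T @ X, X.T @ z.to_numpy())
    assert rows["estimate"].iloc[0] == pytest.approx(beta[1], abs=1e-10)


def test_linear_z_null_simulation():
    rng = np.random.default_rng(4)
    n = 500
    subjects = pd.DataFrame({"subject_id": np.arange(n),
                             "expo": rng.normal(0, 1, n),
                             "cov1": rng.normal(0, 1, n)})
    z = pd.Series(rng.normal(0, 1, n), index=pd.Index(np.arange(n), name="subject_id"))
    rows = linear_z_regression(z, subjects, ("expo",), ("cov1",))
    assert abs(rows["estimate"].iloc[0]) < 0.15
    assert rows["lo95"].iloc[0] < 0 < rows["hi95"].iloc[0]


def test_linear_z_effect_recovery():
    """An injected 0.19-z-per-doubling effect is recovered in most reps."""
    hits = 0
    reps = 40
    for r in range(reps):
        rng = np.random.default_rng(100 + r)
        n = 400
        l2 = rng.normal(0, 1.5, n)    # log2 concentration
        subjects = pd.DataFrame({"subject_id": np.arange(n), "l2": l2,
                                 "cov1": rng.normal(0, 1, n)})
        z = pd.Series(0.19 * l2 + 0.2 * subjects["cov1"].to_numpy()
                      + rng.normal(0, 0.8, n),
                      index=pd.Index(np.arange(n), name="subject_id"))
        rows = linear_z_regression(z, subjects, ("l2",), ("cov1",))
        if rows["lo95"].iloc[0] <= 0.19 <= rows["hi95"].iloc[0]:
            hits += 1
    assert hits >= 33  # 95% CIs: 33/40 allows binomial fluctuation


def test_linear_z_underdetermined_raises():
    subjects = pd.DataFrame({"subject_id": [0, 1], "expo": [0.0, 1.0],
                             "cov1": [1.0, 2.0]})
    z = pd.Series([0.1, 0.2], index=pd.Index([0, 1], name="subject_id"))
    with pytest.raises(ValueError):
        linear_z_regression(z, subjects, ("expo",), ("cov1",))


# ---------------------------------------------------------------------------
# BMI interaction


def test_interaction_zero_coefficient_stratified_rrrs_equal():
    """Generated without interaction: stratified effects agree closely and
    the cross-product term is not significant."""
    rng = np.random.default_rng(6)
    n = 2000
    x = rng.normal(0, 1, n)
    bmi = (rng.random(n) < 0.45).astype(float)
    eta = -0.2 + 0.6 * x             # no x*bmi term
    p1 = 1 / (1 + np.exp(-eta))
    y = (rng.random(n) < p1).astype(int)
    subjects = pd.DataFrame({"subject_id": np.arange(n), "expo": x,
                             "bmi_ge_25": bmi, "cov1": rng.normal(0, 1, n)})
    assign = TrajectoryAssignment(df=pd.DataFrame(
        {"subject_id": np.arange(n), "class_index": y, "max_posterior": 1.0}))
    c = Contrast("doubling", "E", "expo", 1.0)
    rows = bmi_interaction_twostage(assign, subjects, c, ("cov1",), reference=0)
    assert abs(rows["estimate"].iloc[0]) < 0.25
    assert rows["p"].iloc[0] > 0.01


def test_interaction_null_pvalues_uniform():
    """Without a generating interaction, cross-product Wald p-values are
    uniform on (0,1) across replicates (KS test not rejected at 0.01)."""
    from scipy import stats as sps
    ps = []
    for r in range(40):
        rng = np.random.default_rng(700 + r)
        n = 600
        x = rng.normal(0, 1, n)
        bmi = (rng.random(n) < 0.45).astype(float)
        eta = -0.3 + 0.4 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        subjects = pd.DataFrame({"subject_id": np.arange(n), "expo": x,
                                 "bmi_ge_25": bmi,
                                 "cov1": rng.normal(0, 1, n)})
        assign = TrajectoryAssignment(df=pd.DataFrame(
            {"subject_id": np.arange(n), "class_index": y, "max_posterior": 1.0}))
        rows = bmi_interaction_twostage(
            assign, subjects, Contrast("doubling", "E", "expo", 1.0),
            ("cov1",), reference=0)
        ps.append(rows["p"].iloc[0])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_interaction_injected_ln2_detected():
    """A cross-product of ln 2 is detected in the majority of replicates."""
    hits = 0
    reps = 10
    for r in range(reps):
        rng = np.random.default_rng(200 + r)
        n = 800
        x = rng.normal(0, 1, n)
        bmi = (rng.random(n) < 0.45).astype(float)
        eta = -0.2 + 0.3 * x + np.log(2) * x * bmi
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        subjects = pd.DataFrame({"subject_id": np.arange(n), "expo": x,
                                 "bmi_ge_25": bmi,
                                 "cov1": rng.normal(0, 1, n)})
        assign = TrajectoryAssignment(df=pd.DataFrame(
            {"subject_id": np.arange(n), "class_index": y, "max_posterior": 1.0}))
        c = Contrast("doubling", "E", "expo", 1.0)
        rows = bmi_interaction_twostage(assign, subjects, c, ("cov1",), reference=0)
        if rows["p"].iloc[0] < 0.05:
            hits += 1
    assert hits > reps / 2
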