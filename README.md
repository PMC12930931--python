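# growthmix

Latent-class growth mixture modelling of infant weight-for-length
trajectories, with estimation of prenatal element-exposure effects on
trajectory membership.

## The problem

Infants do not follow a single growth curve: distinct subgroups track low,
track high, or accelerate late. Epidemiologists studying prenatal exposures
(toxic and essential trace elements measured in maternal toenail clippings:
As, Hg, Pb, Cu, Mn, Se) want to know whether exposure shifts the probability
of following an unhealthy trajectory, not just attained size at one visit.
This package implements that analysis end to end for longitudinal
weight-for-length (g/cm = 1000 × weight[kg] / length[cm]) measured at up to
ten well-child visits from birth to 18 months:

1. **Preprocessing** — LOD/√2 substitution for non-detects, log2 transform
   and scaling (or tertile coding) of concentrations, per-visit ±4 SD
   outlier exclusion, and removal of subjects with ≤3 measures.
2. **Growth mixture model (GMM)** — a finite mixture of linear mixed models.
   Subject *i* in latent class *k* has
   `y_i | k ~ N(X_i β_k, σ_b² J + σ_e² I)` with `X_i` a quadratic B-spline
   design over age (knots at 3.5 and 9 months, or selected by SSE), a shared
   random intercept σ_b, and residual σ_e; class membership follows a
   multinomial logit `π_ik = softmax(w_i' γ_k)` of exposures and covariates.
   Maximum likelihood via EM with an analytic-score quasi-Newton polish;
   class number chosen by BIC subject to >5% class share and >0.7 posterior
   confidence rules.
3. **Reference naming** — each class's median curve is compared with a
   growth-standard chart by sum of squared differences; the closest class
   is the reference ("Stable-slow"), the rest are named Late-moderate,
   Stable-moderate, Rapid by shape. LMS z-scores (`z = ((x/M)^L − 1)/(L·S)`)
   support attained-size sensitivity outcomes.
4. **Effects** — relative risk ratios per doubling of concentration
   computed *inside* the mixture (`RRR_j = exp(δ·(γ_j − γ_ref))`, exactly
   the ratio of membership-probability ratios), with Wald CIs from the
   observed information; two-stage multinomial comparators on modal
   assignments; Cohen's kappa for assignment agreement; BMI cross-product
   effect modification.
5. **Mixture analysis** — quantile-based g-computation: score each element
   by sample quartile, fit a conditional multinomial model, average
   counterfactual predictions to get marginal risks `r_j(s)`, summarize by
   `log r_j(s) = a_j + ψ_j s` so `exp(ψ_j)` is the risk ratio for raising
   every element one quartile simultaneously, with signed per-element
   weights and a subject-level bootstrap.

Because cohort data of this kind are not public, the package ships a
first-class synthetic cohort generator (`growthmix.simulate`) that draws
from exactly the model above — known class curves, membership coefficients,
correlated log-normal exposures with realistic detection limits — so every
stage can be validated against ground truth.

## Worked example

```python
import growthmix as gm
from growthmix.pipeline import prepare_analysis
from growthmix.gmm import GMMSpec, fit_gmm
from growthmix.effects import Contrast, rrr_onestep

cohort = gm.generate_cohort(gm.default_calibration(n_subjects=600, seed=5))
growth, subjects, pre = prepare_analysis(cohort)

fit = fit_gmm(growth, subjects,
              GMMSpec(K=4, membership_terms=("Hg_l2s", "primiparous"),
                      n_starts=3, seed=1),
              compute_vcov=True)
print(fit.converged, round(fit.loglik, 1), fit.class_shares().round(3))

sd = pre.exposures.scale_sd["Hg"]
print(rrr_onestep(fit, Contrast("doubling", "Hg", "Hg_l2s", 1.0 / sd),
                  reference=0)[["class", "estimate", "lo95", "hi95"]])
```

Output (seed 5):

```
True -18216.6 [0.33 0.4  0.18 0.09]
   class  estimate      lo95      hi95
0      1  1.136338  0.988784  1.305910
1      2  1.176339  0.993577  1.392717
2      3  1.405548  1.142044  1.729850
```

Read: classes are ordered by fitted 18-month weight-for-length; class 0 is
the slowest and the fit converged with shares (0.33, 0.40, 0.18, 0.09). A
doubling of toenail Hg multiplies the risk of following class 3 (the
fastest) rather than class 0 by ≈1.41 (95% CI 1.14–1.73); the generator's
injected per-doubling effects are exp(ln 1.5 / SD_log2) ≈ 1.28 on the
late-accelerating class and exp(ln 1.4 / SD_log2) ≈ 1.23 on the rapid
class, both inside the corresponding intervals.

The full analysis narrative lives in `analysis/01…04_*.py`
(simulate → fit/select/name → single-element effects → mixture), writing
artifacts under `results/`. The same pipeline is scriptable via the
`growthmix` CLI (`simulate`, `fit`, `effects`, `mixture`, `all`).

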