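# Methods

## Model

The longitudinal outcome is raw weight-for-length (g/cm), observed for
subject *i* at ages `t_{i1..i n_i}` (months) within [0, 18]. The growth
mixture model is a K-component mixture of linear mixed models:

- **Mean structure.** Each latent class *k* has its own mean curve
  `μ_k(t) = x(t)' β_k`, where `x(t)` is a quadratic B-spline basis with
  interior knots at 3.5 and 9 months by default (degree 2, boundary
  [0, 18]). The basis is parameterized as an explicit intercept plus the
  remaining normalized B-spline columns; because the normalized basis sums
  to one, this spans the same space while giving the intercept a clean
  interpretation for the random-effect structure. `n_basis = 3 + #knots`.
- **Within-subject dependence.** A subject-level random intercept with SD
  `σ_b` (shared across classes by default) plus iid residuals with SD
  `σ_e`: `Cov(y_i | k) = σ_b² J + σ_e² I`. Class-specific `σ_b`/`σ_e` are
  config options, off by default. Random slopes, autocorrelated residuals
  and non-Gaussian outcomes are out of scope.
- **Membership.** `P(class k | w_i) = softmax_k(w_i' γ_k)` with `γ_1 = 0`;
  `w_i` contains an intercept, the exposure term under study, and the seven
  adjustment covariates (maternal age, education, marital status, smoke
  exposure, fish intake, pre-pregnancy BMI, parity). The mean curves
  contain spline terms only; letting covariates shift the curves themselves
  is a config question we resolved as "off" — the scientific question is
  about membership, and covariate-shifted curves would change the meaning
  of the classes between exposure models.

Sex strata are fitted entirely separately (orchestration, not a model
feature).

## Estimation

EM on the observed-data likelihood, treating (class, random intercept) as
latent:

- E step: responsibilities `r_ik ∝ π_ik f_ik` via the rank-one
  Woodbury/Sherman–Morrison form of the class density (numerically stable
  as σ_b → 0; per-subject cost O(n_i)); posterior intercept moments
  `m_ik = σ_b² S_ik/(σ_e² + n_i σ_b²)`, `v_ik = σ_b² σ_e²/(σ_e² + n_i σ_b²)`
  with `S_ik` the residual sum.
- M step: responsibility-weighted least squares of `y − m` for each `β_k`;
  closed-form variance updates from the posterior moments; 2–3 Newton steps
  with step-halving on the weighted multinomial objective for γ (each step
  verified to increase the Q-function, preserving EM monotonicity, which is
  asserted in tests).
- Initialization: ridge-regularized per-subject spline coefficients are
  clustered by k-means into K groups; later starts jitter the resulting
  curves. Default `n_starts = 20` (mixture likelihoods are multimodal);
  simulation-heavy tests use 2–4 starts, which suffices at the separations
  they generate.
- Polish and convergence. EM converges linearly and its strict tolerance
  (relative log-likelihood change < 1e-8 and max parameter change < 1e-5)
  is often not reached within the iteration cap even when the optimum has
  been found to plotting accuracy. A quasi-Newton (L-BFGS) polish using the
  analytic observed-data score (Fisher's identity: posterior-weighted
  complete-data score) therefore runs afterwards; successful termination or
  a score sup-norm below 1e-2 certifies convergence. Fits that fail all of
  this are reported with `converged = False` — non-convergence is a
  first-class outcome propagated into effect tables, never silently
  dropped.
- Inference: the observed information is computed by central second
  differences of the log-likelihood in the natural parameterization at the
  optimum; its inverse provides Wald covariance for all free parameters
  (class curves, membership logits, SDs).
- Label canonicalization: classes are reordered by fitted mean outcome at
  18 months (ascending) after every fit, making labels reproducible; the
  likelihood is invariant under this relabeling.

Class-number selection (K = 1..6): discard non-converged fits; discard fits
where any modal class holds <5% of subjects; require >80% of each class's
modal members to have maximum posterior >0.7; choose minimal BIC
(−2ℓ + p·log n_subjects) among survivors. All rejections are recorded with
their rule.

## Exposure contrasts and effect estimates

Concentrations below the detection limit are substituted by LOD/√2 and
flagged. Toxic elements (As, Hg, Pb) enter continuously as log2-transformed
values divided by the analytic-sample SD of the log2 values (centring
recorded); the scaling constant is stored so a doubling is exactly
`δ = 1/scale_sd` on the model scale. Essential elements (Cu, Mn, Se) are
coded as sample tertiles (stable-rank ties) with the middle tertile as
reference.

Under the multinomial logit, the ratio-of-relative-risks estimand

    RRR_j = [P(j | shifted) / P(j | base)] / [P(ref | shifted) / P(ref | base)]

reduces *exactly* to `exp(δ (γ_j − γ_ref))` for any covariate vector; the
implementation re-verifies this identity numerically (to 1e-10) on every
call as a guard against term-indexing bugs. CIs are Wald on the log scale
(delta method through the observed information); no profile likelihood, no
multiplicity correction (α = 0.05 two-sided throughout).

The two-stage comparator regresses modal assignments in a separate
multinomial logistic model (statsmodels MNLogit) with the same covariates.
When the assignment model is exposure-free (how classes are enumerated in
practice before exposure modelling), its misclassification is
nondifferential and the two-stage estimate is attenuated toward the null
relative to the one-step estimate — the behaviour our low-separation
simulations reproduce. If instead modal assignments are taken from an
exposure-informed posterior, assignment errors become differential in the
exposure and can inflate the two-stage coefficient; both regimes are easy
to produce and the package leaves the choice of assignment model explicit.

Cohen's kappa (with optional best-permutation label alignment and the
large-sample SE) quantifies agreement between weight- and
weight-for-length-based assignments, supporting the transfer of class names
from the weight channel, where a growth-standard chart exists, to
weight-for-length.

## Reference selection and z-scores

Per class and scheduled visit, the member median of the outcome is compared
with the chart median (linear interpolation between chart rows);
`SSD_k = Σ_visits (median_k − M_chart)²` over the visit set common to all
classes. The argmin class is the reference ("Stable-slow"). Among the rest,
a class whose median sits at or below the chart through 9 months and above
it afterwards is "Late-moderate"; the remaining two are "Stable-moderate"
and "Rapid" by ascending 18-month median, with a final-median fallback (and
a logged warning) when no clean late-crossing class exists. LMS z-scores
use `z = ((x/M)^L − 1)/(L S)` (log form at L = 0) with L, M, S linearly
interpolated. Charts are user-supplied CSVs; the repository generates
synthetic stand-in charts in code and never redistributes chart tables.

## Mixture g-computation

Each element is scored by sample-quartile membership (cut points at
`np.quantile` i/4; values equal to a cut score below it; constant columns
flagged degenerate and excluded). A single conditional multinomial model of
modal class on all six scores plus covariates is fit; setting every score
to s and averaging predicted probabilities over the sample gives marginal
risks `r_j(s)`, and `log r_j(s) = a_j + ψ_j s` is fit by least squares over
s = 0..3. `exp(ψ_j)` is the per-class risk ratio for a simultaneous
one-quartile increase. Weights are the conditional coefficients normalized
within sign (unit sum per direction per class, exact by construction),
following the convention of reporting conditional weights when the
marginal structural model is nonlinear. CIs are 2.5/97.5 percentiles of ψ
over B = 500 nonparametric bootstrap resamples of subjects (the dyad is the
independent unit), seeded and reproducible. Whether to run one conditional
multinomial fit or three class-vs-reference binomial fits was an open
choice; the single multinomial fit keeps the class probabilities coherent
(they sum to one) and is what the marginalization step requires.

## Synthetic cohort generator

`default_calibration()` encodes the study-like conditions: 783 dyads,
sex ratio 0.494, four classes with target shares (0.322, 0.195, 0.363,
0.120); class mean curves pass through fixed per-visit targets (slow class
68.5 → 122 g/cm, rapid 64 → 150 g/cm) chosen so the cohort mean is ≈68 g/cm
at birth and ≈135 g/cm at 18 months; random intercept SD 6 g/cm and
residual SD 5 g/cm (birth SD ≈ 7.8 g/cm); visit schedule (0, 0.5, 1, 2, 4,
6, 9, 12, 15, 18) months with N(0, 0.25²) age jitter (birth exact and never
missing) and 8% independent visit missingness. Exposures are drawn through
a Gaussian copula with log-normal marginals whose medians and IQRs match
typical toenail panels (e.g. Hg median 0.08 µg/g, IQR 0.03–0.14; Se 1.00,
0.91–1.09); log-scale correlations lie in [0.12, 0.41] with Cu–Mn weakest
and Mn–Pb strongest; detection limits give ≈80% Hg and ≈100% Se detection.
Membership coefficients include a modest mercury effect (log 1.5 per SD of
log2 on the late-moderate class, log 1.4 on rapid) and a primiparity effect
(log 1.8 on rapid), with intercepts offset for the mean lift those terms
induce so marginal shares stay on target. Length is a deterministic
sex-specific saturating curve (≈50 → 82 cm) and weight is back-derived as
wfl × length / 1000 — the analysis uses only weight and weight-for-length,
so individual length variation is not simulated. Covariates follow simple
parametric distributions matched to the study's descriptive table.

What the generator does *not* emulate: informative missingness, secular or
seasonal trends, measurement rounding, gestational-age structure,
breastfeeding, and within-pair correlation of covariates beyond the
membership model. Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to real-data violations
of it.

## Simulation study sizes and identifiability

Test simulations are sized to run on one CPU in minutes: parameter recovery
uses 30 replicates of n = 600 with K = 3 classes spaced 2.5 residual SDs
apart; RRR coverage uses 40 replicates of n = 800 with K = 2; the
class-number selection study uses 20 seeds of n = 800 with K = 4. For the
selection study the random-intercept SD is set to 2 g/cm: with adjacent
curves 2–2.5 residual SDs apart, an intercept SD of 4 g/cm leaves the
four-class structure essentially unidentifiable at n = 800 (the
log-likelihood at the generating truth exceeds the two-class optimum by
only ~10 units, so BIC correctly prefers two classes) — class recovery
requires between-subject scatter small relative to the curve gaps, and the
selection study generates data in that regime.

## Numerical choices and degenerate inputs

- Tertile and quantile ties: stable rank order, deterministic.
- Knot-selection ties: lexicographically smallest knot tuple (relative RSS
  tolerance 1e-10).
- Posterior ties in modal assignment: lower class index, counted and
  logged.
- Outlier rule at visits with <2 observations: skipped with a warning (SD
  undefined).
- σ floors at 1e-6 during EM; information matrix inverted by pseudo-inverse
  when near-singular.
- Constant exposure columns: scaling raises; quantile scoring flags
  degenerate and excludes the column from the mixture model.

## Known limitations

- The vcov is the inverse observed information; it ignores uncertainty in
  knot selection and in the reference-class choice.
- Weighted multinomial Newton steps assume full-rank membership designs;
  perfect separation in two-stage models is caught and reported as
  non-convergence rather than resolved (no penalization).
- The bootstrap for the mixture analysis resamples subjects within stratum
  but conditions on the modal assignments (classification uncertainty is
  not propagated into the mixture CIs, matching the two-stage character of
  that analysis).
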