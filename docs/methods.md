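# Methods

## Profile geometry

A segmented eye is a pair of ellipses (cup, disc) in image pixel
coordinates.  The cup-to-disc ratio in direction *d* is the ratio of two
collinear distances measured along the same ray from the **cup centre**:
cup-boundary distance over disc-boundary distance.  Using a common origin
makes each CDR a pure ratio — invariant to image scale and magnification —
and keeps numerator and denominator comparable when the cup is off-centre
in the disc.  Ray–ellipse distances are the positive root of the quadratic
obtained in the ellipse-aligned frame; no polygonal approximation is
involved in the pipeline itself (dense polygonal boundaries appear only as
independent test oracles).

Angle convention: canonical angle 0° is the superior pole, the image
y-axis points down (raster order), and direction index *d* = 1..24 sits at
*d*·15°.  Right eyes index with increasing image *x*; left eyes are
mirrored about the vertical axis so anatomically homologous directions
share an index (the mapping *d* ↔ 24 − *d* is an involution, with the
vertical directions 12 and 24 fixed).  Whether 90° is temporal or nasal is
a labelling choice the classifier is invariant to, because mirroring makes
the two eyes statistically exchangeable; the convention block is embedded
in every model file and checked before a model is applied.

Directions where the cup boundary reaches or crosses the disc boundary are
emitted as *missing*, not clamped to 1: segmentation failures then flow
through the same missing-data pathway the model already supports, instead
of distorting the likelihood with boundary values.

Ellipse fitting from expert landmarks uses the numerically stable direct
least-squares conic fit with the ellipse constraint built into the
generalized eigenproblem (data are centred for conditioning; the conic
normalisation cannot affect the returned geometry because only the
eigenvector direction matters).  At least five non-collinear points are
required; a degenerate best conic raises rather than silently returning a
hyperbola.  Orthogonal point-to-ellipse residuals (Newton iteration on the
parametric stationarity condition) are available for fit quality reports.

DDLS-related scalars: RTD is min over observed directions of (1 − CDR_d),
i.e. the rim-to-disc ratio along the ray at the narrowest rim; DSV is the
vertical chord of the disc through the disc centre in pixels; vCDR is the
ratio of the cup and disc chords along the vertical line through the cup
centre.  RTD from the ray profile (rather than a diameter-based textbook
form) was chosen so that RTD, like the profile itself, is well defined for
partially segmented boundaries.

## Spatial model

Y_id = x(d, g)'β + b_i + e_id with per-group harmonic fixed effects
(sine and cosine at frequencies 2πkd/24, k = 1..m), a per-eye random
intercept b_i ~ N(0, σ_d²) and iid error e_id ~ N(0, σ_e²).  The harmonic
basis keeps the fitted mean curve continuous across the 360°→0° wrap; the
random intercept absorbs between-eye disc-size variation and induces the
compound-symmetric marginal covariance V = σ_d²J + σ_e²I, giving within-eye
correlation σ_d²/(σ_d²+σ_e²) between any two directions.

Estimation is REML (ML optionally).  The likelihood is profiled twice:
β by GLS, and σ_e² in closed form given the variance ratio λ = σ_d²/σ_e²,
leaving a one-dimensional criterion in log λ.  Per-eye sufficient
statistics and the rank-one (Sherman–Morrison) structure of V make each
evaluation O(n_eyes·q²) with no per-observation work, so hundreds of fits
per second are possible at study scale.  The bounded scalar minimisation
is polished by Brent root-finding on the *analytic* derivative of the
profiled criterion (derivative-free minimisation alone cannot localise a
flat optimum beyond ≈√machine-epsilon; with the analytic score the
balanced-layout estimates agree with closed-form ANOVA estimators to
~1e-16).  λ → 0 is allowed: a boundary fit σ_d = 0 is reported with a
flag, not treated as an error.  The fit is deterministic given the data.

Missing directions simply contribute no rows; each eye's marginal
covariance is the compound-symmetric matrix over its observed subset.
No imputation anywhere.

**Order selection** fits m = 1..5 with ML (candidate models differ in
fixed effects, so REML likelihoods would not be comparable), reports AIC
and BIC with k = q + 2 parameters and BIC sample size n_obs, and selects
the BIC minimiser (ties toward the smaller order).  The final model should
be refit with REML, which `pcdr fit --order auto` does.

**Fixed-effect tests** are Wald F statistics on contrasts of the
group-specific parametrization: Intercept (mean of the two group
intercepts, 1 df), Group (their difference, 1 df), Direction (the 2m
group-averaged harmonic coefficients), Direction × Group (the 2m
differences).  Denominator df follow a containment-style convention —
n_eyes − 2 for between-eye terms, n_obs − n_eyes − q + rank(L) for
within-eye terms.  Containment df are software-convention dependent, so
the asymptotic chi-square p-value is always reported alongside and the
den-df column should be read as descriptive.

**Diagnostics**: conditional residuals subtract the BLUP of the random
intercept; their empirical semivariogram over circular angular lag
(1..12 direction units) is summarised by a linear slope with a 95% CI.
Under the assumed iid error the variogram is flat; residual spatial
correlation (e.g. AR structure along the rim) shows as a positive slope,
which the test suite verifies in a misspecification probe.

## Classifier

Empirical-Bayes Gaussian discrimination with the plug-in estimates
(β̂, σ̂_d, σ̂_e).  Both groups share V, so on any observed subset S the
posterior log odds reduce exactly to log(p_G/p_H) + ½(D_H − D_G); the
implementation computes the density-ratio form (log space, dense solve)
*and* the Mahalanobis form (analytic rank-one inverse) on every call and
raises if they disagree — a permanent dual-route guard.  The shared-V
requirement is enforced by construction: means and covariance are always
subset to the same S, so the Gaussian normalising constants are
commensurable.  Priors default to training-set proportions and are
overridable (e.g. to a screening prevalence).  The decision rule is
boundary-inclusive: posterior ≥ p_th → glaucoma.

ROC/AUROC uses the tie-corrected pairwise-concordance statistic
(scikit-learn), with the operating point chosen closest to the (0,1)
corner, ties broken toward higher specificity.  Suspect/unknown eyes are
scored but excluded from ROC fitting and evaluation.  The repeated-split
evaluation refits the full model on each training split (default 70%),
estimates priors from that split, and reports AUROC plus rates at the
split's corner-optimal threshold; it is deterministic given its seed.
For complete profiles the population AUROC of the log-odds score has the
closed form Φ(Δ/√2) with Δ² = δ'V⁻¹δ, δ the mean-curve difference — used
as an independent check of the whole simulate→fit→score chain.

Screening projection rounds to the nearest person at each stage
(detected = round(sens·prev·N); false positives rounded separately before
summing referrals), since the referred count depends on rounding order.

## Synthetic data

`GenerativeTruth` defaults: order 2; healthy mean 0.375 − 0.075·cos(4πd/24)
(two maxima of 0.45 at d = 6 and 18, i.e. the horizontal directions 90°
and 270°, trough 0.30 at the vertical — the elliptical cup shape behind
the ISNT rule); glaucoma mean 0.65 − 0.02·cos(4πd/24) (flatter and
uniformly higher, as in advanced rim loss); σ_d = 0.0892, σ_e = 0.0414
(reference between-eye and within-eye SDs for semi-automated
segmentations); MCAR missingness rate 0 by default.  The mean curves are
stated constants, chosen for qualitative shape, and overridable.

Eyes whose 24 values do not all land in (0,1) are **redrawn**, not
clipped, keeping the retained sample exactly Gaussian conditional on
being in range; the redraw count is returned so unrealistic settings are
visible.  With the default glaucoma level (0.65) roughly 0.3% of
glaucomatous eyes are redrawn, which truncates the largest random
intercepts and biases σ̂_d downward by about 1% at n = 300 — visible in
the recovery numbers and documented rather than hidden.  A second frozen
configuration, `GenerativeTruth.overlapping()` (glaucoma intercept 0.475,
cos-harmonic −0.065; analytic AUROC ≈ 0.84), exists for checks that need
classification errors to actually occur — the default truth separates the
groups almost perfectly, so ROC behaviour near the boundary would be
untestable with it.

The segmentation generator draws disc ellipses (semi-major 80–120 px,
axis ratio 0.8–1, free rotation), scales them by a group-dependent cup
factor (healthy 0.30–0.50, glaucoma 0.60–0.80) with ±5% per-axis jitter
and a centre offset up to 10% of the disc minor axis, rejecting
configurations where the cup leaves the disc, and emits the analytic
ground-truth pCDR alongside for oracle tests.

What the generator does **not** emulate: segmentation error correlated
around the rim, non-MCAR missingness (real boundary failures cluster in
arcs), non-Gaussian tails, inter-eye correlation within a patient, and
any image-level artefact.  Passing tests therefore demonstrate
correctness of the estimation and decision machinery under the model's
own assumptions, not clinical performance on photographs.

## Problem sizes and numerical choices

Simulation-based checks use 100 replicates of 300 eyes for parameter
recovery, 100 replicates of 400 eyes for order selection, 2,000 eyes per
group for the AUROC bound and 1,000 random ellipse pairs for the geometry
oracle — sizes at which Monte-Carlo error is small relative to the
tolerances being verified while a full run stays in the tens of seconds.
Key tolerances: geometry vs polygonal oracle 1e-3 (pixel-equivalent, with
2·10⁴-gon oracles whose own error is ~1e-6); balanced-REML closed-form
agreement 1e-8; posterior duality 1e-12 (relative, guarding the
log-odds scale); AUROC bound 3 Monte-Carlo SEs (Hanley–McNeil).

Degenerate inputs are errors, not warnings: fewer than five landmarks,
collinear landmarks, non-elliptical conics, ray origins on or outside the
boundary, all-missing profiles, single-class ROC inputs, priors at 0 or 1.
The one deliberate soft failure is a cup crossing the disc in some
directions, which yields missing values with a warning (see above).

## Limitations

- The random-intercept model captures size via a level shift only; a
  genuinely tilted or locally notched disc violates compound symmetry.
  The variogram diagnostic detects this but the model does not fix it.
- Containment denominator df are a reporting convention; exact df from
  other mixed-model software will differ (the chi-square version will
  not).
- Priors estimated from training proportions are only appropriate when
  the deployment population resembles the training mix; for screening,
  set the prior to the population prevalence explicitly.
- The classifier assumes the same segmentation process at train and test
  time; a systematically different segmenter shifts profiles and
  invalidates the plug-in means.
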