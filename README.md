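# pcdr — spatial cup-to-disc-ratio profile analysis for glaucoma detection

Glaucoma deforms the optic nerve head: the neuroretinal rim narrows, often
asymmetrically, so a single vertical cup/disc ratio (vCDR) misses much of
the signal.  `pcdr` analyses the **whole** rim.  From a segmented optic-disc
photograph (a cup ellipse and a disc ellipse in pixel coordinates) it
measures the cup-to-disc ratio in 24 directions at 15° intervals around the
cup centre — the **pCDR profile** — and models and classifies that profile.

The package is aimed at researchers in ophthalmic image analysis and
biostatistics who have cup/disc segmentations (expert landmarks or an
automatic segmenter) and want an interpretable, data-efficient alternative
to black-box classifiers, including a classifier that tolerates partially
segmented boundaries without imputation.

## The model

For eye *i* with diagnostic group *g(i)* ∈ {healthy, glaucoma} and
direction *d* = 1..24 (angle *d*·15°, 0° at the superior pole, left eyes
mirrored into a common anatomical frame):

```
Y_id = x(d, g(i))' β + b_i + e_id,   b_i ~ N(0, σ_d²),  e_id ~ N(0, σ_e²)
```

The fixed effects are per-group intercepts plus per-group sine/cosine
harmonics of direction at frequencies 2πkd/24, k = 1..m (order m = 2 by
default, q = 10 coefficients — consistent with an elliptical cup/disc
shape; the order can also be selected by AIC/BIC).  The per-eye random
intercept `b_i` absorbs disc-size differences between eyes and induces a
compound-symmetric within-eye covariance `V = σ_d² J + σ_e² I`, whose
inverse is available analytically.  All parameters are estimated by REML,
using each eye's observed directions only — missing directions never need
imputation.

Classification is empirical-Bayes Gaussian discrimination.  For a new
profile `Y` observed on directions `S` with priors `p_G, p_H`:

```
log odds(glaucoma) = log(p_G/p_H) + ½ (D_H − D_G)
```

where `D_H` and `D_G` are squared Mahalanobis distances of `Y_S` from the
healthy and glaucomatous mean curves under `V_S`.  The difference
`D_H − D_G` is the **Disc Deformation Index (DDI)**: a covariance-rescaled
shape comparison, positive when the disc looks more glaucomatous.  An eye
is called glaucomatous when the posterior probability is ≥ a threshold
(0.90 by default, or the ROC corner-optimal point).  The module also
computes the DDLS-related scalars: rim-to-disc ratio at the narrowest rim
(RTD), vertical disc size in pixels (DSV) and vCDR, plus ROC/AUROC
evaluation, repeated 70/30 split evaluation and population screening-yield
projections.

Because real reference image datasets are external, the package ships a
generator (`pcdr.simulate`) that draws labelled profiles and ellipse pairs
from the model itself, with documented default parameters; every stage is
therefore testable offline.

## Worked example

```python
from pcdr import (GenerativeTruth, GroupPriors, classify, fixed_effect_tests,
                  posterior_probability, reml_fit, simulate_profiles)

truth = GenerativeTruth(seed=42, missing_rate=0.1)   # σ_d=0.0892, σ_e=0.0414
profiles, _ = simulate_profiles(truth, 300, 150)
fit = reml_fit(profiles, order=2)

priors = GroupPriors.from_labels(p.group for p in profiles)
r = posterior_probability(profiles[3], fit, priors)
print(r.D_H, r.D_G, r.ddi, r.posterior, classify(r, 0.9))
```

The fit report for this run (via `pcdr fit --report`):

```
term                  num df  den df             F           p
Intercept                  1     448     13531.343      <0.001
Group                      1     448      1034.587      <0.001
Direction                  4    9300      1432.563      <0.001
Direction x Group          4    9300       457.677      <0.001

Between-eye variation, SD   0.0885
Within-subject variation, SD 0.0414
Spatial correlation          0.8203
```

The variance components recover the generator truth (0.0892 / 0.0414);
the spatial correlation σ_d²/(σ_d²+σ_e²) ≈ 0.82 says 82% of within-eye
variance is shared across directions (disc size).  All four effects are
strongly significant: the profile is not flat, and the two groups differ
in both level and shape.  Scoring the fourth simulated eye (a healthy one,
22 of 24 directions observed) gives `D_H = 18.8`, `D_G = 46.7`, so
`DDI = −27.9`, posterior ≈ 0.0000 → classified healthy.  A repeated
70/30-split evaluation of the same data (`repeated_split_evaluation`,
20 splits) yields a mean AUROC of 100.0% — the default truth separates the
groups almost completely, like high-quality semi-automated segmentations.

The same pipeline is scriptable from the shell:

```sh
pcdr simulate --n-healthy 300 --n-glaucoma 150 --seed 42 --out-profiles p.csv
pcdr fit --profiles p.csv --out-model model.json --report report.txt
pcdr predict --model model.json --profiles p.csv --out predictions.csv
pcdr evaluate --profiles p.csv --n-splits 100 --seed 0 --out eval.json
```

File formats (CSV/JSON schemas, angle conventions) are documented in
`pcdr.io`; model files embed the angle convention and refuse profiles
extracted under a different one.

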