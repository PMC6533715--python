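# Methods

## The shape model and the severity score

A maximal forced expiration traced as flow against expired volume rises to
peak expiratory flow (PEF) and then descends to zero at forced vital
capacity (FVC). Only the descending limb carries the severity signal used
here. It is normalized onto the unit square — `u = (FVC − V)/(FVC − V_PEF)`
(1 at the PEF point, 0 at end-expiration) and `q = Q/PEF` — and resampled
by linear interpolation onto a uniform grid of `n_grid = 100` points
including both endpoints. The PEF point is the first sample attaining the
global flow maximum. Because the limb is shape-only, the score is exactly
invariant under `Q → aQ` and `V → bV + c` (a, b > 0); no percent-predicted
normalization is used anywhere.

The limb is modelled as a power law whose exponent crosses between two
regimes,

    q(u) = u^θ(u),    θ(u) = θ_d + (θ_p − θ_d) · σ((u − u*)/w),

with σ the standard logistic. The rationale is duct mechanics: the
pressure dissipated by flow in a compliant airway rises steeply as
effective calibre falls, so an emphysematous lung sustains near-peak flow
over high-to-mid volumes (θ_p < 1, flattening) and then collapses abruptly
(θ_d ≫ 1, kinking), whereas airway-predominant obstruction yields one
uniform scooped exponent. A single-phase model `q = u^θ` is fitted
alongside; the two-regime fit is kept only when it improves the sum of
squared residuals by at least 2% relative, otherwise the limb is declared
single-phase (no identifiable transition).

The score maps the regime contrast to 0–10:

    ESI = 10 · clip((θ_d − θ_p) / 3.5, 0, 1),

single-phase limbs scoring 0. The reference contrast 3.5 is calibrated so
that the severe archetypes of the synthetic generator land above the
conventional severe boundary of 5 and moderate-range curves near the
moderate group mean. A uniformly concave single-phase limb (θ < 1) also
scores 0: with no second regime there is no contrast to measure.

### Fitting

Bounded trust-region least squares (analytic Jacobian) from a 3×3×3×2
multi-start grid over (θ_p, θ_d, u*, w); bounds θ ∈ [0.05, 6],
u* ∈ [0.1, 0.9], w ∈ [0.02, 0.5]; ties resolved by lowest SSE then lowest
θ_d. Three numerical refinements matter in the presence of measurement
noise, and all three reduce to exact least squares on noise-free data:

1. **Nuisance amplitude.** The limb is normalized by the observed PEF — the
   maximum over ~200 noisy samples — which is biased high by a few percent
   and scales every `q` down multiplicatively. Both models therefore carry
   a bounded amplitude factor (0.8–1.2; profiled analytically in the
   single-phase fit). On exact data the amplitude is 1.
2. **Censored-noise mean.** Physical flow cannot be negative, so noise at
   the near-zero tail is clipped and has positive mean. The refit models
   the observation mean of the censored Gaussian,
   `E[max(N(m, σ̂), 0)] = m·Φ(m/σ̂) + σ̂·φ(m/σ̂)`, with σ̂ estimated from
   the unpenalized residuals; as σ̂ → 0 this is the identity.
3. **Noise-adaptive width shrinkage.** The pair (θ_d − θ_p, w) is only
   weakly identified on noisy limbs: widening the transition can mask extra
   contrast along a nearly flat likelihood ridge. A Fisher-information
   analysis at σ = 0.02 per grid point gives sd(θ_d − θ_p) of 0.5–0.9 for
   mid-severity shapes with w free, versus 0.08 with w known. The refit
   therefore adds a Gaussian penalty drawing w towards a population-typical
   width of 0.15 with prior SD 0.02, weighted by σ̂ so that the penalty
   vanishes on exact data. The prior centre and width were calibrated once
   on synthetic development curves (the usual bias–variance bandwidth
   trade-off) and then frozen.

Even so, the information bound is real: at σ = 0.02 the fitted score lands
within 0.8 of truth for roughly 80–85% of synthetic curves spanning the
full severity range, with the residual heavy tail concentrated at
mid-severity wide-transition shapes where the contrast is intrinsically
under-determined. Scores on noise-free curves recover the generating
parameters to well under 5% relative error.

### Spirometric indices

FEV1/FVC/PEF are reconstructed from the sampled curve for validation
plumbing: expiratory time is `t(V) = ∫ dV′/Q(V′)` (trapezoid on the
samples; zero-flow endpoints borrow the nearest positive reciprocal flow),
and the clock starts at the back-extrapolated time zero — the tangent at
peak flow extrapolated to zero expired volume, the standard spirometric
convention. Without back-extrapolation the arbitrary effort-dependent
rise of the ascending limb leaks directly into FEV1. If the reconstructed
time never reaches 1 s, FEV1 is reported as FVC with a flag.

## Synthetic cohort

One latent severity `s ∈ [0, 1]` drives all modalities:

* **Curve shape:** θ_p = 1.8 − 1.5s, θ_d = 1.8 + 1.6s, u* = 0.6,
  w = 0.25 − 0.18s. At s = 0 the limb is a pure scoop (θ = 1.8); at s = 1
  a flattened limb (θ_p = 0.3) kinking sharply (θ_d = 3.4, w = 0.07). The
  implied true score is 10·clip(3.1s/3.5, 0, 1).
* **Lung scale:** FVC ~ logNormal(ln 3.5, 0.15) L — forced vital capacity
  is largely preserved in emphysema — while PEF ~ logNormal(ln 7 − 0.65s,
  0.15) L/s: absolute flows fall with worsening obstruction (the log-slope
  reproduces a roughly one-third FEV1 drop from the no-emphysema to the
  severe group while FVC stays flat). The shape-only score never sees
  these scales; they matter only for the FEV1/FVC validation coupling.
* **Curves:** linear flow rise over a rise fraction U(0.05, 0.12) of FVC,
  two-regime descent, additive Gaussian flow noise (SD = noise_sd · PEF,
  default 0.02) clipped at zero, first/last samples pinned to zero flow;
  200 samples per curve (a typical spirometer trace), all randomness from
  one seeded generator.
* **CT fractions:** %LAA_-950insp follows a monotone map of s
  (1 + 40·s^1.6 plus ±1 jitter) clipped into group-consistent ranges —
  NE (1, 5.5), ME (6.5, 13.5), SE (14.5, 35) — so every record's staging
  class matches its group by construction. %pLDA is 70–95% of %LAA;
  %LAA_-856exp ≈ 2.2·%LAA + 15 (matching the scale of reported gas-trapping
  means); %fLDA ≈ %LAA_-856exp − %pLDA, clipped to keep the voxel classes
  consistent. Paired volumes are synthesized by assigning exact voxel
  counts per response-map class and sampling HU uniformly within
  class-consistent ranges.
* **Profiles:** per region (left/right × upper/middle/lower), weights over
  the four ordered classes from a Beta(1 + 4s_r, 5 − 4s_r) density
  integrated over four equal bins, with per-region severity jitter
  (SD 0.05) and near-uniform volume weights.
* **Cohort structure:** per group a target score is drawn from the group
  Gaussian (means 1.1/3.1/6.8, SDs 1.5/2.6/2.5, sizes 57/58/79), clipped to
  [0, 10] and inverted to s through the score map (s clipped to [0, 1], so
  targets above the map's ceiling of ~8.86 saturate).

### Gas compression

`apply_gas_compression` re-plots a curve on the plethysmographic (thoracic)
volume axis: under expiratory effort the intrathoracic gas is compressed by
Boyle's law, so the thoracic volume change exceeds the expired volume,
`V_pleth = V + ΔV(u)` with `ΔV = TGV·p(u)/(P_B + p(u))`, P_B = 101.3 kPa.
The effort profile is `p(u) = palv·sin(πu/2)`: alveolar driving pressure is
maximal near total lung capacity and declines with volume, so compression
is concentrated at high-to-mid volumes and is released towards
end-expiration. Consequently the early flow drop spans *less* volume on
the thoracic axis — the plethysmographic curve is steeper exactly where the
mouth-volume curve of an emphysematous subject looks flat. A profile that
vanished at the PEF point would shift volumes the other way and make the
thoracic curve flatter, contradicting that behaviour, which is why the
peak sits at u = 1.

### What the generator does not emulate

Real MEFV curves carry effort variability, cough artefacts, and
back-extrapolation failures; real CT carries scanner/kernel effects,
registration error and spatially structured emphysema, none of which are
simulated (volumes are voxel-aligned by construction, HU are uniform within
class). Passing tests demonstrate internal consistency of the methods
under the stated noise model — not clinical performance.

## CT densitometry

Strict thresholds: a voxel is "low" below −950 HU (inspiration) or −856 HU
(expiration); equality is assigned to the non-low side, preserving
complementarity of the class rules. The insp-low/exp-high combination has
no established name and is labelled Other: it is excluded from the three
named percentages but kept in the denominator, so the four classes
partition the mask and %LAA_-950insp = %pLDA + %Other identically.
Staging is NE < 6 ≤ ME < 14 ≤ SE on %LAA_-950insp. Lung masks are inputs;
no segmentation or registration is implemented.

## SILA and clustering

For two subjects, per region, SILA accumulates |CDF_p(k) − CDF_q(k)| over
the three internal cut points of the ordered classes — exactly the
1-Wasserstein distance between the class distributions with unit ground
distance, hence a pseudometric. Normal is included as grade 0 (the
alternative, restricting to the three LAA grades, would ignore how much of
the lung is normal at all). Regional distances are combined with volume
weights; for a pair the two subjects' weights are averaged. Only the four
ordered classes enter; nonzero ground-glass/reticular/honeycombing
fractions are renormalized out with a warning.

Affinity propagation runs vectorized responsibility/availability updates
on the negated dissimilarity, diagonal set to the preference (default:
median off-diagonal similarity), damping 0.7, declaring convergence when
the exemplar set is stable for 50 iterations (cap 500). A tiny seeded
jitter (1e−12 of the similarity range) breaks exact ties. On
non-convergence a valid labelling is still returned with
`converged=False`.

## Statistics

* **Steiger's Z** for two dependent overlapping correlations uses Fisher
  transforms with the asymptotic covariance evaluated at the
  back-transformed mean correlation; the input 3×3 correlation matrix must
  be positive semidefinite. A subject-resampling bootstrap variant is
  provided as the "robust" reading.
* **Welch ANOVA** accepts raw groups or (mean, SD, n) triples — the
  statistic is a function of the summaries only, so printed tables can be
  tested directly. **Games–Howell** uses pairwise Welch degrees of freedom
  and the studentized-range distribution with the number of groups as the
  range parameter.
* **Logistic regression** is Newton–Raphson maximum likelihood; perfect or
  quasi-separation is detected (disjoint class ranges or runaway
  coefficients) and flagged, with the returned coefficients still ranking
  subjects monotonically so ROC analysis remains valid.
* **cv_roc** stratifies ten folds (seeded), fits on each training split and
  scores held-out probabilities. The reported ROC/AUC is computed on the
  pooled held-out probabilities (a rank statistic identical to
  Mann–Whitney U/(n₁n₂)); per-fold AUCs and a vertically averaged ROC over
  a common false-positive grid summarize fold variability. The operating
  point maximizes Youden's J, ties broken towards higher specificity.
* **Chi-squared** is Pearson's test without continuity correction; all
  expected counts must be positive.

## Problem sizes used in the checks

The end-to-end checks run the full 194-subject cohort once (about a minute
of curve fitting) and share it; score-recovery studies use 200 seeded
curves; type-I-error simulations use 2000 replicates at n ≈ 100–200; the
ROC simulation averages 200 replicates of the 194-subject design. The
acceptance script runs the ROC simulation only (a few seconds).

## Known limitations

* The transition width is intrinsically under-determined at realistic
  noise (see the identifiability analysis above); fitted w should be read
  as a regularized, not a measured, quantity on noisy data.
* The score saturates at a contrast of 3.5: contrasts beyond it are
  indistinguishable at 10.
* The generator's severity is one-dimensional; mixed airway/emphysema
  phenotypes that move θ_p and θ_d independently are not simulated.
* SILA with differing per-subject volume weights is a dissimilarity, not a
  strict metric (the weight averaging can mildly violate the triangle
  inequality when weights differ grossly); with shared weights it is a
  pseudometric, which the tests assert.
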