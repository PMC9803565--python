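# Methods

This note records the models implemented in `btseg`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
phantom studies do and do not demonstrate.

## Phantom model

Real clinical MRI is not redistributable, so the test bed is a
parametric phantom: an axis-aligned ellipse (semi-axes 0.42 × the image
side) of "brain tissue" intensity on a dark background, containing one
disk of "tumour" intensity placed uniformly at random wholly inside the
ellipse.  Default tissue means are (20, 120, 230) on the 8-bit scale —
three well-separated classes, the tumour brightest, as in
contrast-enhanced imaging.  Degradations:

* **Noise** — additive zero-mean Gaussian, clipped to [0, 255].  MRI
  magnitude noise is Rician, but at the moderate SNRs studied here the
  Gaussian approximation is standard; Rician noise is a declared
  non-goal.  Default study level σ = 10 (about 10 % of the
  tissue–tumour contrast), with σ = 15 for the denoising stress test.
* **Blocking** — per 8×8 tile, a DCT is quantized with the standard
  luminance table scaled by an IJG-style quality factor, reproducing
  JPEG-like boundary steps.  Tiles are level-shifted by their own mean
  (not the fixed 128 of JPEG) so constant regions are exactly
  representable at every quality; quality 100 is the identity.

Phantoms are pure functions of (spec, seed): the same spec yields
bit-identical images, which is what makes every downstream study
reproducible.

What the phantom does **not** emulate: anatomy beyond one ellipse,
intensity inhomogeneity (bias fields), partial-volume edges, Rician
noise, 3-D structure.  Passing the phantom studies therefore shows the
pipeline's internal consistency and its behaviour under controlled
degradation — not clinical performance.

## Denoising

Pipeline: 2-level 2-D DWT (periodized `bior4.4`) → universal soft
threshold of each detail band → adaptive bilateral filter of the
approximation band at each level → inverse DWT → clip to [0, 255].

* **Wavelet and depth.** A biorthogonal 9/7-class wavelet with
  symmetric filters avoids phase distortion at edges; two levels reach
  the frequency band where blocking energy lives without touching
  gross anatomy.  Periodization keeps exact size halving and perfect
  reconstruction (verified to 1e−8 relative).
* **Threshold.** T = σ̂ √(2 ln N) per detail band, σ̂ = MAD/0.6745 of
  the band's diagonal detail.  The soft rule is the default
  (continuous shrinkage, no spurious spikes); the hard rule is a
  config switch.
* **Bilateral base scales.** σ_d = 1.8 px with an 11×11 window; the
  base range scale is σ_r = 1.0·σ̂ — one noise standard deviation, so
  noise-level variation is averaged while tissue contrasts (an order
  of magnitude larger) are preserved.
* **σ_r adaptation.** Block boundaries are probed with a [−1, 0, 1]
  central difference spanning the boundary, so a clean step of height
  h reports exactly h; at a detected boundary σ_r is raised to
  max(base, 1.1·step) and decays linearly back to base over a 2-pixel
  band.  Two guards keep real structure safe: a per-line cap at twice
  the boundary line's median response (blocking is consistent along a
  line; an isolated large response is a genuine edge crossing it, or a
  noise spike), and a gate at 3σ̂ (a step must stand out from noise to
  count as an artifact).  Without these guards the filter blurs every
  edge that happens to cross a block-boundary line, and denoising can
  be a net loss.
* **σ_d adaptation.** σ_d is scaled by clamp(s₀/(s₀ + a), 0.3, 1) where
  a is the local intensity standard deviation *in excess of* the noise
  floor s₀ = σ̂.  The excess matters: raw local std is ≈ σ̂ even in
  perfectly flat regions, and driving σ_d with it would cripple
  smoothing everywhere.
* **Degenerate inputs.** Noise estimates are floored at 1e−6 and σ_r at
  1e−3, so noiseless images pass through essentially unchanged (the
  near-identity limit is tested at a max deviation of 1 intensity
  unit).

Measured on 96×96 phantoms: MSE against the clean image improves in
20/20 seeds at σ = 10 and σ = 15 (mean MSE ratio ≈ 0.46 at σ = 15), and
the mean block-boundary step drops in 20/20 seeds on quality-30 blocky
inputs.

## Segmentation

**FCM.**  J_m = Σᵢ Σⱼ u_ij^m ‖x_i − c_j‖², m = 2 by default.
Alternating updates descend J_m monotonically (tested over 20 random
starts).  Conventions: memberships of a point at zero distance from
one or more centers are split equally among those centers; a cluster
whose total membership vanishes raises a diagnostic error; iteration
stops when max|ΔU| < 1e−5 or after 300 rounds.  All core operations
accept per-point weights.

**GCPSO.**  Canonical guaranteed-convergence form: non-best particles
use v ← ωv + c₁r₁(pbest − x) + c₂r₂(gbest − x); the globally best
particle uses v ← −x + gbest + ωv + ρ(t)(1 − 2r), i.e. its next
position samples gbest + ωv ± ρ uniformly.  ρ doubles after more than
sc = 15 consecutive improvements of gbest and halves after more than
fc = 5 consecutive failures; a success resets the failure counter and
vice versa; ρ is clamped to [1e−10, data range].

**Hybrid.**  Population 20, ω = 0.72, c₁ = c₂ = 1.49, ρ(0) = 1 —
standard constriction-regime values.  Fitness is J_m with memberships
recomputed at the particle's centers.  Every generation each particle
is refined by 2 FCM iterations and keeps the refined centers when
fitness improves (Lamarckian).  Termination: 20 stagnant generations
or 100 total; the returned solution is gbest polished to full FCM
convergence, so the hybrid can never end worse than the basin it
found.  All of these are config knobs; the interleaving schedule
(refine_every / inner_fcm_iters) is deliberately exposed because no
single canonical schedule exists.

**Images.**  Pixel features are intensities only (1-D).  The image's
unique rounded 8-bit values are clustered with pixel counts as sample
weights — algebraically identical objective and centers to per-pixel
clustering, at ≤ 256 points instead of 10⁴–10⁵.  Labels are reordered
by ascending center intensity so label c−1 is always the brightest
class; max-membership ties go to the lowest label.  The tumour mask is
the brightest class restricted to its largest 8-connected component
(the tumour is modelled compact; scattered bright misclassifications
are dropped).

Measured: 3 well-separated 2-D Gaussian blobs (σ = 1, 50 points each)
are recovered within 0.5 of the true means in 20/20 seeds; the
noiseless 3-level phantom is segmented exactly; at σ = 10 after
denoising, pixel accuracy ≥ 95 % and tumour Dice ≥ 0.9 in 10/10 seeds
(typically ≈ 99.9 % and ≈ 0.997).

## Texture features

Directed (unsymmetrized) co-occurrence matrices at signed offsets
(0,1), (−1,1), (−1,0), (−1,−1) — the 0°/45°/90°/135° probes with
negative row offsets pointing up — at 128 and 256 uniform gray levels
(bin = ⌊v·levels/256⌋).  Features: contrast Σ(i−j)²P, correlation from
the marginal means/stds, energy ΣP², homogeneity ΣP/(1+(i−j)²).
Correlation with a zero-variance marginal is reported as NaN rather
than an arbitrary number.  A `symmetric` flag accumulates P + Pᵀ for
users who prefer the symmetrized convention.  The implementation
agrees with `skimage.feature.graycomatrix`/`graycoprops` to 1e−10
under matched conventions.

## Classification

The five kernels are implemented directly (the linear, polynomial
(⟨x,y⟩+1)^d, Gaussian RBF exp(−‖x−y‖²/2σ²), exponential RBF
exp(−‖x−y‖/2σ²) with the unsquared distance, and ANOVA
(Σ_k exp(−σ(x_k−y_k)²))^d — the last two follow the standard
conventions since no single canonical definition exists).  Features
are standardized; the soft-margin dual (C = 1) is solved by a standard
QP via a precomputed Gram matrix.  The kernel study sweeps polynomial
degree 1–5 and radial/ANOVA scale 1–5 with stratified 5-fold CV and
reports each family's best sensitivity/specificity/accuracy.  On 40
tumour vs 40 tumour-free phantom textures (32 GLCM features each) the
GRBF kernel reaches 100 % cross-validated accuracy — the phantom
classes are far more separable than clinical data, so this is a
correctness check, not a clinical claim.

## Evaluation conventions

Pixel-level rates: TPR = 100·TP/(TP+FN), TNR = 100·TN/(TN+FP),
FNR = 100 − TPR, FPR = 100 − TNR, accuracy = (TPR + TNR)/2.  The
balanced-accuracy convention is used because it is the arithmetic that
published per-image benchmark rows of this pipeline family satisfy
exactly (two rows of one comparison table deviate from it and are
presumed typos).  It is *not* symmetric under swapping prediction and
truth, which is documented and tested.  A truth mask lacking a class
yields NaN for the affected rates.  PSNR uses peak 255 and reports
infinity for identical images.

## Problem sizes

The standard study sizes are 96×96 phantoms, 10–20 seeds per property,
150-point blob fixtures, and 80-image texture datasets — small enough
for the full suite to run in seconds while keeping every estimate's
Monte-Carlo error well inside the tested margins.

## Known limitations

* Phantom realism as listed above; clinical performance is untested.
* Intensity-only pixel features: no spatial regularization, so heavy
  noise without denoising produces speckled label maps.
* The universal threshold over-smooths fine texture at high σ; the
  hard rule recovers some of it at the cost of occasional artifacts.
* GCPSO guarantees local, not global, convergence; the swarm makes
  escaping poor FCM basins likely, not certain.
* 2-D single-channel only; no DICOM/volume handling.
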