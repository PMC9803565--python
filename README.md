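# btseg

Brain-tumour MRI analysis toolkit: adaptive bilateral multiresolution
denoising, hybrid GCPSO–FCM fuzzy segmentation, GLCM texture features,
kernel SVM classification, and the matching evaluation metrics.

`btseg` is aimed at medical-image-analysis practitioners who want a
tested, reproducible implementation of this classic pipeline.  Because
clinical MRI datasets are rarely redistributable, the package ships a
deterministic phantom generator (elliptical brain, compact bright
tumour, exact ground-truth masks, optional Gaussian noise and JPEG-style
blocking artifacts) so every stage runs end-to-end with no downloads.

## The methods

**Denoising.** The image is decomposed into wavelet sub-bands
(biorthogonal 9/7-class wavelet, 2 levels).  Detail bands are shrunk
with the universal threshold T = σ̂√(2 ln N) (σ̂ from the median absolute
deviation of the finest diagonal band); each approximation band passes
through a bilateral filter

&nbsp;&nbsp;&nbsp;&nbsp;w(p, q) ∝ exp(−‖p−q‖²/2σ_d²) · exp(−(I_p−I_q)²/2σ_r²)

whose two scales adapt locally: σ_r is raised at block-transform
boundaries to at least the measured boundary discontinuity (a range
scale below a discontinuity cannot reduce it; one above it can), and
σ_d is shrunk where texture activity exceeds the noise floor, so
texture is not over-smoothed.  Block discontinuities are probed with a
[−1, 0, 1] central difference spanning each boundary.

**Segmentation.** Fuzzy c-means minimizes
J_m = Σᵢ Σⱼ u_ij^m ‖x_i − c_j‖² via the membership update
u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)} and weighted-mean centers.  Because
FCM is a local optimizer, it is wrapped in a guaranteed-convergence
particle swarm (GCPSO): particles encode center sets, fitness is J_m at
the particle's centers, and the globally best particle samples a box of
diameter ρ(t) around gbest, v ← −x + gbest + ωv + ρ(t)(1−2r), with ρ
doubling after more than sc = 15 consecutive successes and halving
after more than fc = 5 consecutive failures.  Each particle is
periodically refined by a few FCM iterations (Lamarckian replacement).
The brightest cluster, reduced to its largest connected component,
becomes the tumour mask.

**Texture & classification.** Gray-level co-occurrence matrices at
0°/45°/90°/135° and 128/256 gray levels give contrast, correlation,
energy and homogeneity per direction; a soft-margin SVM with one of
five kernels (linear, polynomial, Gaussian RBF, exponential RBF, ANOVA)
separates tumour from tumour-free texture, reporting sensitivity,
specificity and accuracy.  Segmentation masks are scored with
pixel-level TPR/TNR/FPR/FNR and the balanced accuracy (TPR + TNR)/2.

## Worked example

```python
from btseg import (PhantomSpec, make_phantom, add_noise,
                   adaptive_bilateral_multiresolution, segment_image,
                   tumour_mask, confusion_rates, dice, mse, psnr)

spec = PhantomSpec(height=96, width=96, tumour_radius=10, seed=3)
clean, truth = make_phantom(spec)          # noiseless phantom + mask
noisy = add_noise(clean, sigma=10.0, seed=42)
denoised = adaptive_bilateral_multiresolution(noisy)
print(f"MSE  noisy->clean    : {mse(noisy, clean):7.2f}")
print(f"MSE  denoised->clean : {mse(denoised, clean):7.2f}")
print(f"PSNR denoised        : {psnr(denoised, clean):7.2f} dB")

labels = segment_image(denoised, c=3)      # 0=background 1=tissue 2=tumour
pred = tumour_mask(labels)
r = confusion_rates(pred, truth)
print(f"TPR {r.tpr:.3f}  TNR {r.tnr:.3f}  accuracy {r.accuracy:.3f}")
print(f"Dice overlap         : {dice(pred, truth):.4f}")
```

prints

```
MSE  noisy->clean    :   98.71
MSE  denoised->clean :   73.30
PSNR denoised        :   29.48 dB
TPR 99.045  TNR 100.000  accuracy 99.522
Dice overlap         : 0.9952
```

i.e. denoising removed about a quarter of the noise energy at σ = 10,
and the recovered tumour mask misses under 1 % of true tumour pixels
with no false positives.  The same pipeline is available from the
shell:

```sh
btseg phantom --height 96 --width 96 --radius 10 --sigma 10 --seed 3 \
      --out noisy.png --mask-out truth.png
btseg denoise noisy.png --out denoised.png
btseg segment denoised.png --labels-out labels.png --mask-out mask.png --seed 3
btseg eval mask.png truth.png
```

`btseg run` executes the whole pipeline from a YAML config and writes
every intermediate artifact plus a JSON report; `btseg features` and
`btseg classify --study` cover the texture and kernel-comparison
stages.

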