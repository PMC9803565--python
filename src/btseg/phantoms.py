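"""Synthetic MRI-like phantom generation.

Real clinical scans are rarely redistributable, so every stage of the
pipeline is exercised on deterministic phantoms: an elliptical "brain"
of intermediate intensity on a dark background, containing a compact
bright disk standing in for a tumour, with exact ground-truth masks.
Additive Gaussian noise and JPEG-style 8x8 blocking artifacts can be
layered on top to emulate acquisition noise and lossy compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_region_map",
    "add_noise",
    "add_blockiness",
]

# IJG baseline luminance quantization table (quality 50).
_JPEG_LUMA_Q50 = np.array(
    [
        [16, 11, 10, 16, 24, 40, 51, 61],
        [12, 12, 14, 19, 26, 58, 60, 55],
        [14, 13, 16, 24, 40, 57, 69, 56],
        [14, 17, 22, 29, 51, 87, 80, 62],
        [18, 22, 37, 56, 68, 109, 103, 77],
        [24, 35, 55, 64, 81, 104, 113, 92],
        [49, 64, 78, 87, 103, 121, 120, 101],
        [72, 92, 95, 98, 112, 100, 103, 99],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image.

    Parameters
    ----------
    height, width : int
        Image dimensions in pixels (at least 32 each).
    tissue_means : tuple of float
        Mean intensities of (background, brain tissue, tumour), strictly
        increasing within [0, 255] — the tumour is the brightest class.
    tumour_radius : float
        Radius of the tumour disk in pixels; must fit well inside the
        brain ellipse (< min(height, width)/4).
    noise_sigma : float
        Standard deviation of additive Gaussian noise (0 = clean).
    block_quality : int or None
        If set (1-100), JPEG-style 8x8 blocking artifacts are applied at
        this quality after noising.
    seed : int
        Seed for tumour placement and noise; same seed, same bytes.
    """

    height: int = 128
    width: int = 128
    tissue_means: tuple[float, float, float] = (20.0, 120.0, 230.0)
    tumour_radius: float = 12.0
    noise_sigma: float = 0.0
    block_quality: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be at least 32x32")
        means = tuple(float(v) for v in self.tissue_means)
        if len(means) != 3:
            raise ValueError("tissue_means must list background, tissue, tumour")
        if not all(0 <= v <= 255 for v in means):
            raise ValueError("tissue_means must lie in [0, 255]")
        if not (means[0] < means[1] < means[2]):
            raise ValueError("tissue_means must be strictly increasing")
        if not 1 <= self.tumour_radius < min(self.height, self.width) / 4:
            raise ValueError(
                "tumour_radius must be >= 1 and < min(height, width)/4"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.block_quality is not None and not 1 <= self.block_quality <= 100:
            raise ValueError("block_quality must be in 1..100")


def _geometry(spec: PhantomSpec):
    """Brain ellipse and a seed-dependent tumour centre inside it."""
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = 0.42 * h, 0.42 * w  # semi-axes (rows, cols)
    rng = np.random.default_rng(spec.seed)
    r = spec.tumour_radius
    # Sample a tumour centre such that the whole disk stays inside the
    # ellipse: shrink the admissible ellipse by the radius.
    ia, ib = a - r - 1.0, b - r - 1.0
    while True:
        t = rng.uniform(0.0, 2.0 * np.pi)
        u = np.sqrt(rng.uniform(0.0, 1.0)) * 0.9
        ty = cy + u * ia * np.sin(t)
        tx = cx + u * ib * np.cos(t)
        # containment check for the farthest point of the disk
        if ((ty - cy) / (a - r)) ** 2 + ((tx - cx) / (b - r)) ** 2 <= 1.0:
            break
    return (cy, cx, a, b), (ty, tx)


def make_region_map(spec: PhantomSpec) -> np.ndarray:
    """Integer region labels: 0 background, 1 brain tissue, 2 tumour."""
    (cy, cx, a, b), (ty, tx) = _geometry(spec)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    tumour = (yy - ty) ** 2 + (xx - tx) ** 2 <= spec.tumour_radius**2
    regions = np.zeros((spec.height, spec.width), dtype=np.int64)
    regions[inside] = 1
    regions[tumour] = 2
    return regions


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the noiseless phantom and its binary tumour mask.

    Returns
    -------
    img : float ndarray (height, width)
        Pixel values equal to ``tissue_means`` on the respective regions.
        Noise / blockiness requested in the spec are applied on top.
    mask : bool ndarray
        True exactly on tumour pixels.
    """
    regions = make_region_map(spec)
    means = np.asarray(spec.tissue_means, dtype=float)
    img = means[regions]
    mask = regions == 2
    if spec.noise_sigma > 0:
        img = add_noise(img, spec.noise_sigma, seed=spec.seed + 1)
    if spec.block_quality is not None:
        img = add_blockiness(img, quality=spec.block_quality)
    return img, mask


def add_noise(img: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add zero-mean Gaussian noise of standard deviation ``sigma``.

    Output is clipped to [0, 255]; ``sigma=0`` returns an exact copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    img = np.asarray(img, dtype=float)
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    return np.clip(img + rng.normal(0.0, sigma, size=img.shape), 0.0, 255.0)


def _quant_table(block: int, quality: int) -> np.ndarray:
    """IJG-style quality scaling of the baseline luminance table."""
    if quality < 50:
        scale = 5000.0 / quality
    else:
        scale = 200.0 - 2.0 * quality
    base = _JPEG_LUMA_Q50
    if block != 8:
        # resample the 8x8 table to the requested block size
        idx = (np.arange(block) * 8 // block).clip(0, 7)
        base = base[np.ix_(idx, idx)]
    q = np.floor((base * scale + 50.0) / 100.0)
    return np.maximum(q, 1.0)


def add_blockiness(img: np.ndarray, block: int = 8, quality: int = 50) -> np.ndarray:
    """Simulate lossy block-transform compression artifacts.

    Each ``block`` x ``block`` tile is level-shifted by its own mean,
    DCT-transformed, quantized with a quality-scaled luminance table and
    inverted, producing the familiar intensity steps at tile boundaries.
    The per-block mean shift makes constant images exactly representable
    at every quality; ``quality=100`` is the identity.
    """
    if block < 2:
        raise ValueError("block size must be at least 2")
    if not 1 <= quality <= 100:
        raise ValueError("quality must be in 1..100")
    img = np.asarray(img, dtype=float)
    if quality == 100:
        return img.copy()
    h, w = img.shape
    ph = (-h) % block
    pw = (-w) % block
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    q = _quant_table(block, quality)
    out = np.empty_like(padded)
    for i in range(0, padded.shape[0], block):
        for j in range(0, padded.shape[1], block):
            tile = padded[i : i + block, j : j + block]
            mean = tile.mean()
            coef = dctn(tile - mean, norm="ortho")
            coef = np.round(coef / q) * q
            out[i : i + block, j : j + block] = idctn(coef, norm="ortho") + mean
    return np.clip(out[:h, :w], 0.0, 255.0)
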