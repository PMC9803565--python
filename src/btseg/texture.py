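"""Gray-level co-occurrence matrices and four Haralick-style features.

A GLCM at offset (dr, dc) counts ordered pairs of quantized gray levels
(p[r, c], p[r+dr, c+dc]) over all valid positions and normalizes to a
probability matrix P.  From P we derive:

    contrast    = sum (i-j)^2 P_ij
    correlation = (sum ij P_ij - mu_x mu_y) / (sigma_x sigma_y)
    energy      = sum P_ij^2
    homogeneity = sum P_ij / (1 + (i-j)^2)

with mu/sigma from the marginal distributions of P.  Matrices are
directed (not symmetrized) by default: the signed offsets (0,1),
(-1,1), (-1,0), (-1,-1) are the standard 0/45/90/135-degree probes
with dr < 0 pointing up the image.  Correlation is NaN when either
marginal has zero variance (single gray level along that axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_OFFSETS",
    "quantize",
    "glcm",
    "glcm_features",
    "extract_feature_table",
]

# (angle in degrees, (dr, dc)) — the canonical four directions
TABLE_OFFSETS: tuple[tuple[int, tuple[int, int]], ...] = (
    (0, (0, 1)),
    (45, (-1, 1)),
    (90, (-1, 0)),
    (135, (-1, -1)),
)


def quantize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Uniformly bin 8-bit intensities into ``levels`` gray levels.

    bin = floor(v * levels / 256); ``levels=256`` is the identity on
    integer 8-bit input.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    img = np.asarray(img)
    v = np.clip(img, 0, 255)
    return np.minimum((v.astype(np.int64) * levels) // 256, levels - 1)


def glcm(
    img: np.ndarray,
    offset: tuple[int, int],
    levels: int,
    symmetric: bool = False,
    normed: bool = True,
) -> np.ndarray:
    """Co-occurrence matrix of a quantized image at one signed offset."""
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    img = np.asarray(img, dtype=np.int64)
    h, w = img.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError("image smaller than the offset span")
    src_r = slice(max(0, -dr), h - max(0, dr))
    dst_r = slice(max(0, dr), h + min(0, dr))
    src_c = slice(max(0, -dc), w - max(0, dc))
    dst_c = slice(max(0, dc), w + min(0, dc))
    i = img[src_r, src_c].ravel()
    j = img[dst_r, dst_c].ravel()
    counts = np.bincount(i * levels + j, minlength=levels * levels)
    P = counts.reshape(levels, levels).astype(float)
    if symmetric:
        P = P + P.T
    if normed:
        P /= P.sum()
    return P


def glcm_features(P: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM.

    Correlation is NaN when a marginal standard deviation is zero.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    idx = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diff2 = (ii - jj) ** 2
    contrast = float(np.sum(diff2 * P))
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + diff2)))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    var_x = float(((idx - mu_x) ** 2) @ px)
    var_y = float(((idx - mu_y) ** 2) @ py)
    if var_x <= 0 or var_y <= 0:
        correlation = float("nan")
    else:
        correlation = float(
            (np.sum(ii * jj * P) - mu_x * mu_y) / np.sqrt(var_x * var_y)
        )
    return contrast, correlation, energy, homogeneity


def extract_feature_table(
    img: np.ndarray,
    level_counts: tuple[int, ...] = (128, 256),
    symmetric: bool = False,
) -> pd.DataFrame:
    """Feature table over {128, 256} gray levels x four directions.

    One row per (levels, angle) pair — eight rows by default — with
    columns levels, angle, offset_r, offset_c, contrast, correlation,
    energy, homogeneity.
    """
    rows = []
    for levels in level_counts:
        q = quantize(img, levels)
        for angle, (dr, dc) in TABLE_OFFSETS:
            P = glcm(q, (dr, dc), levels, symmetric=symmetric)
            contrast, corr, energy, homog = glcm_features(P)
            rows.append(
                {
                    "levels": levels,
                    "angle": angle,
                    "offset_r": dr,
                    "offset_c": dc,
                    "contrast": contrast,
                    "correlation": corr,
                    "energy": energy,
                    "homogeneity": homog,
                }
            )
    return pd.DataFrame(rows)
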