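"""Windowed gray-level co-occurrence (GLCM) texture features.

Implements co-occurrence counting and the three Haralick features used
for pixel classification — angular second moment (ASM), contrast and
correlation — over a fixed-size window centred at each pixel of a T1ce
slice, averaged over the four unit-distance directions.

Conventions
-----------
* Distance d = 1; angles 0, 45, 90, 135 degrees map to pixel offsets
  (dy, dx) = (0, 1), (-1, 1), (-1, 0), (-1, -1) in row/col coordinates.
* GLCMs are symmetric by default (each pair counted in both orders).
* An even window of side ``w`` centred at pixel (y, x) covers rows
  ``y - w/2 .. y + w/2 - 1`` (and likewise columns), clipped at the
  image border rather than padded.
* Degenerate rules: a zero-total GLCM yields (0, 0, 0); correlation with
  a zero marginal standard deviation is defined as 0.

:func:`texture_feature_maps` computes the same quantities for every ROI
pixel at once using per-pair-code integral images; equality with the
per-pixel path is covered by tests.

Examples
--------
>>> import numpy as np
>>> from segfuse.texture import compute_glcm, haralick_features
>>> checker = np.indices((4, 4)).sum(axis=0) % 2
>>> feats = haralick_features(compute_glcm(checker, (0, 1), levels=2))
>>> (feats.asm, feats.contrast, feats.correlation)
(0.5, 1.0, -1.0)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MaskingError, QuantizationError

#: angle (degrees) -> offset (dy, dx) at distance 1.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_LEVELS = 8
DEFAULT_WINDOW = 8


@dataclass
class GLCMatrix:
    """Co-occurrence counts for one offset."""

    counts: np.ndarray  # (levels, levels) nonnegative integers
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def normalized(self) -> np.ndarray:
        """Joint probability p(i, j); all-zero for an empty matrix."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts.astype(np.float64) / total


@dataclass
class HaralickFeatures:
    """The (ASM, contrast, correlation) triple of one GLCM."""

    asm: float
    contrast: float
    correlation: float

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.contrast, self.correlation])


def quantize_gray_levels(
    raster: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear equal-width binning into integers 0..levels-1.

    Bins are half-open ``[min + k*w, min + (k+1)*w)``; values at or below
    ``min`` map to 0, values at or above ``max`` map to ``levels - 1``.
    A constant raster (``max == min`` when the range is inferred) maps to
    all zeros.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if value_range is None:
        lo, hi = (raster.min(), raster.max()) if raster.size else (0.0, 1.0)
        if hi <= lo:
            return np.zeros(raster.shape, dtype=np.int64)
    else:
        lo, hi = value_range
        if hi <= lo:
            raise QuantizationError(f"invalid quantization range ({lo}, {hi})")
    width = (hi - lo) / levels
    q = np.floor((raster - lo) / width).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    q_raster: np.ndarray,
    offset: tuple[int, int],
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = True,
) -> GLCMatrix:
    """Count in-bounds pixel pairs (p, p + offset) with values (i, j).

    With ``symmetric=True`` the transpose is added, so each pair is
    counted once in each order (standard Haralick convention).
    """
    q = np.asarray(q_raster)
    if q.size and (q.min() < 0 or q.max() >= levels):
        raise QuantizationError(f"quantized values outside 0..{levels - 1}")
    dy, dx = offset
    h, w = q.shape if q.ndim == 2 else (0, 0)
    counts = np.zeros((levels, levels), dtype=np.int64)
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    if y1 > y0 and x1 > x0:
        i = q[y0:y1, x0:x1].ravel()
        j = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
        np.add.at(counts, (i, j), 1)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts=counts, levels=levels, offset=(dy, dx), symmetric=symmetric)


def haralick_features(glcm: GLCMatrix) -> HaralickFeatures:
    """ASM, contrast and correlation of a (possibly empty) GLCM.

    On the normalized joint distribution p(i, j):

    * ASM         = sum_ij p(i,j)^2
    * contrast    = sum_ij (i - j)^2 p(i,j)
    * correlation = sum_ij (i - mu_i)(j - mu_j) p(i,j) / (sigma_i sigma_j)

    with mu/sigma the marginal means and standard deviations.
    """
    p = glcm.normalized()
    if p.sum() == 0:
        return HaralickFeatures(0.0, 0.0, 0.0)
    idx = np.arange(glcm.levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((idx * p_i).sum())
    mu_j = float((idx * p_j).sum())
    var_i = float(((idx - mu_i) ** 2 * p_i).sum())
    var_j = float(((idx - mu_j) ** 2 * p_j).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        cov = float(((ii - mu_i) * (jj - mu_j) * p).sum())
        corr = cov / np.sqrt(var_i * var_j)
    return HaralickFeatures(asm, contrast, corr)


def _window_bounds(y: int, x: int, h: int, w: int, window: int):
    half = window // 2
    return (
        max(0, y - half),
        min(h, y + window - half),
        max(0, x - half),
        min(w, x + window - half),
    )


def window_features(
    raster: np.ndarray,
    pixel: tuple[int, int],
    window: int = DEFAULT_WINDOW,
    levels: int = DEFAULT_LEVELS,
    value_range: tuple[float, float] | None = None,
    symmetric: bool = True,
    prequantized: bool = False,
) -> HaralickFeatures:
    """Angle-averaged Haralick triple for the window centred at ``pixel``.

    The window is clipped at image borders. The quantization range is
    per-image (not per-window) so windows of one slice share gray bins.
    """
    raster = np.asarray(raster)
    h, w = raster.shape
    y, x = pixel
    if not (0 <= y < h and 0 <= x < w):
        raise IndexError(f"pixel {pixel} outside raster of shape {raster.shape}")
    q = raster if prequantized else quantize_gray_levels(raster, levels, value_range)
    y0, y1, x0, x1 = _window_bounds(y, x, h, w, window)
    sub = q[y0:y1, x0:x1]
    triples = [
        haralick_features(compute_glcm(sub, off, levels, symmetric)).as_array()
        for off in ANGLE_OFFSETS.values()
    ]
    mean = np.mean(triples, axis=0)
    return HaralickFeatures(*mean.tolist())


def _windowed_pair_counts(code_hist, y, x, dy, dx, h, w, window):
    """Rectangle sums of per-pair-code indicator maps over clipped windows.

    ``code_hist`` is a padded integral image stack of shape
    (levels^2, h+1, w+1) over anchor positions. For the window of pixel
    (y, x), a pair anchored at (r, c) lies fully inside iff both (r, c)
    and (r+dy, c+dx) are inside, which shrinks the anchor rectangle by
    the offset on the appropriate side.
    """
    half = window // 2
    r0 = np.clip(y - half, 0, h)
    r1 = np.clip(y + window - half, 0, h)
    c0 = np.clip(x - half, 0, w)
    c1 = np.clip(x + window - half, 0, w)
    ar0 = r0 + max(0, -dy)
    ar1 = r1 - max(0, dy)
    ac0 = c0 + max(0, -dx)
    ac1 = c1 - max(0, dx)
    ar1 = np.maximum(ar1, ar0)
    ac1 = np.maximum(ac1, ac0)
    return (
        code_hist[:, ar1, ac1]
        - code_hist[:, ar0, ac1]
        - code_hist[:, ar1, ac0]
        + code_hist[:, ar0, ac0]
    )


def _features_from_counts(counts: np.ndarray, levels: int) -> np.ndarray:
    """Vectorized Haralick triple from symmetric counts (L*L, N) -> (3, N)."""
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    ii = ii.ravel()[:, None]
    jj = jj.ravel()[:, None]
    total = counts.sum(axis=0)
    safe = np.where(total > 0, total, 1).astype(np.float64)
    p = counts / safe
    asm = (p**2).sum(axis=0)
    contrast = ((ii - jj) ** 2 * p).sum(axis=0)
    mu_i = (ii * p).sum(axis=0)
    mu_j = (jj * p).sum(axis=0)
    var_i = ((ii - mu_i) ** 2 * p).sum(axis=0)
    var_j = ((jj - mu_j) ** 2 * p).sum(axis=0)
    cov = ((ii - mu_i) * (jj - mu_j) * p).sum(axis=0)
    denom = np.sqrt(var_i * var_j)
    corr = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    empty = total == 0
    out = np.stack([asm, contrast, corr])
    out[:, empty] = 0.0
    return out


def texture_feature_maps(
    t1ce_raster: np.ndarray,
    roi_mask: np.ndarray,
    window: int = DEFAULT_WINDOW,
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = True,
) -> np.ndarray:
    """Per-pixel (ASM, contrast, correlation) maps over the ROI.

    Returns a (3, H, W) array, zero outside the ROI. The quantization
    range is the in-ROI min/max of the slice. Equivalent to calling
    :func:`window_features` at every ROI pixel, but computed with
    integral images over pair-code indicators.
    """
    t1ce = np.asarray(t1ce_raster, dtype=np.float64)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != t1ce.shape:
        raise MaskingError(
            f"ROI shape {roi.shape} does not match raster shape {t1ce.shape}"
        )
    h, w = t1ce.shape
    out = np.zeros((3, h, w), dtype=np.float64)
    if not roi.any():
        return out
    lo, hi = t1ce[roi].min(), t1ce[roi].max()
    value_range = (float(lo), float(hi)) if hi > lo else None
    q = quantize_gray_levels(t1ce, levels, value_range)
    ys, xs = np.nonzero(roi)

    acc = np.zeros((3, ys.size), dtype=np.float64)
    for dy, dx in ANGLE_OFFSETS.values():
        # Pair-code map over valid anchors, then padded integral images.
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        codes = np.full((h, w), -1, dtype=np.int64)
        codes[y0:y1, x0:x1] = (
            q[y0:y1, x0:x1] * levels + q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        )
        n_codes = levels * levels
        onehot = np.zeros((n_codes, h, w), dtype=np.int64)
        vy, vx = np.nonzero(codes >= 0)
        onehot[codes[vy, vx], vy, vx] = 1
        integral = np.zeros((n_codes, h + 1, w + 1), dtype=np.int64)
        integral[:, 1:, 1:] = onehot.cumsum(axis=1).cumsum(axis=2)

        counts = _windowed_pair_counts(integral, ys, xs, dy, dx, h, w, window)
        if symmetric:
            counts = counts + counts.reshape(levels, levels, -1).transpose(
                1, 0, 2
            ).reshape(n_codes, -1)
        acc += _features_from_counts(counts.astype(np.float64), levels)
    acc /= len(ANGLE_OFFSETS)
    out[:, ys, xs] = acc
    return out
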