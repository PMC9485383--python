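"""Intensity normalization, cropping and label-space conversion.

Normalization is applied per volume and per modality, over in-brain
voxels only: percentile clipping first, then z-scoring. Background
(outside the brain mask) is left untouched and stays exactly zero.

Label spaces
------------
``brats``
    {0, 1, 2, 4}: background, necrotic/non-enhancing, edema, enhancing.
``binary``
    {0, 1}: background vs any tumor tissue.
``class_index``
    {0, 1, 2, 3}: background, edema, necrosis/non-enhancing, enhancing —
    a contiguous index space for classifiers and score maps.
"""

from __future__ import annotations

import numpy as np

from .exceptions import LabelError, PreprocessingError

BRATS_LABELS = (0, 1, 2, 4)

#: brats label -> class index (background, edema, necrosis, enhancing).
_BRATS_TO_CLASS = {0: 0, 2: 1, 1: 2, 4: 3}
_CLASS_TO_BRATS = {v: k for k, v in _BRATS_TO_CLASS.items()}

CLASS_NAMES = ("background", "edema", "necrosis", "enhancing")


def _check_brats(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), BRATS_LABELS)
    if bad.size:
        raise LabelError(f"labels outside BRATS space {BRATS_LABELS}: {bad.tolist()}")
    return labels.astype(np.int64)


def clip_percentiles(
    raster: np.ndarray,
    brain_mask: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 1.0,
) -> np.ndarray:
    """Clip in-brain intensities to [p_low, p_(100-high)] of in-brain values."""
    raster = np.asarray(raster, dtype=np.float64)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise PreprocessingError("empty brain mask")
    vals = raster[brain_mask]
    lo, hi = np.percentile(vals, [low_pct, 100.0 - high_pct])
    out = raster.copy()
    out[brain_mask] = np.clip(vals, lo, hi)
    return out


def zscore_normalize(raster: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-std transform of in-brain intensities; background stays 0."""
    raster = np.asarray(raster, dtype=np.float64)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise PreprocessingError("empty brain mask")
    vals = raster[brain_mask]
    sd = vals.std()
    if sd == 0:
        raise PreprocessingError("zero in-brain standard deviation")
    out = np.zeros_like(raster)
    out[brain_mask] = (vals - vals.mean()) / sd
    return out


def crop_center(
    raster: np.ndarray, target: tuple[int, int] = (192, 192)
) -> tuple[np.ndarray, tuple[int, int]]:
    """Center-crop the trailing two axes to ``target``.

    Returns the cropped raster and the (row, col) offsets so that
    predictions can be mapped back into the original frame. No padding:
    inputs smaller than the target are an error.
    """
    raster = np.asarray(raster)
    h, w = raster.shape[-2:]
    th, tw = target
    if h < th or w < tw:
        raise PreprocessingError(
            f"input in-plane size {h}x{w} smaller than target {th}x{tw}"
        )
    oy = (h - th) // 2
    ox = (w - tw) // 2
    return raster[..., oy : oy + th, ox : ox + tw], (oy, ox)


def to_binary_labels(labels: np.ndarray) -> np.ndarray:
    """BRATS labels -> {0, 1}: any tumor tissue maps to 1."""
    labels = _check_brats(labels)
    return (labels != 0).astype(np.int64)


def to_class_index(labels: np.ndarray) -> np.ndarray:
    """BRATS labels -> contiguous class indices 0..3.

    0->0 (background), 2->1 (edema), 1->2 (necrosis/non-enhancing),
    4->3 (enhancing).
    """
    labels = _check_brats(labels)
    lut = np.zeros(5, dtype=np.int64)
    for b, c in _BRATS_TO_CLASS.items():
        lut[b] = c
    return lut[labels]


def from_class_index(classes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_class_index`."""
    classes = np.asarray(classes)
    bad = np.setdiff1d(np.unique(classes), list(_CLASS_TO_BRATS))
    if bad.size:
        raise LabelError(f"class indices outside 0..3: {bad.tolist()}")
    lut = np.zeros(4, dtype=np.int64)
    for c, b in _CLASS_TO_BRATS.items():
        lut[c] = b
    return lut[classes.astype(np.int64)]
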