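"""Whole-tumor ROI generation from the best single modality.

Four binary segmentation models are trained, one per modality, under an
identical configuration; the modality whose model scores the highest
mean whole-tumor F-measure on an evaluation split is selected, and its
predicted mask gates a combined [FLAIR, T1ce, T2] image: outside-mask
pixels are zeroed, inside-mask pixels pass through untouched. T1 takes
part in model selection only and never appears in the ROI image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import f_measure
from .exceptions import MaskingError, SelectionError
from .formats_io import MODALITIES, ModalityStack
from .net_stage import (
    NetConfig,
    SegmentationNet,
    build_network,
    extract_score_maps,
    predict_argmax,
    train_segmentation,
)

#: Channels of an ROI image, in fixed order.
ROI_CHANNELS = ("FLAIR", "T1ce", "T2")


@dataclass
class ROIImage:
    """Masked combined-modality image: zero wherever the mask is false."""

    channels: np.ndarray  # (3, H, W) in ROI_CHANNELS order
    mask: np.ndarray  # boolean (H, W)


def train_modality_models(
    stacks: list[ModalityStack],
    binary_labels: list[np.ndarray],
    net_config: NetConfig,
) -> dict[str, tuple[SegmentationNet, list[float]]]:
    """Train one single-channel binary model per modality (same config/seed).

    Returns modality -> (model, loss trace).
    """
    out = {}
    cfg = replace(net_config, in_channels=1, n_classes=2)
    labels = np.stack(binary_labels)
    for c, mod in enumerate(MODALITIES):
        images = np.stack([s.data[c : c + 1] for s in stacks])
        model = build_network(cfg)
        trace = train_segmentation(model, images, labels)
        out[mod] = (model, trace)
    return out


def predict_roi_mask(model: SegmentationNet, modality_raster: np.ndarray) -> np.ndarray:
    """Boolean whole-tumor mask: argmax class 1 of the binary score maps."""
    raster = np.asarray(modality_raster, dtype=np.float64)
    scores = extract_score_maps(model, raster[None])
    return predict_argmax(scores).astype(bool)


def select_best_modality(
    models: dict[str, SegmentationNet],
    eval_stacks: list[ModalityStack],
    eval_binary_labels: list[np.ndarray],
) -> tuple[str, dict[str, float]]:
    """Pick the modality with the highest mean whole-tumor F-measure.

    Ties break by canonical modality order. The full score table is
    returned alongside the winner.
    """
    if not eval_stacks:
        raise SelectionError("empty evaluation split for modality selection")
    table = {}
    for mod in MODALITIES:
        if mod not in models:
            continue
        scores = []
        for stack, lab in zip(eval_stacks, eval_binary_labels):
            mask = predict_roi_mask(models[mod], stack.channel(mod))
            scores.append(f_measure(mask, lab.astype(bool)))
        table[mod] = float(np.mean(scores))
    if not table:
        raise SelectionError("no trained models supplied")
    best = max(
        table, key=lambda m: (table[m], -MODALITIES.index(m))
    )
    return best, table


def apply_roi_mask(stack: ModalityStack, mask: np.ndarray) -> ROIImage:
    """Mask the combined [FLAIR, T1ce, T2] channels with the ROI."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.data.shape[1:]:
        raise MaskingError(
            f"mask shape {mask.shape} does not match stack shape {stack.data.shape[1:]}"
        )
    channels = np.stack([stack.channel(m) for m in ROI_CHANNELS])
    channels = np.where(mask[None], channels, 0.0)
    return ROIImage(channels=channels, mask=mask)
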