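"""Synthetic multi-modal phantom subjects with BRATS-style labels.

Each phantom is a 2D slice (the pipeline's processing unit): an
elliptical "brain" containing a nested lesion — an edema ring (label 2)
around a core made of a necrotic interior (label 1) and an enhancing rim
(label 4). Modalities are rendered from a per-(modality, region) contrast
table, textured with region-specific stationary noise so co-occurrence
statistics discriminate the subregions, and optionally modulated by a
smooth multiplicative bias field.

Blob boundaries use a low-order radial Fourier perturbation of an
ellipse, giving irregular but controllable shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import formats_io
from .exceptions import ConfigError
from .formats_io import MODALITIES, ModalityStack, SubjectRecord

REGIONS = ("brain", "edema", "necrosis", "enhancing")

# Mean intensity (in [0,1]) per (modality, region); background is 0.
# Edema/whole tumor hyperintense on FLAIR and T2, enhancing rim
# hyperintense and necrosis hypointense on T1ce, weak contrast on T1.
DEFAULT_CONTRAST = {
    ("FLAIR", "brain"): 0.35,
    ("FLAIR", "edema"): 0.85,
    ("FLAIR", "necrosis"): 0.60,
    ("FLAIR", "enhancing"): 0.60,
    ("T1", "brain"): 0.50,
    ("T1", "edema"): 0.45,
    ("T1", "necrosis"): 0.42,
    ("T1", "enhancing"): 0.55,
    ("T1ce", "brain"): 0.45,
    ("T1ce", "edema"): 0.50,
    ("T1ce", "necrosis"): 0.20,
    ("T1ce", "enhancing"): 0.90,
    ("T2", "brain"): 0.42,
    ("T2", "edema"): 0.56,
    ("T2", "necrosis"): 0.50,
    ("T2", "enhancing"): 0.48,
}

# region -> (noise_sd, smoothing_sigma in px). Distinct pairs per region
# give distinct expected co-occurrence statistics.
DEFAULT_TEXTURE = {
    "brain": (0.02, 1.0),
    "edema": (0.05, 0.5),
    "necrosis": (0.10, 0.0),
    "enhancing": (0.03, 1.0),
}


@dataclass
class PhantomConfig:
    """Cohort-level generation parameters.

    Area fractions are all relative to the brain area and must satisfy
    0 < enhancing < core < tumor <= 1 (ranges compared bound-wise).
    """

    image_size: tuple[int, int] = (192, 192)
    n_subjects: int = 8
    seed: int = 0
    brain_axes: tuple[tuple[float, float], tuple[float, float]] = ((55.0, 70.0), (65.0, 85.0))
    tumor_frac: tuple[float, float] = (0.10, 0.18)
    core_frac: tuple[float, float] = (0.050, 0.085)
    enhancing_frac: tuple[float, float] = (0.020, 0.034)
    contrast_table: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    texture_table: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE))
    global_noise_sd: float = 0.01
    bias_field: float = 0.0  # multiplicative amplitude; 0 disables
    train_fraction: float = 0.75

    def __post_init__(self):
        for name, rng_ in (
            ("tumor_frac", self.tumor_frac),
            ("core_frac", self.core_frac),
            ("enhancing_frac", self.enhancing_frac),
        ):
            if not (0 <= rng_[0] <= rng_[1]):
                raise ConfigError(f"{name} range must be ordered and nonnegative")
        if not (
            self.enhancing_frac[1] < self.core_frac[0]
            and self.core_frac[1] < self.tumor_frac[0]
            and self.tumor_frac[1] <= 1.0
        ):
            raise ConfigError(
                "nesting fractions must satisfy enhancing < core < tumor <= 1"
            )
        for (mod, region), v in self.contrast_table.items():
            if mod not in MODALITIES or region not in REGIONS:
                raise ConfigError(f"unknown contrast_table key {(mod, region)}")
            if not (0.0 <= v <= 1.0):
                raise ConfigError("contrast intensities must lie in [0, 1]")
        for region, (sd, _sigma) in self.texture_table.items():
            if region not in REGIONS:
                raise ConfigError(f"unknown texture_table region {region}")
            if sd < 0:
                raise ConfigError("noise_sd must be nonnegative")


def texture_dominant_config(**overrides) -> PhantomConfig:
    """Config whose necrosis/enhancing regions differ mainly in texture.

    Contrast for necrosis vs enhancing is near-equal on every modality
    while their (noise_sd, smoothing_sigma) pairs are well separated, so
    intensity alone cannot distinguish the two core subregions but
    co-occurrence statistics can.
    """
    contrast = dict(DEFAULT_CONTRAST)
    contrast.update(
        {
            ("T1ce", "necrosis"): 0.62,
            ("T1ce", "enhancing"): 0.66,
            ("T1", "necrosis"): 0.48,
            ("T1", "enhancing"): 0.50,
            ("T2", "necrosis"): 0.60,
            ("T2", "enhancing"): 0.62,
            ("FLAIR", "necrosis"): 0.60,
            ("FLAIR", "enhancing"): 0.62,
        }
    )
    texture = {
        "brain": (0.02, 1.0),
        "edema": (0.04, 1.0),
        "necrosis": (0.16, 0.0),
        "enhancing": (0.02, 1.5),
    }
    cfg = PhantomConfig(contrast_table=contrast, texture_table=texture)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PhantomSubject:
    stack: ModalityStack
    labels: np.ndarray  # BRATS space {0,1,2,4}
    subject_seed: int


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    area: float,
    axis_ratio: float,
    angle: float,
    fourier: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Perturbed-ellipse mask with approximately the requested area.

    The boundary radius is ``r0 * (1 + sum_k a_k cos(k*phi + phase_k))``
    in an elliptical frame; ``r0`` is corrected once against the measured
    area so configured area fractions are met closely.
    """
    if area < 8:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / axis_ratio
    r = np.hypot(u, v)
    phi = np.arctan2(v, u)
    pert = np.ones_like(phi)
    for k, (a_k, ph_k) in enumerate(zip(fourier, phases), start=2):
        pert += a_k * np.cos(k * phi + ph_k)
    pert = np.maximum(pert, 0.2)
    r0 = math.sqrt(area / (math.pi * axis_ratio))
    mask = r <= r0 * pert
    actual = mask.sum()
    if actual > 0:  # one-step area correction
        r0 *= math.sqrt(area / actual)
        mask = r <= r0 * pert
    return mask


def render_region_texture(
    raster: np.ndarray,
    region_mask: np.ndarray,
    noise_sd: float,
    smoothing_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add smoothed stationary noise of marginal sd ``noise_sd`` inside a region."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ConfigError("region_mask is empty")
    out = np.asarray(raster, dtype=np.float64).copy()
    if noise_sd == 0:
        return out
    noise = rng.normal(0.0, 1.0, raster.shape)
    if smoothing_sigma > 0:
        noise = ndimage.gaussian_filter(noise, smoothing_sigma)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    out[region_mask] += noise_sd * noise[region_mask]
    return out


def generate_subject(config: PhantomConfig, subject_seed: int) -> PhantomSubject:
    """Render one phantom subject, deterministic in (config.seed, subject_seed)."""
    rng = np.random.default_rng([config.seed, subject_seed])
    h, w = config.image_size
    cy, cx = h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4)

    # Brain ellipse.
    ay = rng.uniform(*config.brain_axes[0])
    ax = rng.uniform(*config.brain_axes[1])
    yy, xx = np.mgrid[0:h, 0:w]
    brain = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    brain_area = float(brain.sum())

    # Nested lesion blobs; one shared perturbation keeps shrunken copies nested.
    tumor_area = rng.uniform(*config.tumor_frac) * brain_area
    core_area = rng.uniform(*config.core_frac) * brain_area
    enh_area = rng.uniform(*config.enhancing_frac) * brain_area
    necro_area = max(core_area - enh_area, 0.0)

    t_cy = cy + rng.uniform(-0.35, 0.35) * ay
    t_cx = cx + rng.uniform(-0.35, 0.35) * ax
    fourier = rng.uniform(0.03, 0.12, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    axis_ratio = rng.uniform(0.7, 1.3)
    angle = rng.uniform(0, np.pi)

    inner_brain = ndimage.binary_erosion(brain, iterations=2)
    tumor = _blob_mask((h, w), (t_cy, t_cx), tumor_area, axis_ratio, angle, fourier, phases)
    tumor &= inner_brain
    core = _blob_mask((h, w), (t_cy, t_cx), core_area, axis_ratio, angle, fourier, phases)
    core &= ndimage.binary_erosion(tumor, iterations=1) if tumor.any() else tumor
    necro = _blob_mask((h, w), (t_cy, t_cx), necro_area, axis_ratio, angle, fourier, phases)
    necro &= ndimage.binary_erosion(core, iterations=1) if core.any() else core

    labels = np.zeros((h, w), dtype=np.int64)
    labels[tumor] = 2  # edema ring (overwritten below inside the core)
    labels[core] = 4  # enhancing rim
    labels[necro] = 1  # necrotic interior

    region_masks = {
        "brain": brain & (labels == 0),
        "edema": labels == 2,
        "necrosis": labels == 1,
        "enhancing": labels == 4,
    }

    data = np.zeros((len(MODALITIES), h, w), dtype=np.float64)
    for c, mod in enumerate(MODALITIES):
        img = np.zeros((h, w), dtype=np.float64)
        for region, mask in region_masks.items():
            img[mask] = config.contrast_table[(mod, region)]
        for region, mask in region_masks.items():
            if mask.any():
                sd, sigma = config.texture_table.get(region, (0.0, 0.0))
                img = render_region_texture(img, mask, sd, sigma, rng)
        if config.global_noise_sd > 0:
            img[brain] += rng.normal(0.0, config.global_noise_sd, (h, w))[brain]
        if config.bias_field > 0:
            bias = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 40.0)
            span = np.abs(bias).max()
            if span > 0:
                bias = bias / span
            img[brain] *= 1.0 + config.bias_field * bias[brain]
        # Background must stay exactly 0 (brain-mask convention); in-brain
        # values are kept strictly positive so the mask survives rendering.
        img[brain] = np.clip(img[brain], 1e-4, 1.5)
        data[c] = img

    stack = ModalityStack(data=data, brain_mask=brain)
    return PhantomSubject(stack=stack, labels=labels, subject_seed=subject_seed)


def generate_cohort(config: PhantomConfig, out_dir) -> list[SubjectRecord]:
    """Write ``config.n_subjects`` phantoms and a manifest with a seeded split.

    The train/test split takes ``ceil(train_fraction * n)`` subjects for
    training (the round-up rule BRATS-style stratified counts follow).
    """
    from .pipeline import split_cohort  # local import: avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(config.n_subjects):
        subject = generate_subject(config, i)
        sid = f"phantom_{i:03d}"
        sdir = out_dir / sid
        modality_paths = {}
        for c, mod in enumerate(MODALITIES):
            rel = f"{sid}/{mod.lower()}.nii"
            formats_io.write_volume(subject.stack.data[c], out_dir / rel)
            modality_paths[mod] = rel
        label_rel = f"{sid}/labels.nii"
        formats_io.write_volume(subject.labels, out_dir / label_rel)
        records.append(
            SubjectRecord(
                subject_id=sid,
                grade="synthetic",
                modality_paths=modality_paths,
                label_path=label_rel,
            )
        )
    if records:
        train, test = split_cohort(records, config.train_fraction, config.seed)
        split = {
            "train": [r.subject_id for r in train],
            "test": [r.subject_id for r in test],
            "seed": config.seed,
        }
    else:
        split = {"train": [], "test": [], "seed": config.seed}
    formats_io.write_manifest(records, out_dir / "manifest.json", extra={"split": split})
    return records
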