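"""Reading and writing volumes, slices, masks and subject manifests.

The on-disk cohort layout is one directory per subject containing one
NIfTI (or PNG stack) per modality plus an optional label volume, tied
together by a JSON manifest listing :class:`SubjectRecord` entries.

Canonical modality order is ``("FLAIR", "T1", "T1ce", "T2")`` everywhere;
downstream stages select channels by name, never by ad-hoc index.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .exceptions import CohortError, FormatError

#: Canonical modality order. Channel c of every stack corresponds to
#: MODALITIES[c].
MODALITIES = ("FLAIR", "T1", "T1ce", "T2")

GRADES = ("HGG", "LGG", "synthetic")


@dataclass
class SubjectRecord:
    """Paths and metadata for a single subject."""

    subject_id: str
    grade: str
    modality_paths: dict  # modality name -> path (str)
    label_path: Optional[str] = None

    def __post_init__(self):
        if self.grade not in GRADES:
            raise CohortError(
                f"subject {self.subject_id}: unknown grade {self.grade!r}"
            )
        unknown = set(self.modality_paths) - set(MODALITIES)
        if unknown:
            raise CohortError(
                f"subject {self.subject_id}: unknown modality keys {sorted(unknown)}"
            )


@dataclass
class ModalityStack:
    """Co-registered modality rasters plus a brain mask.

    ``data`` has shape (4, H, W) for a 2D slice or (4, D, H, W) for a
    volume, channels in canonical :data:`MODALITIES` order.
    """

    data: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        if self.data.shape[0] != len(MODALITIES):
            raise CohortError(
                f"stack must have {len(MODALITIES)} channels, got {self.data.shape[0]}"
            )
        if self.brain_mask.shape != self.data.shape[1:]:
            raise CohortError("brain_mask shape does not match modality shape")

    def channel(self, modality: str) -> np.ndarray:
        """Return the raster for ``modality`` (by name)."""
        return self.data[MODALITIES.index(modality)]


@dataclass
class VolumeMeta:
    """Orientation metadata carried through read/write round trips."""

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def read_volume(path) -> tuple[np.ndarray, VolumeMeta]:
    """Read a NIfTI file or a directory of PNG slices.

    Returns the raster cast to floating point (integer content is
    preserved exactly in the float values) and orientation metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not slices:
            raise FormatError(f"PNG stack directory {path} contains no .png files")
        rasters = [np.asarray(iio.imread(p)) for p in slices]
        shapes = {r.shape for r in rasters}
        if len(shapes) > 1:
            raise FormatError(
                f"inconsistent slice shapes in PNG stack {path}: {sorted(shapes)}"
            )
        if rasters[0].ndim != 2:
            raise FormatError(f"PNG slices in {path} are not grayscale 2D")
        data = np.stack(rasters).astype(np.float64)
        return data, VolumeMeta()
    if path.suffix.lower() == ".png":
        return np.asarray(iio.imread(path)).astype(np.float64), VolumeMeta()
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.float64)
        return data, VolumeMeta(affine=np.asarray(img.affine))
    raise FormatError(f"unsupported volume format: {path}")


def write_volume(raster: np.ndarray, path, meta: Optional[VolumeMeta] = None) -> None:
    """Write ``raster`` to ``path`` (NIfTI or PNG by extension).

    Integer rasters round-trip exactly; real rasters within single
    precision. Parent directories are created as needed.
    """
    raster = np.asarray(raster)
    if not np.all(np.isfinite(raster)):
        raise FormatError(f"refusing to write non-finite raster to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = meta or VolumeMeta()
    if path.suffix.lower() == ".png":
        if raster.ndim != 2:
            raise FormatError("PNG output requires a 2D raster")
        arr = raster
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.rint(arr)
        if arr.min() < 0 or arr.max() > 65535:
            raise FormatError("PNG output requires values in [0, 65535]")
        dtype = np.uint8 if arr.max() <= 255 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
        return
    if path.name.endswith((".nii", ".nii.gz")):
        if np.issubdtype(raster.dtype, np.integer) or np.issubdtype(
            raster.dtype, np.bool_
        ):
            out = raster.astype(np.int16)
        else:
            out = raster.astype(np.float32)
        nib.save(nib.Nifti1Image(out, meta.affine), str(path))
        return
    raise FormatError(f"unsupported volume format: {path}")


def load_subject(
    record: SubjectRecord, base_dir=None
) -> tuple[ModalityStack, Optional[np.ndarray]]:
    """Load a subject's modalities (canonical order) and optional labels.

    The brain mask defaults to the union of nonzero voxels across
    modalities (BRATS volumes are skull-stripped with zero background).
    """
    base = Path(base_dir) if base_dir is not None else None

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() or base is None else base / p

    rasters = []
    for mod in MODALITIES:
        if mod not in record.modality_paths:
            raise CohortError(f"subject {record.subject_id}: missing modality {mod}")
        raster, _ = read_volume(_resolve(record.modality_paths[mod]))
        rasters.append(raster)
    shapes = {r.shape for r in rasters}
    if len(shapes) > 1:
        raise CohortError(
            f"subject {record.subject_id}: modality shape mismatch {sorted(shapes)}"
        )
    data = np.stack(rasters)
    brain_mask = np.any(data != 0, axis=0)
    labels = None
    if record.label_path is not None:
        lab, _ = read_volume(_resolve(record.label_path))
        if lab.shape != data.shape[1:]:
            raise CohortError(
                f"subject {record.subject_id}: label shape {lab.shape} does not "
                f"match modality shape {data.shape[1:]}"
            )
        labels = np.rint(lab).astype(np.int64)
    return ModalityStack(data=data, brain_mask=brain_mask), labels


def _record_to_dict(record: SubjectRecord, base: Optional[Path]) -> dict:
    def _rel(p):
        if p is None:
            return None
        p = Path(p)
        if base is not None and p.is_absolute():
            try:
                return os.path.relpath(p, base)
            except ValueError:
                return str(p)
        return str(p)

    return {
        "subject_id": record.subject_id,
        "grade": record.grade,
        "modality_paths": {m: _rel(p) for m, p in record.modality_paths.items()},
        "label_path": _rel(record.label_path),
    }


def write_manifest(records: list[SubjectRecord], path, extra: Optional[dict] = None):
    """Write a JSON manifest. Paths are stored relative to the manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent.resolve()
    doc = {"subjects": [_record_to_dict(r, base) for r in records]}
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> list[SubjectRecord]:
    """Read a manifest written by :func:`write_manifest`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed manifest {path}: {exc}") from exc
    if "subjects" not in doc or not isinstance(doc["subjects"], list):
        raise FormatError(f"malformed manifest {path}: missing 'subjects' list")
    records = []
    for i, entry in enumerate(doc["subjects"]):
        try:
            records.append(
                SubjectRecord(
                    subject_id=entry["subject_id"],
                    grade=entry["grade"],
                    modality_paths=dict(entry["modality_paths"]),
                    label_path=entry.get("label_path"),
                )
            )
        except (KeyError, TypeError, CohortError) as exc:
            raise FormatError(f"malformed manifest {path}, subject #{i}: {exc}") from exc
    return records


def read_manifest_extras(path) -> dict:
    """Return non-subject keys of a manifest (e.g. the recorded split)."""
    doc = json.loads(Path(path).read_text())
    return {k: v for k, v in doc.items() if k != "subjects"}
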