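"""End-to-end orchestration: preprocess -> ROI -> features -> classify.

One :class:`PipelineConfig` drives the four stages, all seeded, and the
run report collects per-stage timings, the modality-selection table, the
decision-tree depth setting and the paired method comparison
(net-only argmax vs score+texture decision tree) on the held-out test
split. Training and model selection never touch test subjects; the ids
each stage consumed are recorded in an access log the tests audit.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import formats_io, preprocess, texture
from .exceptions import ConfigError
from .formats_io import MODALITIES, ModalityStack, SubjectRecord
from .fusion import (
    DTConfig,
    assemble_features,
    classify_pixels,
    reconstruct_label_map,
    save_tree,
    train_dt,
)
from .evaluation import compare_methods
from .net_stage import (
    NetConfig,
    build_network,
    extract_score_maps,
    predict_argmax,
    train_segmentation,
)
from .phantom import PhantomConfig
from .roi_stage import (
    apply_roi_mask,
    predict_roi_mask,
    select_best_modality,
    train_modality_models,
)


@dataclass
class SplitConfig:
    fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction < 1.0):
            raise ConfigError("train fraction must lie strictly in (0, 1)")


@dataclass
class PreprocessConfig:
    clip_low_pct: float = 1.0
    clip_high_pct: float = 1.0
    target_size: tuple[int, int] = (192, 192)
    keep_empty_roi_slices: bool = True


@dataclass
class ROIConfig:
    source: str = "predicted"  # "predicted" | "oracle"
    modality: Optional[str] = None  # fix a modality to skip selection
    val_fraction: float = 0.25  # carve-out of the train split for selection

    def __post_init__(self):
        if self.source not in ("predicted", "oracle"):
            raise ConfigError("roi.source must be 'predicted' or 'oracle'")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ConfigError(f"unknown roi.modality {self.modality!r}")


@dataclass
class FusionStageConfig:
    dt: DTConfig = field(default_factory=DTConfig)
    max_pixels_per_subject: Optional[int] = None
    sample_seed: int = 0


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    phantom: Optional[PhantomConfig] = None
    manifest: Optional[str] = None
    split: SplitConfig = field(default_factory=SplitConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    binary_net: NetConfig = field(
        default_factory=lambda: NetConfig(in_channels=1, n_classes=2)
    )
    multiclass_net: NetConfig = field(
        default_factory=lambda: NetConfig(
            in_channels=3, n_classes=4, class_weights="inverse"
        )
    )
    texture_levels: int = 8
    texture_window: int = 8
    fusion: FusionStageConfig = field(default_factory=FusionStageConfig)

    def __post_init__(self):
        if self.phantom is None and self.manifest is None:
            raise ConfigError("configure either a phantom cohort or a manifest")


def split_cohort(
    records: list[SubjectRecord],
    fraction: float = 0.75,
    seed: int = 0,
    stratify_by_grade: bool = True,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Grade-stratified train/test split taking ceil(fraction * n) per stratum.

    The round-up rule reproduces the 158/57 train and 52/18 test counts
    of a 210 HGG + 75 LGG cohort at fraction 0.75. Strata with fewer
    than 2 subjects go entirely to the train split (with a warning).
    """
    if not records:
        raise ConfigError("cannot split an empty cohort")
    if not (0.0 < fraction < 1.0):
        raise ConfigError("train fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        strata.setdefault(rec.grade if stratify_by_grade else "all", []).append(rec)
    train, test = [], []
    for grade in sorted(strata):
        group = strata[grade]
        if len(group) < 2:
            warnings.warn(
                f"stratum {grade!r} has fewer than 2 subjects; assigning to train"
            )
            train.extend(group)
            continue
        order = rng.permutation(len(group))
        n_train = min(math.ceil(fraction * len(group)), len(group) - 1)
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


@dataclass
class _Subject:
    record: SubjectRecord
    stack: ModalityStack
    labels: Optional[np.ndarray]
    crop_offsets: tuple[int, int] = (0, 0)


def _preprocess_subject(
    record: SubjectRecord, base_dir, cfg: PreprocessConfig
) -> _Subject:
    stack, labels = formats_io.load_subject(record, base_dir=base_dir)
    data, offsets = preprocess.crop_center(stack.data, cfg.target_size)
    mask, _ = preprocess.crop_center(stack.brain_mask, cfg.target_size)
    if labels is not None:
        labels, _ = preprocess.crop_center(labels, cfg.target_size)
    out = np.empty_like(data, dtype=np.float64)
    for c in range(data.shape[0]):
        clipped = preprocess.clip_percentiles(
            data[c], mask, cfg.clip_low_pct, cfg.clip_high_pct
        )
        out[c] = preprocess.zscore_normalize(clipped, mask)
    return _Subject(
        record=record,
        stack=ModalityStack(data=out, brain_mask=mask),
        labels=labels,
        crop_offsets=offsets,
    )


def run_pipeline(config: PipelineConfig, return_artifacts: bool = False):
    """Execute all stages; returns (and persists) the run report.

    With ``return_artifacts=True``, also returns the in-memory stage
    outputs (preprocessed subjects, ROI masks/images, score maps, texture
    maps, predictions) for structural checks.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "access_log": {}}
    timings = report["stages"]

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            timings[name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return done

    # -- cohort -------------------------------------------------------------
    done = _stage("cohort")
    if config.phantom is not None:
        from .phantom import generate_cohort

        cohort_dir = out_dir / "cohort"
        records = generate_cohort(config.phantom, cohort_dir)
        base_dir = cohort_dir
    else:
        records = formats_io.read_manifest(config.manifest)
        base_dir = Path(config.manifest).parent
    done(n_subjects=len(records))

    # -- split --------------------------------------------------------------
    done = _stage("split")
    train_recs, test_recs = split_cohort(
        records, config.split.fraction, config.split.seed
    )
    train_ids = [r.subject_id for r in train_recs]
    test_ids = [r.subject_id for r in test_recs]
    report["split"] = {"train": train_ids, "test": test_ids}
    done(n_train=len(train_ids), n_test=len(test_ids))

    # -- preprocess ---------------------------------------------------------
    done = _stage("preprocess")
    subjects = {
        r.subject_id: _preprocess_subject(r, base_dir, config.preprocess)
        for r in records
    }
    done()

    def _binary_labels(sid):
        return preprocess.to_binary_labels(subjects[sid].labels)

    # -- ROI stage ----------------------------------------------------------
    done = _stage("roi")
    roi_masks: dict[str, np.ndarray] = {}
    modality_table: dict[str, float] = {}
    if config.roi.source == "oracle":
        best_modality = config.roi.modality or "FLAIR"
        for sid, subj in subjects.items():
            roi_masks[sid] = _binary_labels(sid).astype(bool)
        report["access_log"]["roi_train"] = []
    else:
        n_val = max(1, round(config.roi.val_fraction * len(train_ids)))
        sel_rng = np.random.default_rng(config.split.seed + 1)
        order = sel_rng.permutation(len(train_ids))
        val_ids = [train_ids[i] for i in order[:n_val]]
        fit_ids = [train_ids[i] for i in order[n_val:]] or val_ids
        report["access_log"]["roi_train"] = sorted(fit_ids)
        report["access_log"]["roi_select"] = sorted(val_ids)

        if config.roi.modality is None:
            fit_stacks = [subjects[s].stack for s in fit_ids]
            fit_labels = [_binary_labels(s) for s in fit_ids]
            models = train_modality_models(fit_stacks, fit_labels, config.binary_net)
            best_modality, modality_table = select_best_modality(
                {m: mt[0] for m, mt in models.items()},
                [subjects[s].stack for s in val_ids],
                [_binary_labels(s) for s in val_ids],
            )
            best_model = models[best_modality][0]
        else:
            best_modality = config.roi.modality
            c = MODALITIES.index(best_modality)
            images = np.stack(
                [subjects[s].stack.data[c : c + 1] for s in train_ids]
            )
            labels = np.stack([_binary_labels(s) for s in train_ids])
            best_model = build_network(
                replace(config.binary_net, in_channels=1, n_classes=2)
            )
            train_segmentation(best_model, images, labels)
            report["access_log"]["roi_train"] = sorted(train_ids)
        best_model.save(out_dir / "models" / "roi_model.npz")
        for sid, subj in subjects.items():
            mask = predict_roi_mask(best_model, subj.stack.channel(best_modality))
            roi_masks[sid] = mask & subj.stack.brain_mask
    report["modality_selection"] = {
        "best": best_modality,
        "table": modality_table,
        "source": config.roi.source,
    }
    done(best_modality=best_modality)

    # -- ROI images ---------------------------------------------------------
    roi_images = {
        sid: apply_roi_mask(subj.stack, roi_masks[sid])
        for sid, subj in subjects.items()
    }
    for sid in subjects:
        formats_io.write_volume(
            roi_masks[sid].astype(np.int64), out_dir / "roi_masks" / f"{sid}.nii"
        )

    # -- multiclass network -------------------------------------------------
    done = _stage("multiclass_net")
    mc_cfg = replace(config.multiclass_net, in_channels=3, n_classes=4)
    mc_model = build_network(mc_cfg)
    mc_images = np.stack([roi_images[s].channels for s in train_ids])
    mc_labels = np.stack(
        [preprocess.to_class_index(subjects[s].labels) for s in train_ids]
    )
    mc_trace = train_segmentation(mc_model, mc_images, mc_labels)
    mc_model.save(out_dir / "models" / "multiclass_model.npz")
    report["access_log"]["multiclass_train"] = sorted(train_ids)
    score_maps = {
        sid: extract_score_maps(mc_model, roi_images[sid].channels)
        for sid in subjects
    }
    done(
        n_parameters=mc_model.n_parameters,
        initial_loss=mc_trace[0],
        final_loss=mc_trace[-1],
    )

    # -- texture maps -------------------------------------------------------
    done = _stage("texture")
    texture_maps = {
        sid: texture.texture_feature_maps(
            subj.stack.channel("T1ce"),
            roi_masks[sid],
            window=config.texture_window,
            levels=config.texture_levels,
        )
        for sid, subj in subjects.items()
    }
    for sid in test_ids:
        formats_io.write_volume(
            texture_maps[sid], out_dir / "texture_maps" / f"{sid}.nii"
        )
    done()

    # -- decision tree ------------------------------------------------------
    done = _stage("decision_tree")
    samp = np.random.default_rng(config.fusion.sample_seed)
    feats, labs = [], []
    for sid in train_ids:
        table = assemble_features(
            score_maps[sid],
            texture_maps[sid],
            roi_masks[sid],
            gt_class_index=preprocess.to_class_index(subjects[sid].labels),
            subject_id=sid,
        )
        f, l = table.features, table.labels
        cap = config.fusion.max_pixels_per_subject
        if cap is not None and f.shape[0] > cap:
            keep = samp.choice(f.shape[0], size=cap, replace=False)
            f, l = f[keep], l[keep]
        feats.append(f)
        labs.append(l)
    train_features = np.concatenate(feats) if feats else np.zeros((0, 7))
    train_labels = np.concatenate(labs) if labs else np.zeros(0, dtype=int)
    trained_tree = train_dt(train_features, train_labels, config.fusion.dt)
    save_tree(trained_tree, out_dir / "models" / "decision_tree.json")
    report["access_log"]["dt_train"] = sorted(train_ids)
    done(
        n_train_pixels=int(train_features.shape[0]),
        train_accuracy=trained_tree.train_accuracy,
        d_tree=config.fusion.dt.d_tree,
    )

    # -- prediction + evaluation -------------------------------------------
    done = _stage("predict_evaluate")
    hybrid_preds, net_preds, gts = {}, {}, {}
    for sid in test_ids:
        table = assemble_features(score_maps[sid], texture_maps[sid], roi_masks[sid])
        classes = classify_pixels(trained_tree, table.features)
        hybrid_preds[sid] = reconstruct_label_map(
            classes, roi_masks[sid], roi_masks[sid].shape
        )
        net_preds[sid] = preprocess.from_class_index(predict_argmax(score_maps[sid]))
        gts[sid] = subjects[sid].labels
        formats_io.write_volume(
            hybrid_preds[sid], out_dir / "predictions" / f"{sid}_hybrid.nii"
        )
        formats_io.write_volume(
            net_preds[sid], out_dir / "predictions" / f"{sid}_net_only.nii"
        )
    comparison = compare_methods(net_preds, hybrid_preds, gts)
    report["comparison"] = {
        "mean_difference": comparison["mean_difference"],
        "methods": {
            name: {"mean": m.mean, "std": m.std, "per_subject": m.per_subject}
            for name, m in comparison["methods"].items()
        },
    }
    done()

    report["config_summary"] = {
        "seeds": {
            "split": config.split.seed,
            "binary_net": config.binary_net.seed,
            "multiclass_net": config.multiclass_net.seed,
            "dt": config.fusion.dt.seed,
            "phantom": config.phantom.seed if config.phantom else None,
        },
        "d_tree": config.fusion.dt.d_tree,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if return_artifacts:
        artifacts = {
            "subjects": subjects,
            "roi_masks": roi_masks,
            "roi_images": roi_images,
            "score_maps": score_maps,
            "texture_maps": texture_maps,
            "hybrid_preds": hybrid_preds,
            "net_preds": net_preds,
            "tree": trained_tree,
        }
        return report, artifacts
    return report


def predictions_from_report(out_dir) -> dict[str, dict[str, np.ndarray]]:
    """Reload persisted test predictions, keyed by method then subject."""
    out_dir = Path(out_dir)
    preds: dict[str, dict[str, np.ndarray]] = {"hybrid": {}, "net_only": {}}
    for path in sorted((out_dir / "predictions").glob("*.nii")):
        for method in preds:
            suffix = f"_{method}"
            if path.stem.endswith(suffix):
                raster, _ = formats_io.read_volume(path)
                preds[method][path.stem[: -len(suffix)]] = np.rint(raster).astype(int)
    return preds
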