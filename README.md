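# segfuse

Hybrid brain-tumor segmentation at desk scale: a four-stage pipeline that

1. **preprocesses** multi-modal MRI slices (1% percentile clipping, per-volume
   z-scoring over the brain region, center crop to 192×192),
2. generates a whole-tumor **ROI mask** with the best single-modality binary
   segmentation network and uses it to gate a combined FLAIR/T1ce/T2 image,
3. extracts per-pixel features — the 4 per-class **score maps** of an
   encoder–decoder segmentation network (max-pooling-index unpooling) fused
   with 3 windowed **GLCM texture features** (ASM, contrast, correlation;
   8×8 windows on T1ce, d=1, four directions averaged), and
4. classifies every ROI pixel with a **decision tree** (default depth 100),
   reconstructing BRATS-style label maps ({0,1,2,4}) that are evaluated with
   region-grouped F-measures (WT/TC/ET) against a net-only argmax baseline.

Real cohorts are access-controlled, so the package ships a **phantom
generator**: nested elliptical lesions (edema ⊃ core = necrosis + enhancing
rim) with modality-specific contrast and region-specific stationary texture,
making every stage trainable and testable offline. The network is pure numpy
(hand-written backprop), so everything runs on one CPU with no framework
dependency.

## CLI

```sh
# generate an 8-subject synthetic cohort with manifest + train/test split
segfuse phantom generate --out cohort/ --n-subjects 8 --seed 7

# run the full pipeline from a YAML config
segfuse run --config pipeline.yaml

# per-stage utilities
segfuse texture maps --image t1ce.nii --roi mask.nii --out features.nii
segfuse net train --manifest cohort/manifest.json --classes 2 --modality FLAIR --out roi.npz
segfuse eval run --pred preds/ --gt gt/ --out metrics.json
```

A minimal `pipeline.yaml`:

```yaml
out_dir: out
phantom: {n_subjects: 8, seed: 7}
split: {fraction: 0.75, seed: 7}
binary_net: {in_channels: 1, n_classes: 2, epochs: 25, class_weights: inverse}
multiclass_net: {in_channels: 3, n_classes: 4, epochs: 40, class_weights: inverse}
fusion: {dt: {d_tree: 100}}
```

The run report (`out/report.json`) contains per-stage timings, the
modality-selection F-measure table, the decision-tree settings, and the
paired net-only vs hybrid comparison (mean ± std per region) on the held-out
test split. Intermediates (ROI masks, model checkpoints, texture maps, the
JSON-serialized tree, predictions) are persisted next to it.

## Layout

| module | role |
| --- | --- |
| `segfuse.formats_io` | NIfTI/PNG volumes, subject records, JSON manifests |
| `segfuse.preprocess` | clipping, z-scoring, cropping, label-space maps |
| `segfuse.phantom` | synthetic multi-modal subjects and cohorts |
| `segfuse.net_stage` | numpy encoder–decoder with pooling-index unpooling |
| `segfuse.roi_stage` | per-modality binary models, selection, ROI masking |
| `segfuse.texture` | windowed GLCM engine (ASM, contrast, correlation) |
| `segfuse.fusion` | 7-element feature vectors, decision tree, label maps |
| `segfuse.evaluation` | WT/TC/ET F-measures and method comparison |
| `segfuse.pipeline` | end-to-end orchestration, splits, run report |
| `segfuse.cli` | `segfuse` command group |
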