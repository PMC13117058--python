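# paintseg

Segmentation-driven morphological profiling for Cell Painting microscopy.

High-content screens image cells stained with five fluorescent dyes (DNA,
ER, RNA/nucleoli, actin–Golgi–plasma membrane, mitochondria) plus
brightfield, then quantify compound effects through thousands of per-cell
morphological features. The quality of every downstream number hinges on
instance segmentation — assigning each cell and each nucleus its own label.
`paintseg` implements the full post-model workflow for this setting, aimed
at image-analysis engineers and screening scientists who want a scriptable,
testable pipeline:

* **Ground-truth preparation** — convert outline annotations (border = 255
  PNGs) into instance label masks: outline inversion, 4-connected
  component labelling, background/sliver removal, and per-instance
  dilation to restore the border pixels, plus centered ROI cropping.
* **Instance segmentation from confidence maps** — any model (or the
  bundled classical baseline) supplies per-class *area* and *border*
  probability maps; instances are recovered by thresholding, seeding where
  area evidence dominates border evidence, and marker-based watershed on
  the border map so touching objects split along border ridges.
* **Nucleus-guided refinement** — cells holding ≥ 2 nucleus centroids are
  partitioned by nearest-centroid assignment; small anucleate fragments
  are deleted (isolated) or merged into the neighbor with the weakest
  shared-border evidence. Cytoplasm = cell − nucleus.
* **Feature extraction** — eight CellProfiler-compatible groups per object
  and compartment: AreaShape (incl. 30 Zernike magnitudes at degree 9),
  Correlation, Granularity, Intensity, Location, Neighbors,
  RadialDistribution, Texture (13 Haralick statistics).
* **Evaluation and QC** — greedy one-to-one IoU matching (threshold 0.5)
  with precision `P = TP/(TP+FP)`, recall `R = TP/(TP+FN)`,
  `F1 = 2PR/(P+R)` and the Jaccard-style detection score
  `AP = TP/(TP+FP+FN)`; feature tables are compared to a reference via
  min–max-normalized MSE/MAE pooled per group, and redundancy is reduced
  by greedy correlation filtering in descending variance order.
* **Synthetic fixtures** — a seeded generator of Cell Painting-like scenes
  with exact masks, outlines and ideal confidence maps, so the entire
  pipeline is testable without downloading any data.

## Worked example

```python
from paintseg import (SceneParams, generate_scene, instances_from_confidence,
                      split_multinucleated, merge_or_remove_fragments,
                      match_instances, detection_metrics, FeatureCatalog,
                      extract_all)

# a scene with 10 cells: 2 drawn as merged double-nucleate blobs and
# 3 small anucleate fragments planted as segmentation-style errors
scene = generate_scene(SceneParams(size=512, n_cells=10,
                                   multi_nucleate_fraction=0.2,
                                   fragment_fraction=0.3), seed=3)

nuclei = instances_from_confidence(scene.confidence["nucleus"])
cells = instances_from_confidence(scene.confidence["cell"])
before = detection_metrics(match_instances(scene.reference_cells, cells))
cells = split_multinucleated(cells, nuclei)
cells = merge_or_remove_fragments(cells, nuclei,
                                  scene.confidence["cell"].border_map)
after = detection_metrics(match_instances(scene.reference_cells, cells))
print(f"cell AP before refinement: {before.ap:.3f}")
print(f"cell AP after refinement:  {after.ap:.3f}")

catalog = FeatureCatalog(channels=("DNA", "RNA"), granularity_scales=4)
table = extract_all(catalog, scene.stack, cells, nuclei)
print(f"feature table: {table.n_objects} rows x {len(table.feature_columns)} features")
```

Output:

```
cell AP before refinement: 0.667
cell AP after refinement:  1.000
feature table: 36 rows x 165 features
```

The planted merges and fragments cost a third of the detection score;
nucleus-guided refinement recovers a perfect AP because every merged blob
is split at its two nucleus centroids and every fragment is removed or
absorbed. The 36 rows are 12 objects × 3 compartments (cell, nucleus,
cytoplasm); the column count follows in closed form from the catalog
configuration.

## Command line

Each stage is also a subcommand operating on a dataset directory:

```bash
paintseg synth data/ --n-scenes 3 --n-cells 10 --seed 1
paintseg pipeline data/            # prep -> segment -> refine -> features -> evaluate
paintseg evaluate data/            # metrics JSON for refined masks vs truth
paintseg qc data/ --reference-csv reference.csv
paintseg prioritize data/ --corr-threshold 0.9
```

Every config key of the pipeline can live in a YAML file (`--config`) and
is echoed to `effective-config.yaml` in the dataset directory; reruns with
the same config and seed are bit-identical.

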