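"""End-to-end pipeline orchestration over an on-disk dataset layout.

The layout mirrors plate-organized microscopy data::

    <root>/manifest.csv                      plate,well,site,category
    <root>/images/<name>-<CH>.tiff           one grayscale TIFF per channel
    <root>/outlines/<name>-{cell,nucleus}.png
    <root>/truth/<name>-{cells,nuclei}.tiff          (synthetic data only)
    <root>/truth/<name>-reference-cells.tiff
    <root>/confidence/<name>-{cell,nucleus}-{class,border}.tiff

Each stage reads the previous stage's artifacts and writes its own, so the
fused ``run_pipeline`` and the individual CLI subcommands produce identical
results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from paintseg import mask_prep
from paintseg.features import DEFAULT_FEATURE_CHANNELS, FeatureCatalog, extract_all
from paintseg.instance_engine import (
    DEFAULT_CLASS_THRESHOLD,
    DEFAULT_SEED_MARGIN,
    DEFAULT_SMOOTHING_SIGMA,
    ConfidenceMaps,
    baseline_confidence_maps,
    instances_from_confidence,
    semantic_foreground_instances,
)
from paintseg.io_plate import (
    COMPARTMENTS,
    DEFAULT_CHANNELS,
    ChannelStack,
    FeatureTable,
    PlateCoordinate,
    SubsetManifest,
    read_channel_stack,
    read_feature_table,
    write_channel_stack,
    write_feature_table,
)
from paintseg.metrics_qc import (
    DEFAULT_CORR_THRESHOLD,
    DEFAULT_IOU_THRESHOLD,
    compare_feature_tables,
    detection_metrics,
    match_instances,
    metrics_from_counts,
    pixelwise_foreground_iou,
    prioritize_features,
    write_metrics_json,
)
from paintseg.refine import (
    DEFAULT_MIN_AREA_FRACTION,
    default_min_area,
    derive_cytoplasm,
    merge_or_remove_fragments,
    split_multinucleated,
)
from paintseg.synthfix import SceneParams, generate_scene

import imageio.v3 as iio


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Unknown keys are rejected when loading from a mapping / YAML file, and
    the effective configuration (defaults + overrides) is echoed into the
    output directory of every run.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    feature_channels: tuple[str, ...] = DEFAULT_FEATURE_CHANNELS
    compartments: tuple[str, ...] = COMPARTMENTS
    class_threshold: float = DEFAULT_CLASS_THRESHOLD
    seed_margin: float = DEFAULT_SEED_MARGIN
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA
    cell_mode: str = "instance"  # or "semantic"
    outline_min_area: int = mask_prep.DEFAULT_MIN_AREA
    roi_size: int | None = None
    min_area: float | None = None  # fragment threshold; None -> data-driven
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION
    zernike_degree: int = 9
    granularity_scales: int = 16
    radial_bins: int = 4
    texture_levels: int = 8
    texture_offsets: tuple[int, ...] = (3,)
    neighbor_distance: int = 5
    iou_threshold: float = DEFAULT_IOU_THRESHOLD
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_mode not in ("instance", "semantic"):
            raise ValueError(f"cell_mode must be 'instance' or 'semantic', got {self.cell_mode!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("channels", "feature_channels", "compartments", "texture_offsets"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    def catalog(self) -> FeatureCatalog:
        return FeatureCatalog(
            channels=self.feature_channels,
            compartments=self.compartments,
            zernike_degree=self.zernike_degree,
            granularity_scales=self.granularity_scales,
            radial_bins=self.radial_bins,
            texture_levels=self.texture_levels,
            texture_offsets=self.texture_offsets,
            neighbor_distance=self.neighbor_distance,
        )


class StageError(RuntimeError):
    """A stage failure annotated with the stage and image coordinate."""

    def __init__(self, stage: str, coord: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {coord}: {cause}")
        self.stage = stage
        self.coord = coord
        self.cause = cause


# ---------------------------------------------------------------------------
# dataset writing (synth) and per-stage runners
# ---------------------------------------------------------------------------

def write_synthetic_dataset(
    root: str | Path,
    n_scenes: int = 3,
    params: SceneParams = SceneParams(),
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> SubsetManifest:
    """Generate ``n_scenes`` scenes into the standard dataset layout."""
    root = Path(root)
    for sub in ("images", "outlines", "truth", "confidence"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_scenes):
        coord = PlateCoordinate("SYN000001", "ABCDEFGHIJKLMNOP"[i // 24], i % 24 + 1, 5)
        scene = generate_scene(params, seed=seed, coord=coord)
        name = coord.image_name
        write_channel_stack(scene.stack, root / "images", prefix=name)
        for comp in ("cell", "nucleus"):
            iio.imwrite(root / "outlines" / f"{name}-{comp}.png", scene.outlines[comp])
        mask_prep.write_mask(scene.cells, root / "truth" / f"{name}-cells.tiff")
        mask_prep.write_mask(scene.nuclei, root / "truth" / f"{name}-nuclei.tiff")
        mask_prep.write_mask(
            scene.reference_cells, root / "truth" / f"{name}-reference-cells.tiff"
        )
        for comp in ("cell", "nucleus"):
            maps = scene.confidence[comp]
            maps.write(
                root / "confidence" / f"{name}-{comp}-class.tiff",
                root / "confidence" / f"{name}-{comp}-border.tiff",
            )
        entries.append((coord, "synthetic"))
    manifest = SubsetManifest(entries)
    manifest.write(root / "manifest.csv")
    return manifest


def _coords(root: Path) -> list[PlateCoordinate]:
    manifest = SubsetManifest.read(root / "manifest.csv")
    return [coord for coord, _ in manifest]


def run_prep_masks(root: str | Path, config: PipelineConfig) -> None:
    """Outline images -> restored instance label masks under prep/."""
    root = Path(root)
    for coord in _coords(root):
        name = coord.image_name
        try:
            for comp, out_name in (("cell", "cells"), ("nucleus", "nuclei")):
                outline = mask_prep.read_outline(root / "outlines" / f"{name}-{comp}.png")
                mask = mask_prep.outlines_to_instances(outline, config.outline_min_area)
                mask = mask_prep.restore_borders(mask)
                if config.roi_size:
                    mask = mask_prep.crop_center_roi(mask, config.roi_size)
                mask_prep.write_mask(mask, root / "prep" / f"{name}-{out_name}.tiff")
        except Exception as exc:
            raise StageError("prep-masks", name, exc) from exc


def _load_stack(root: Path, coord: PlateCoordinate, channels) -> ChannelStack:
    paths = {c: root / "images" / f"{coord.image_name}-{c}.tiff" for c in channels}
    return read_channel_stack(paths, coord)


def _load_confidence(root: Path, name: str, comp: str) -> ConfidenceMaps | None:
    class_path = root / "confidence" / f"{name}-{comp}-class.tiff"
    border_path = root / "confidence" / f"{name}-{comp}-border.tiff"
    if class_path.is_file() and border_path.is_file():
        return ConfidenceMaps.read(class_path, border_path)
    return None


def run_segment(root: str | Path, config: PipelineConfig) -> None:
    """Confidence maps (on disk, or baseline-generated) -> instance masks."""
    root = Path(root)
    for coord in _coords(root):
        name = coord.image_name
        try:
            maps = {c: _load_confidence(root, name, c) for c in ("cell", "nucleus")}
            if maps["cell"] is None or maps["nucleus"] is None:
                stack = _load_stack(root, coord, config.channels)
                generated = baseline_confidence_maps(stack, config.smoothing_sigma)
                maps = {c: maps[c] or generated[c] for c in ("cell", "nucleus")}
            nuclei = instances_from_confidence(
                maps["nucleus"], config.class_threshold, config.seed_margin
            )
            if config.cell_mode == "semantic":
                cells = semantic_foreground_instances(maps["cell"], config.class_threshold)
            else:
                cells = instances_from_confidence(
                    maps["cell"], config.class_threshold, config.seed_margin
                )
            mask_prep.write_mask(cells, root / "segmented" / f"{name}-cells.tiff")
            mask_prep.write_mask(nuclei, root / "segmented" / f"{name}-nuclei.tiff")
        except Exception as exc:
            raise StageError("segment", name, exc) from exc


def run_refine(root: str | Path, config: PipelineConfig) -> None:
    """Nucleus-guided splitting + fragment merging -> refined masks."""
    root = Path(root)
    for coord in _coords(root):
        name = coord.image_name
        try:
            cells = mask_prep.read_mask(root / "segmented" / f"{name}-cells.tiff")
            nuclei = mask_prep.read_mask(root / "segmented" / f"{name}-nuclei.tiff")
            cell_maps = _load_confidence(root, name, "cell")
            border = (
                cell_maps.border_map
                if cell_maps is not None
                else np.zeros(cells.shape, dtype=float)
            )
            cells = split_multinucleated(cells, nuclei)
            min_area = config.min_area
            if min_area is None:
                min_area = default_min_area(cells, nuclei, config.min_area_fraction)
            cells = merge_or_remove_fragments(cells, nuclei, border, min_area)
            mask_prep.write_mask(cells, root / "refined" / f"{name}-cells.tiff")
            mask_prep.write_mask(nuclei, root / "refined" / f"{name}-nuclei.tiff")
        except Exception as exc:
            raise StageError("refine", name, exc) from exc


def run_features(root: str | Path, config: PipelineConfig) -> FeatureTable:
    """Per-object feature extraction over refined masks -> features.csv."""
    root = Path(root)
    catalog = config.catalog()
    tables = []
    for coord in _coords(root):
        name = coord.image_name
        try:
            stack = _load_stack(root, coord, config.channels)
            cells = mask_prep.read_mask(root / "refined" / f"{name}-cells.tiff")
            nuclei = mask_prep.read_mask(root / "refined" / f"{name}-nuclei.tiff")
            tables.append(extract_all(catalog, stack, cells, nuclei, coord))
        except Exception as exc:
            raise StageError("features", name, exc) from exc
    import pandas as pd

    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    table = FeatureTable(frame)
    write_feature_table(table, root / "features.csv")
    return table


def run_evaluate(root: str | Path, config: PipelineConfig) -> dict:
    """Refined masks vs ground truth -> metrics.json (pooled + per image)."""
    root = Path(root)
    report: dict = {"per_image": {}, "iou_threshold": config.iou_threshold}
    for kind, truth_name, pred_name in (
        ("cell", "reference-cells", "cells"),
        ("nucleus", "nuclei", "nuclei"),
    ):
        tp = fp = fn = 0
        ious: list[float] = []
        pix = []
        for coord in _coords(root):
            name = coord.image_name
            try:
                truth_path = root / "truth" / f"{name}-{truth_name}.tiff"
                if not truth_path.is_file() and truth_name == "reference-cells":
                    truth_path = root / "truth" / f"{name}-cells.tiff"
                gt = mask_prep.read_mask(truth_path)
                pred = mask_prep.read_mask(root / "refined" / f"{name}-{pred_name}.tiff")
                match = match_instances(gt, pred, config.iou_threshold)
                m = detection_metrics(match)
                tp += match.tp
                fp += match.fp
                fn += match.fn
                ious += [iou for _, _, iou in match.pairs]
                pix.append(pixelwise_foreground_iou(gt, pred))
                report["per_image"].setdefault(name, {})[kind] = {
                    "counts": {"tp": match.tp, "fp": match.fp, "fn": match.fn},
                    **m.to_dict(),
                }
            except Exception as exc:
                raise StageError("evaluate", name, exc) from exc
        pooled = metrics_from_counts(tp, fp, fn).to_dict()
        pooled["mean_matched_iou"] = float(np.mean(ious)) if ious else 0.0
        pooled["pixelwise_foreground_iou"] = float(np.mean(pix)) if pix else 0.0
        pooled["counts"] = {"tp": tp, "fp": fp, "fn": fn}
        report[kind] = pooled
    write_metrics_json(report, root / "metrics.json")
    return report


def run_qc(root: str | Path, config: PipelineConfig, reference_csv: str | Path) -> None:
    """Measured features vs a reference table -> qc.csv."""
    root = Path(root)
    measured = read_feature_table(root / "features.csv")
    reference = read_feature_table(reference_csv)
    report = compare_feature_tables(measured, reference)
    report.to_csv(root / "qc.csv")


def run_prioritize(root: str | Path, config: PipelineConfig) -> list[str]:
    """Correlation-based feature prioritization -> prioritized.txt."""
    root = Path(root)
    table = read_feature_table(root / "features.csv")
    selected = prioritize_features(table, config.corr_threshold)
    (root / "prioritized.txt").write_text("\n".join(selected) + "\n")
    return selected


def run_pipeline(
    root: str | Path,
    config: PipelineConfig,
    reference_csv: str | Path | None = None,
    use_prepared_masks: bool = False,
) -> dict:
    """Run prep -> segment -> refine -> features (-> evaluate / qc /
    prioritize) over a dataset directory; returns the metrics report.

    When ``use_prepared_masks`` is set, the outline-derived masks stand in
    for the segmentation output (the configuration used to benchmark the
    feature extractor against reference outputs on shared masks).
    """
    root = Path(root)
    config.to_yaml(root / "effective-config.yaml")
    run_prep_masks(root, config)
    if use_prepared_masks:
        (root / "segmented").mkdir(exist_ok=True)
        for coord in _coords(root):
            name = coord.image_name
            for kind in ("cells", "nuclei"):
                mask = mask_prep.read_mask(root / "prep" / f"{name}-{kind}.tiff")
                mask_prep.write_mask(mask, root / "segmented" / f"{name}-{kind}.tiff")
    else:
        run_segment(root, config)
    run_refine(root, config)
    run_features(root, config)
    report = {}
    if (root / "truth").is_dir():
        report = run_evaluate(root, config)
    if reference_csv is not None:
        run_qc(root, config, reference_csv)
    run_prioritize(root, config)
    return report
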