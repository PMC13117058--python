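"""Instance segmentation from class / border confidence maps.

A segmentation model (or the classical baseline below) provides, per object
class, a *class map* scoring the probability that a pixel lies inside an
object and a *border map* scoring the probability that it lies on an object
boundary.  Instances are recovered by thresholding the class map, seeding
markers where class evidence clearly dominates border evidence, and
flooding the border map with a marker-based watershed so that touching
objects split along border ridges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.segmentation import watershed

from paintseg.io_plate import ChannelStack

#: Class-map threshold defining segmentation foreground.
DEFAULT_CLASS_THRESHOLD = 0.5
#: Required margin of class over border confidence for watershed seeds.
DEFAULT_SEED_MARGIN = 0.3
#: Gaussian sigma (px) used by the classical baseline map generator.
DEFAULT_SMOOTHING_SIGMA = 2.0


@dataclass
class ConfidenceMaps:
    """Per-class pixel probabilities for object area and object border."""

    class_map: np.ndarray
    border_map: np.ndarray

    def __post_init__(self) -> None:
        self.class_map = np.asarray(self.class_map, dtype=float)
        self.border_map = np.asarray(self.border_map, dtype=float)
        if self.class_map.shape != self.border_map.shape:
            raise ValueError(
                f"class map {self.class_map.shape} and border map "
                f"{self.border_map.shape} differ in shape"
            )
        for name, arr in (("class", self.class_map), ("border", self.border_map)):
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError(f"{name} map values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_map.shape

    def write(self, class_path: str | Path, border_path: str | Path) -> None:
        for path, arr in ((class_path, self.class_map), (border_path, self.border_map)):
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(str(path), arr.astype(np.float32))

    @classmethod
    def read(cls, class_path: str | Path, border_path: str | Path) -> "ConfidenceMaps":
        """Read maps from float32 TIFFs in [0, 1] or 16-bit TIFFs (scaled)."""
        maps = []
        for path in (class_path, border_path):
            arr = tifffile.imread(str(path))
            if arr.dtype == np.uint16:
                arr = arr.astype(float) / 65535.0
            elif arr.dtype == np.uint8:
                arr = arr.astype(float) / 255.0
            maps.append(np.asarray(arr, dtype=float))
        return cls(*maps)


def _soft_threshold(image: np.ndarray) -> np.ndarray:
    """Map an intensity image to [0, 1] with 0.5 pinned at the Otsu level.

    Values are min-max rescaled, then the ranges below and above the Otsu
    threshold are mapped linearly onto [0, 0.5] and [0.5, 1] respectively —
    a soft, monotone thresholding that keeps sub-threshold structure.
    """
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=float)
    s = (image - lo) / (hi - lo)
    t = float(threshold_otsu(s))
    t = min(max(t, 1e-6), 1 - 1e-6)
    out = np.where(s < t, 0.5 * s / t, 0.5 + 0.5 * (s - t) / (1 - t))
    return np.clip(out, 0.0, 1.0)


def _border_from_class(class_map: np.ndarray) -> np.ndarray:
    grad = sobel(class_map)
    m = float(grad.max())
    return grad / m if m > 0 else np.zeros_like(grad)


def baseline_confidence_maps(
    stack: ChannelStack,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
) -> dict[str, ConfidenceMaps]:
    """Classical confidence-map generator from the DNA and RNA channels.

    Nuclei are scored from the (smoothed, rescaled, softly Otsu-thresholded)
    DNA channel; whole cells from the pixelwise max of RNA and DNA, since
    the RNA stain covers cytoplasm and nucleoli but can dim over chromatin.
    Border maps are the normalized gradient magnitude of each class map.
    Any trained model producing maps in the same format can replace this.
    """
    for required in ("DNA", "RNA"):
        if not stack.has_channel(required):
            raise ValueError(f"baseline confidence maps require the {required!r} channel")
    dna = stack.channel("DNA").astype(float)
    rna = stack.channel("RNA").astype(float)
    out: dict[str, ConfidenceMaps] = {}
    for cls_name, plane in (("nucleus", dna), ("cell", np.maximum(rna, dna))):
        sm = gaussian(plane, sigma=smoothing_sigma, preserve_range=True)
        class_map = _soft_threshold(sm)
        out[cls_name] = ConfidenceMaps(class_map, _border_from_class(class_map))
    return out


def instances_from_confidence(
    maps: ConfidenceMaps,
    class_threshold: float = DEFAULT_CLASS_THRESHOLD,
    seed_margin: float = DEFAULT_SEED_MARGIN,
) -> np.ndarray:
    """Post-process confidence maps into an instance label mask.

    Foreground is ``class_map >= class_threshold``.  Watershed seeds are the
    connected components of ``class_map - border_map >= seed_margin`` inside
    the foreground — regions where area evidence clearly dominates border
    evidence, i.e. object cores.  The border map is flooded from the seeds
    (marker-based watershed restricted to the foreground), so each seed
    yields one instance and touching objects split along border ridges.
    Foreground pixels unreachable from any seed are kept as their own
    connected-component instances rather than dropped.
    """
    if not 0 < class_threshold < 1:
        raise ValueError(f"class_threshold must be in (0, 1), got {class_threshold}")
    fg = maps.class_map >= class_threshold
    if not fg.any():
        return np.zeros(maps.shape, dtype=np.int32)
    seed_mask = ((maps.class_map - maps.border_map) >= seed_margin) & fg
    seeds, n_seeds = ndi.label(seed_mask)
    if n_seeds == 0:
        labels, _ = ndi.label(fg)
        return labels.astype(np.int32)
    labels = watershed(maps.border_map, markers=seeds, mask=fg)
    # orphan foreground (separate components with no seed) -> own instances
    orphan = fg & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan)
        labels = labels + np.where(extra > 0, extra + n_seeds, 0)
    return labels.astype(np.int32)


def semantic_foreground_instances(
    maps: ConfidenceMaps,
    class_threshold: float = DEFAULT_CLASS_THRESHOLD,
) -> np.ndarray:
    """Semantic-mode cell segmentation: thresholded foreground labelled as
    plain connected components, with no border-guided splitting.

    Intended for the ``cell_mode = "semantic"`` pipeline variant, where cell
    foreground is carved into instances afterwards by the nucleus-guided
    refinement (touching cells are split at nucleus centroids instead of
    border ridges).
    """
    if not 0 < class_threshold < 1:
        raise ValueError(f"class_threshold must be in (0, 1), got {class_threshold}")
    labels, _ = ndi.label(maps.class_map >= class_threshold)
    return labels.astype(np.int32)
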