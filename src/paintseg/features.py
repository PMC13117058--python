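"""CellProfiler-compatible per-object feature extraction.

Eight feature groups are measured per object and compartment (cell,
nucleus, cytoplasm = cell minus nucleus): AreaShape (incl. Zernike shape
moments), Correlation, Granularity, Intensity, Location, Neighbors,
RadialDistribution and Texture (the 13 Haralick statistics).  The catalog
is configuration-driven — channels, Zernike degree, granularity scales,
radial bins, texture levels/offsets — and its column order is deterministic
given a configuration, with a closed-form column count.

Conventions follow published CellProfiler definitions where applicable:
X = column, Y = row, pixel coordinates 0-based; quantiles use linear
interpolation; statistics whose definition divides by a zero variance are
defined as 0; objects with an empty compartment receive all-zero rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from paintseg.io_plate import (
    COMPARTMENTS,
    KEY_COLUMNS,
    ChannelStack,
    FeatureTable,
    PlateCoordinate,
)
from paintseg.refine import derive_cytoplasm

GROUPS = (
    "AreaShape",
    "Correlation",
    "Granularity",
    "Intensity",
    "Location",
    "Neighbors",
    "RadialDistribution",
    "Texture",
)

_AREASHAPE_NAMES = (
    "Area",
    "Perimeter",
    "FormFactor",
    "Compactness",
    "Eccentricity",
    "MajorAxisLength",
    "MinorAxisLength",
    "Orientation",
    "Solidity",
    "Extent",
    "EquivalentDiameter",
    "EulerNumber",
    "ConvexArea",
    "Center_X",
    "Center_Y",
    "BoundingBoxArea",
    "BoundingBoxMinimum_X",
    "BoundingBoxMinimum_Y",
    "BoundingBoxMaximum_X",
    "BoundingBoxMaximum_Y",
    "MaxFeretDiameter",
    "MinFeretDiameter",
    "MeanRadius",
    "MedianRadius",
    "MaximumRadius",
)

_INTENSITY_NAMES = (
    "IntegratedIntensity",
    "MeanIntensity",
    "StdIntensity",
    "MinIntensity",
    "MaxIntensity",
    "MedianIntensity",
    "MADIntensity",
    "LowerQuartileIntensity",
    "UpperQuartileIntensity",
    "MassDisplacement",
    "IntegratedIntensityEdge",
    "MeanIntensityEdge",
    "StdIntensityEdge",
    "MinIntensityEdge",
    "MaxIntensityEdge",
)

_CORRELATION_NAMES = (
    "Correlation",
    "Slope",
    "Overlap",
    "MandersM1",
    "MandersM2",
    "K1",
    "K2",
)

_NEIGHBOR_NAMES = (
    "NumberOfNeighbors",
    "PercentTouching",
    "FirstClosestDistance",
    "SecondClosestDistance",
    "AngleBetweenNeighbors",
)

_HARALICK_NAMES = (
    "AngularSecondMoment",
    "Contrast",
    "Correlation",
    "Variance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InfoMeas1",
    "InfoMeas2",
)

#: Fluorescent channels measured by default (brightfield planes carry no
#: stain-specific intensity signal).
DEFAULT_FEATURE_CHANNELS = ("DNA", "ER", "RNA", "AGP", "Mito")


def zernike_indices(degree: int) -> list[tuple[int, int]]:
    """All (n, m) with 0 <= m <= n <= degree and n - m even (degree 9: 30)."""
    return [(n, m) for n in range(degree + 1) for m in range(n % 2, n + 1, 2)]


@dataclass(frozen=True)
class FeatureCatalog:
    """Deterministic ordered descriptor list for one extraction run."""

    channels: tuple[str, ...] = DEFAULT_FEATURE_CHANNELS
    compartments: tuple[str, ...] = COMPARTMENTS
    zernike_degree: int = 9
    granularity_scales: int = 16
    radial_bins: int = 4
    texture_levels: int = 8
    texture_offsets: tuple[int, ...] = (3,)
    neighbor_distance: int = 5
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown feature group(s): {sorted(unknown)}")
        bad = set(self.compartments) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment(s): {sorted(bad)}")

    def columns(self) -> list[str]:
        """Enumerate all feature column names in canonical order."""
        cols: list[str] = []
        ch = self.channels
        if "AreaShape" in self.groups:
            cols += [f"AreaShape_{n}" for n in _AREASHAPE_NAMES]
            cols += [f"AreaShape_Zernike_{n}_{m}" for n, m in zernike_indices(self.zernike_degree)]
        if "Correlation" in self.groups:
            for i in range(len(ch)):
                for j in range(i + 1, len(ch)):
                    cols += [f"Correlation_{n}_{ch[i]}_{ch[j]}" for n in _CORRELATION_NAMES]
        if "Granularity" in self.groups:
            for c in ch:
                cols += [f"Granularity_{s}_{c}" for s in range(1, self.granularity_scales + 1)]
        if "Intensity" in self.groups:
            for c in ch:
                cols += [f"Intensity_{n}_{c}" for n in _INTENSITY_NAMES]
        if "Location" in self.groups:
            cols += ["Location_Center_X", "Location_Center_Y"]
            for c in ch:
                cols += [
                    f"Location_CenterMassIntensity_X_{c}",
                    f"Location_CenterMassIntensity_Y_{c}",
                    f"Location_MaxIntensity_X_{c}",
                    f"Location_MaxIntensity_Y_{c}",
                ]
        if "Neighbors" in self.groups:
            cols += [f"Neighbors_{n}" for n in _NEIGHBOR_NAMES]
        if "RadialDistribution" in self.groups:
            for c in ch:
                for stat in ("FracAtD", "MeanFrac", "RadialCV"):
                    cols += [
                        f"RadialDistribution_{stat}_{c}_{b}of{self.radial_bins}"
                        for b in range(1, self.radial_bins + 1)
                    ]
        if "Texture" in self.groups:
            for c in ch:
                for off in self.texture_offsets:
                    cols += [f"Texture_{n}_{c}_{off}" for n in _HARALICK_NAMES]
        return cols

    def expected_column_count(self) -> int:
        """Closed-form column count for this configuration."""
        c = len(self.channels)
        n = 0
        if "AreaShape" in self.groups:
            n += 25 + len(zernike_indices(self.zernike_degree))
        if "Correlation" in self.groups:
            n += len(_CORRELATION_NAMES) * c * (c - 1) // 2
        if "Granularity" in self.groups:
            n += self.granularity_scales * c
        if "Intensity" in self.groups:
            n += 15 * c
        if "Location" in self.groups:
            n += 2 + 4 * c
        if "Neighbors" in self.groups:
            n += 5
        if "RadialDistribution" in self.groups:
            n += 3 * self.radial_bins * c
        if "Texture" in self.groups:
            n += 13 * c * len(self.texture_offsets)
        return n

    @staticmethod
    def group_of(column: str) -> str:
        return column.split("_", 1)[0]


# ---------------------------------------------------------------------------
# per-object helpers
# ---------------------------------------------------------------------------

def _edge_mask(mask: np.ndarray) -> np.ndarray:
    """Object pixels with at least one non-object 4-neighbor."""
    eroded = ndi.binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0
    )
    return mask & ~eroded


def _hull_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-corner point cloud of the object (never degenerate)."""
    rows, cols = np.nonzero(mask)
    pts = np.stack([rows, cols], axis=1).astype(float)
    corners = np.concatenate(
        [pts + d for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    return corners


def _feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """(max, min) Feret diameters from the convex hull of pixel corners."""
    pts = _hull_points(mask)
    hull = ConvexHull(pts)
    v = pts[hull.vertices]
    # max Feret: largest pairwise vertex distance
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    max_feret = float(np.sqrt(d2.max()))
    # min Feret: rotating calipers — smallest width over hull edge normals
    edges = np.roll(v, -1, axis=0) - v
    norms = np.hypot(edges[:, 0], edges[:, 1])
    keep = norms > 0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / norms[keep, None]
    proj = v @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return max_feret, float(widths.min())


def areashape_features(mask: np.ndarray) -> dict[str, float]:
    """Size and shape descriptors of one (possibly disconnected) object.

    Perimeter is the boundary path length (axial step 1, diagonal sqrt 2,
    corner-corrected); FormFactor = 4 pi A / P^2 is 1 for a perfect disk;
    Compactness = 2 pi E[d^2] / A (1 for a filled disk); radii are
    distance-to-boundary statistics over the object's pixels.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(measure.perimeter(mask, neighborhood=4))
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    mean_sq = float(((rows - cy) ** 2 + (cols - cx) ** 2).mean())
    edt = ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    radii = edt[mask]
    max_feret, min_feret = _feret_diameters(mask)
    minr, minc, maxr, maxc = props.bbox
    return {
        "Area": area,
        "Perimeter": perimeter,
        "FormFactor": 4 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        "Compactness": 2 * math.pi * mean_sq / area,
        "Eccentricity": float(props.eccentricity),
        "MajorAxisLength": float(props.axis_major_length),
        "MinorAxisLength": float(props.axis_minor_length),
        "Orientation": float(np.degrees(props.orientation)),
        "Solidity": float(props.solidity),
        "Extent": float(props.extent),
        "EquivalentDiameter": float(props.equivalent_diameter_area),
        "EulerNumber": float(props.euler_number),
        "ConvexArea": float(props.area_convex),
        "Center_X": float(cx),
        "Center_Y": float(cy),
        "BoundingBoxArea": float((maxr - minr) * (maxc - minc)),
        "BoundingBoxMinimum_X": float(minc),
        "BoundingBoxMinimum_Y": float(minr),
        "BoundingBoxMaximum_X": float(maxc),
        "BoundingBoxMaximum_Y": float(maxr),
        "MaxFeretDiameter": max_feret,
        "MinFeretDiameter": min_feret,
        "MeanRadius": float(radii.mean()),
        "MedianRadius": float(np.median(radii)),
        "MaximumRadius": float(radii.max()),
    }


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out = out + c * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(mask: np.ndarray, degree: int = 9) -> dict[str, float]:
    """Area-normalized Zernike moment magnitudes of an object's shape.

    The object is mapped onto the unit disk via its centroid and minimum
    enclosing radius; each moment is A_nm = (n+1)/pi * sum f V*_nm dA with
    the pixel area element 1/R^2, so a solid disk has |A_00| ~ 1 and
    magnitudes are rotation invariant.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    dy = rows - cy
    dx = cols - cx
    r = np.hypot(dy, dx)
    radius = max(float(r.max()), 1.0)
    rho = r / radius
    theta = np.arctan2(dy, dx)
    d_area = 1.0 / radius**2
    out = {}
    for n, m in zernike_indices(degree):
        basis = _radial_poly(n, m, rho) * np.exp(-1j * m * theta)
        a = (n + 1) / math.pi * np.sum(basis) * d_area
        out[f"Zernike_{n}_{m}"] = float(abs(a))
    return out


def intensity_features(channel: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Intensity statistics of one object on one channel."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    vals = np.asarray(channel, dtype=float)[mask]
    rows, cols = np.nonzero(mask)
    total = float(vals.sum())
    if total > 0:
        my = float((rows * vals).sum()) / total
        mx = float((cols * vals).sum()) / total
        displacement = math.hypot(my - rows.mean(), mx - cols.mean())
    else:
        displacement = 0.0
    edge = _edge_mask(mask)
    evals = np.asarray(channel, dtype=float)[edge]
    med = float(np.median(vals))
    return {
        "IntegratedIntensity": total,
        "MeanIntensity": float(vals.mean()),
        "StdIntensity": float(vals.std()),
        "MinIntensity": float(vals.min()),
        "MaxIntensity": float(vals.max()),
        "MedianIntensity": med,
        "MADIntensity": float(np.median(np.abs(vals - med))),
        "LowerQuartileIntensity": float(np.percentile(vals, 25)),
        "UpperQuartileIntensity": float(np.percentile(vals, 75)),
        "MassDisplacement": displacement,
        "IntegratedIntensityEdge": float(evals.sum()),
        "MeanIntensityEdge": float(evals.mean()) if evals.size else 0.0,
        "StdIntensityEdge": float(evals.std()) if evals.size else 0.0,
        "MinIntensityEdge": float(evals.min()) if evals.size else 0.0,
        "MaxIntensityEdge": float(evals.max()) if evals.size else 0.0,
    }


def location_features(
    channels: dict[str, np.ndarray], mask: np.ndarray
) -> dict[str, float]:
    """Binary centroid plus per-channel intensity-weighted and max locations.

    X is the column coordinate and Y the row coordinate; max-intensity
    location ties resolve to the first occurrence in raster order.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    rows, cols = np.nonzero(mask)  # raster order
    out = {"Center_X": float(cols.mean()), "Center_Y": float(rows.mean())}
    for name, channel in channels.items():
        vals = np.asarray(channel, dtype=float)[rows, cols]
        total = float(vals.sum())
        if total > 0:
            out[f"CenterMassIntensity_X_{name}"] = float((cols * vals).sum()) / total
            out[f"CenterMassIntensity_Y_{name}"] = float((rows * vals).sum()) / total
        else:
            out[f"CenterMassIntensity_X_{name}"] = float(cols.mean())
            out[f"CenterMassIntensity_Y_{name}"] = float(rows.mean())
        i = int(np.argmax(vals))  # first raster occurrence on ties
        out[f"MaxIntensity_X_{name}"] = float(cols[i])
        out[f"MaxIntensity_Y_{name}"] = float(rows[i])
    return out


def _otsu_above(vals: np.ndarray) -> np.ndarray:
    """Boolean 'signal' selection within an object by Otsu; a constant
    channel is treated as entirely signal."""
    if np.unique(vals).size < 2:
        return np.ones(vals.shape, dtype=bool)
    return vals > threshold_otsu(vals)


def correlation_features(
    channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    """Colocalization measures between two channels within one object."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("correlation requires an object with >= 2 pixels")
    a = np.asarray(channel_a, dtype=float)[mask]
    b = np.asarray(channel_b, dtype=float)[mask]
    va, vb = a.var(), b.var()
    cov = float(((a - a.mean()) * (b - b.mean())).mean())
    corr = cov / math.sqrt(va * vb) if va > 0 and vb > 0 else 0.0
    slope = cov / va if va > 0 else 0.0
    denom = math.sqrt(float((a**2).sum()) * float((b**2).sum()))
    overlap = float((a * b).sum()) / denom if denom > 0 else 0.0
    above_a = _otsu_above(a)
    above_b = _otsu_above(b)
    sum_a, sum_b = float(a.sum()), float(b.sum())
    m1 = float(a[above_b].sum()) / sum_a if sum_a > 0 else 0.0
    m2 = float(b[above_a].sum()) / sum_b if sum_b > 0 else 0.0
    sum_ab = float((a * b).sum())
    k1 = sum_ab / float((a**2).sum()) if (a**2).sum() > 0 else 0.0
    k2 = sum_ab / float((b**2).sum()) if (b**2).sum() > 0 else 0.0
    return {
        "Correlation": corr,
        "Slope": slope,
        "Overlap": overlap,
        "MandersM1": m1,
        "MandersM2": m2,
        "K1": k1,
        "K2": k2,
    }


def granularity_spectrum(
    channel: np.ndarray, mask: np.ndarray, n_scales: int = 16
) -> np.ndarray:
    """Granularity spectrum by iterative grayscale openings.

    Element i (1-based) is 100 x (mean intensity removed by the opening at
    disk radius i, relative to the previous scale) / (original mean within
    the object).  The spectrum sums to the total fraction of intensity
    removable at the probed scales; fine texture loads early elements.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    rows, cols = np.nonzero(mask)
    pad = n_scales + 1
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub_mask = np.pad(mask[r0:r1, c0:c1], pad)
    sub_img = np.pad(np.asarray(channel, dtype=float)[r0:r1, c0:c1], pad)
    # fill non-object pixels with their nearest object pixel's value so the
    # openings probe the object's texture, not the mask's silhouette (a
    # constant object then yields an exactly zero spectrum)
    _, (ir, ic) = ndi.distance_transform_edt(~sub_mask, return_indices=True)
    img = sub_img[ir, ic]
    orig_mean = float(img[sub_mask].mean())
    spectrum = np.zeros(n_scales, dtype=float)
    if orig_mean <= 0:
        return spectrum
    prev = img
    prev_mean = orig_mean
    for i in range(1, n_scales + 1):
        opened = ndi.grey_opening(img, footprint=disk(i))
        # digital disks are not perfectly nested; clamp to keep the
        # granulometric family monotone (increments never negative)
        opened = np.minimum(opened, prev)
        cur_mean = float(opened[sub_mask].mean())
        spectrum[i - 1] = 100.0 * (prev_mean - cur_mean) / orig_mean
        prev = opened
        prev_mean = cur_mean
    return spectrum


def radial_distribution(
    channel: np.ndarray, mask: np.ndarray, n_bins: int = 4
) -> dict[str, float]:
    """Radial intensity distribution over concentric rings.

    Pixels are binned by normalized distance d_center / (d_center + d_edge)
    into ``n_bins`` equal-width rings; FracAtD is the fraction of total
    object intensity per ring, MeanFrac divides it by the ring's area
    fraction, and RadialCV is the coefficient of variation of mean
    intensity across 8 angular wedges within the ring.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    rows, cols = np.nonzero(mask)
    vals = np.asarray(channel, dtype=float)[rows, cols]
    cy, cx = rows.mean(), cols.mean()
    d_center = np.hypot(rows - cy, cols - cx)
    edt = ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    d_edge = edt[rows, cols]
    denom = d_center + d_edge
    norm = np.where(denom > 0, d_center / np.maximum(denom, 1e-12), 0.0)
    bins = np.minimum((norm * n_bins).astype(int), n_bins - 1)
    theta = np.arctan2(rows - cy, cols - cx)
    wedges = np.minimum(((theta + math.pi) / (2 * math.pi) * 8).astype(int), 7)
    total_intensity = float(vals.sum())
    n_pix = rows.size
    out: dict[str, float] = {}
    for b in range(n_bins):
        ring = bins == b
        ring_sum = float(vals[ring].sum())
        frac = ring_sum / total_intensity if total_intensity > 0 else 0.0
        area_frac = float(ring.sum()) / n_pix
        mean_frac = frac / area_frac if area_frac > 0 else 0.0
        cv = 0.0
        if ring.any():
            means = [
                float(vals[ring & (wedges == w)].mean())
                for w in range(8)
                if (ring & (wedges == w)).any()
            ]
            m = float(np.mean(means))
            if m > 0 and len(means) > 1:
                cv = float(np.std(means)) / m
        key = f"{b + 1}of{n_bins}"
        out[f"FracAtD_{key}"] = frac
        out[f"MeanFrac_{key}"] = mean_frac
        out[f"RadialCV_{key}"] = cv
    return out


def neighbor_features(mask: np.ndarray, distance: int = 5) -> dict[int, dict[str, float]]:
    """Per-object neighborhood context within a label mask.

    NumberOfNeighbors counts other objects intersecting the object expanded
    by ``distance`` px; PercentTouching is the percentage of the object's
    boundary pixels lying within ``distance`` of another object; closest
    distances are centroid-to-centroid; AngleBetweenNeighbors is subtended
    at the centroid by the two closest neighbors (degrees, 0 with < 2).
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out: dict[int, dict[str, float]] = {}
    if labels.size == 0:
        return out
    centroids = {
        int(lab): np.array(c)
        for lab, c in zip(labels, ndi.center_of_mass(mask > 0, mask, labels))
    }
    se = disk(distance)
    for lab in labels:
        lab = int(lab)
        obj = mask == lab
        grown = ndi.binary_dilation(obj, structure=se)
        neigh = np.unique(mask[grown])
        neigh = [int(v) for v in neigh if v > 0 and v != lab]
        edge = _edge_mask(obj)
        others = (mask > 0) & ~obj
        if others.any() and edge.any():
            d_others = ndi.distance_transform_edt(~others)
            touching = float((d_others[edge] <= distance).mean()) * 100.0
        else:
            touching = 0.0
        c0 = centroids[lab]
        dists = sorted(
            (float(np.hypot(*(centroids[o] - c0))), o) for o in centroids if o != lab
        )
        first = dists[0][0] if len(dists) >= 1 else 0.0
        second = dists[1][0] if len(dists) >= 2 else 0.0
        angle = 0.0
        if len(neigh) >= 2 and len(dists) >= 2:
            u = centroids[dists[0][1]] - c0
            v = centroids[dists[1][1]] - c0
            nu, nv = np.hypot(*u), np.hypot(*v)
            if nu > 0 and nv > 0:
                angle = float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1, 1))))
        out[lab] = {
            "NumberOfNeighbors": float(len(neigh)),
            "PercentTouching": touching,
            "FirstClosestDistance": first,
            "SecondClosestDistance": second,
            "AngleBetweenNeighbors": angle,
        }
    return out


def quantize_intensities(vals: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max quantization to ``levels`` gray levels (constant -> 0)."""
    vals = np.asarray(vals, dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(vals.shape, dtype=int)
    q = ((vals - lo) / (hi - lo) * levels).astype(int)
    return np.minimum(q, levels - 1)


_GLCM_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees


def cooccurrence_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    offset: int,
    direction: tuple[int, int],
    levels: int,
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix for one
    direction; pairs count only when both pixels belong to the object.
    Returns the all-zero matrix when no pair exists."""
    dr, dc = direction[0] * offset, direction[1] * offset
    h, w = mask.shape
    p = np.zeros((levels, levels), dtype=float)
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    m1 = mask[r0s:r0e, c0s:c0e]
    m2 = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    both = m1 & m2
    if not both.any():
        return p
    i = quantized[r0s:r0e, c0s:c0e][both]
    j = quantized[r0s + dr : r0e + dr, c0s + dc : c0e + dc][both]
    np.add.at(p, (i, j), 1.0)
    p = p + p.T
    return p / p.sum()


def _haralick_statistics(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of one normalized symmetric GLCM.

    Logarithms are base 2; any statistic whose definition divides by a zero
    variance (Correlation, InfoMeas1) is defined as 0.
    """
    levels = p.shape[0]
    idx = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = math.sqrt(float(((idx - mu_x) ** 2 * px).sum()))
    sd_y = math.sqrt(float(((idx - mu_y) ** 2 * py).sum()))

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    corr = 0.0
    if sd_x > 0 and sd_y > 0:
        corr = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    mu = mu_x
    variance = float(((ii - mu) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    # sum / difference distributions
    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * levels - 1, dtype=float)
    k_diff = idx
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _entropy(p_sum)
    entropy = _entropy(p.ravel())
    diff_mean = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    diff_ent = _entropy(p_diff)
    hx = _entropy(px)
    hy = _entropy(py)
    pxy = np.outer(px, py)
    valid = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[valid] * np.log2(pxy[valid])).sum())
    pos = pxy > 0
    hxy2 = float(-(pxy[pos] * np.log2(pxy[pos])).sum())
    info1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    info2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return dict(
        zip(
            _HARALICK_NAMES,
            (
                asm,
                contrast,
                corr,
                variance,
                idm,
                sum_avg,
                sum_var,
                sum_ent,
                entropy,
                diff_var,
                diff_ent,
                info1,
                info2,
            ),
        )
    )


def haralick_texture(
    channel: np.ndarray, mask: np.ndarray, levels: int = 8, offset: int = 3
) -> dict[str, float]:
    """The 13 Haralick texture statistics, averaged over 4 directions.

    Intensities inside the object are min-max quantized to ``levels`` gray
    levels; co-occurrence is counted at the given pixel offset along 0, 45,
    90 and 135 degrees (symmetric, normalized per direction).  Directions
    with no in-object pixel pair are skipped from the average; an object
    with no pair in any direction (e.g. a single pixel) yields all zeros.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub_mask = mask[r0:r1, c0:c1]
    sub_vals = np.asarray(channel, dtype=float)[r0:r1, c0:c1]
    q = np.zeros(sub_mask.shape, dtype=int)
    q[sub_mask] = quantize_intensities(sub_vals[sub_mask], levels)
    acc = {name: 0.0 for name in _HARALICK_NAMES}
    n_dir = 0
    for direction in _GLCM_DIRECTIONS:
        p = cooccurrence_matrix(q, sub_mask, offset, direction, levels)
        if p.sum() == 0:
            continue
        stats = _haralick_statistics(p)
        for name in _HARALICK_NAMES:
            acc[name] += stats[name]
        n_dir += 1
    if n_dir == 0:
        return {name: 0.0 for name in _HARALICK_NAMES}
    return {name: acc[name] / n_dir for name in _HARALICK_NAMES}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

_DEGENERATE_COORD = PlateCoordinate("synthetic", "A", 1, 1)


def _compartment_masks(
    cells: np.ndarray, nuclei: np.ndarray, compartments: tuple[str, ...]
) -> dict[str, np.ndarray]:
    masks = {}
    for comp in compartments:
        if comp == "cell":
            masks[comp] = np.asarray(cells)
        elif comp == "nucleus":
            masks[comp] = np.asarray(nuclei)
        elif comp == "cytoplasm":
            masks[comp] = derive_cytoplasm(cells, nuclei)
    return masks


def _object_ids(comp: str, cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Object id universe per compartment: cytoplasm rows exist for every
    cell id even when the cytoplasm is empty (nucleus fills the cell)."""
    base = nuclei if comp == "nucleus" else cells
    ids = np.unique(np.asarray(base))
    return ids[ids > 0]


def extract_all(
    catalog: FeatureCatalog,
    stack: ChannelStack,
    cells: np.ndarray,
    nuclei: np.ndarray,
    coord: PlateCoordinate | None = None,
) -> FeatureTable:
    """Extract the full catalog for every object and compartment.

    Returns one row per (object, compartment); columns are exactly the
    catalog's descriptors in order.  Objects whose compartment is empty
    (e.g. a cell fully covered by its nucleus has no cytoplasm) receive
    all-zero rows rather than missing values, keeping tables rectangular.
    """
    for c in catalog.channels:
        if not stack.has_channel(c):
            raise ValueError(f"catalog channel {c!r} absent from stack")
    if coord is None:
        coord = stack.coord or _DEGENERATE_COORD
    channels = {c: stack.channel(c).astype(float) for c in catalog.channels}
    columns = catalog.columns()
    masks = _compartment_masks(cells, nuclei, catalog.compartments)
    records: list[dict] = []
    for comp in catalog.compartments:
        mask = masks[comp]
        ids = _object_ids(comp, cells, nuclei)
        neigh = (
            neighbor_features(mask, catalog.neighbor_distance)
            if "Neighbors" in catalog.groups
            else {}
        )
        for obj_id in ids:
            obj = mask == obj_id
            row: dict = dict(
                plate=coord.plate_id,
                well=coord.well,
                site=coord.site,
                compartment=comp,
                object_id=int(obj_id),
            )
            if not obj.any():
                row.update({c: 0.0 for c in columns})
                records.append(row)
                continue
            feats: dict[str, float] = {}
            if "AreaShape" in catalog.groups:
                for k, v in areashape_features(obj).items():
                    feats[f"AreaShape_{k}"] = v
                for k, v in zernike_magnitudes(obj, catalog.zernike_degree).items():
                    feats[f"AreaShape_{k}"] = v
            if "Correlation" in catalog.groups:
                ch = catalog.channels
                for i in range(len(ch)):
                    for j in range(i + 1, len(ch)):
                        if int(obj.sum()) >= 2:
                            vals = correlation_features(channels[ch[i]], channels[ch[j]], obj)
                        else:
                            vals = {k: 0.0 for k in _CORRELATION_NAMES}
                        for k, v in vals.items():
                            feats[f"Correlation_{k}_{ch[i]}_{ch[j]}"] = v
            if "Granularity" in catalog.groups:
                for c in catalog.channels:
                    spec = granularity_spectrum(channels[c], obj, catalog.granularity_scales)
                    for s, v in enumerate(spec, start=1):
                        feats[f"Granularity_{s}_{c}"] = float(v)
            if "Intensity" in catalog.groups:
                for c in catalog.channels:
                    for k, v in intensity_features(channels[c], obj).items():
                        feats[f"Intensity_{k}_{c}"] = v
            if "Location" in catalog.groups:
                for k, v in location_features(channels, obj).items():
                    feats[f"Location_{k}"] = v
            if "Neighbors" in catalog.groups:
                for k, v in neigh.get(int(obj_id), {n: 0.0 for n in _NEIGHBOR_NAMES}).items():
                    feats[f"Neighbors_{k}"] = v
            if "RadialDistribution" in catalog.groups:
                for c in catalog.channels:
                    for k, v in radial_distribution(channels[c], obj, catalog.radial_bins).items():
                        stat, ring = k.split("_")
                        feats[f"RadialDistribution_{stat}_{c}_{ring}"] = v
            if "Texture" in catalog.groups:
                for c in catalog.channels:
                    for off in catalog.texture_offsets:
                        for k, v in haralick_texture(
                            channels[c], obj, catalog.texture_levels, off
                        ).items():
                            feats[f"Texture_{k}_{c}_{off}"] = v
            row.update({c: feats[c] for c in columns})
            records.append(row)
    frame = pd.DataFrame(records, columns=list(KEY_COLUMNS) + columns)
    return FeatureTable(frame)
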