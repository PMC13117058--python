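"""Seeded generator of synthetic Cell Painting-like scenes with ground truth.

Each scene contains non-overlapping elliptical cells, each holding one
interior elliptical nucleus (optionally two, for split tests), rendered
into the standard channel layout: DNA bright in nuclei, RNA over cytoplasm
and nucleoli, ER / AGP / Mito as textured cytoplasmic stains and three
edge-weighted brightfield planes, with Poisson shot noise plus additive
Gaussian read noise clipped to the 16-bit range.  Alongside the image the
generator emits exact cell / nucleus label masks, 1-px outline images,
ideal class / border confidence maps and — when merge errors or anucleate
fragments are planted — a clean reference mask, so every pipeline stage can
be tested end to end without any data download.

What the scenes deliberately do not emulate: real staining heterogeneity,
illumination gradients, out-of-focus light and compound-specific
phenotypes.  Passing tests on these scenes validate the algorithmic
behavior of the pipeline, not its biological performance on microscopy
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from paintseg.io_plate import DEFAULT_CHANNELS, ChannelStack, PlateCoordinate
from paintseg.instance_engine import ConfidenceMaps
from paintseg.mask_prep import draw_outlines


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters; the realized object counts are recorded back
    into the returned scene's params when packing fails."""

    size: int = 512
    n_cells: int = 12
    cell_axes: tuple[float, float] = (16.0, 28.0)  # semi-axis range, px
    nucleus_fraction: tuple[float, float] = (0.4, 0.55)
    multi_nucleate_fraction: float = 0.0
    fragment_fraction: float = 0.0
    fragment_axes: tuple[float, float] = (3.0, 5.0)
    noise_sigma: float = 120.0
    shot_noise: bool = True
    confidence_blur: float = 0.0
    margin: int = 6
    gap: int = 3
    max_retries: int = 200
    realized_cells: int | None = None
    realized_fragments: int | None = None

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("scene size must be >= 64")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class SceneTruth:
    """A synthetic scene and its complete ground truth."""

    stack: ChannelStack
    cells: np.ndarray            # as-drawn mask: planted merges are single labels,
                                 # planted fragments are extra labels
    nuclei: np.ndarray
    reference_cells: np.ndarray  # clean truth: merges split, fragments absent
    outlines: dict[str, np.ndarray]
    confidence: dict[str, ConfidenceMaps]
    params: SceneParams
    coord: PlateCoordinate


def _scene_rng(seed: int, coord: PlateCoordinate) -> np.random.Generator:
    """One independent stream per (seed, plate, well, site)."""
    plate_code = sum(ord(c) * 31**i for i, c in enumerate(coord.plate_id)) % (2**31)
    return np.random.default_rng(
        [seed, plate_code, ord(coord.well_row), coord.well_col, coord.site]
    )


def _ellipse_mask(
    size: int, center: tuple[float, float], axes: tuple[float, float], angle: float
) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size].astype(float)
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Band-limited texture field in [0, 1]."""
    raw = rng.normal(size=(size, size))
    sm = ndi.gaussian_filter(raw, sigma)
    lo, hi = sm.min(), sm.max()
    return (sm - lo) / (hi - lo) if hi > lo else np.zeros_like(sm)


def _place_ellipses(rng, params: SceneParams):
    """Rejection-sample non-overlapping cell footprints.

    Returns (cells_parts, fragments): cells_parts is a list whose entries
    are lists of (center, axes, angle) — one entry for plain cells, two for
    planted double (merged) cells; fragments is a list of single ellipses.
    """
    size = params.size
    occupied = np.zeros((size, size), dtype=bool)
    gap_se = np.ones((2 * params.gap + 1,) * 2, dtype=bool)
    n_multi = int(round(params.multi_nucleate_fraction * params.n_cells))
    cells_parts = []
    for i in range(params.n_cells):
        double = i < n_multi
        placed = None
        for _ in range(params.max_retries):
            a = rng.uniform(*params.cell_axes)
            b = rng.uniform(*params.cell_axes)
            angle = rng.uniform(0, np.pi)
            pad = params.margin + max(a, b) + (max(a, b) if double else 0)
            cy = rng.uniform(pad, size - pad)
            cx = rng.uniform(pad, size - pad)
            parts = [((cy, cx), (a, b), angle)]
            if double:
                # congruent second lobe offset along the u axis, overlapping
                # ~40%, far enough that the two nuclei stay disjoint
                off = 1.2 * a
                cy2 = cy + off * np.sin(angle)
                cx2 = cx + off * np.cos(angle)
                parts.append(((cy2, cx2), (a, b), angle))
            mask = np.zeros((size, size), dtype=bool)
            for center, axes, ang in parts:
                mask |= _ellipse_mask(size, center, axes, ang)
            if mask[:1].any() or mask[-1:].any() or mask[:, :1].any() or mask[:, -1:].any():
                continue
            grown = ndi.binary_dilation(mask, structure=gap_se)
            if (grown & occupied).any():
                continue
            occupied |= grown
            placed = parts
            break
        if placed is not None:
            cells_parts.append(placed)
    n_frag = int(round(params.fragment_fraction * params.n_cells))
    fragments = []
    for _ in range(n_frag):
        for _ in range(params.max_retries):
            a = rng.uniform(*params.fragment_axes)
            b = rng.uniform(*params.fragment_axes)
            angle = rng.uniform(0, np.pi)
            pad = params.margin + max(a, b)
            cy = rng.uniform(pad, size - pad)
            cx = rng.uniform(pad, size - pad)
            mask = _ellipse_mask(size, (cy, cx), (a, b), angle)
            if not mask.any():
                continue
            grown = ndi.binary_dilation(mask, structure=gap_se)
            if (grown & occupied).any():
                continue
            occupied |= grown
            fragments.append(((cy, cx), (a, b), angle))
            break
    return cells_parts, fragments


def generate_scene(
    params: SceneParams = SceneParams(),
    seed: int = 0,
    coord: PlateCoordinate | None = None,
) -> SceneTruth:
    """Generate one fully reproducible synthetic scene.

    The same (params, seed, coord) always yields a bit-identical scene.
    When packing fails after bounded retries the scene simply contains
    fewer objects; the realized counts are recorded in the returned
    ``params``.
    """
    if coord is None:
        coord = PlateCoordinate("SYN000001", "A", 1, 5)
    rng = _scene_rng(seed, coord)
    size = params.size
    cells_parts, fragments = _place_ellipses(rng, params)

    cells = np.zeros((size, size), dtype=np.int32)
    reference = np.zeros((size, size), dtype=np.int32)
    nuclei = np.zeros((size, size), dtype=np.int32)
    nucleolus_seeds: list[tuple[float, float]] = []
    next_ref = 1
    next_nuc = 1
    for lab, parts in enumerate(cells_parts, start=1):
        part_masks = [_ellipse_mask(size, c, ax, an) for c, ax, an in parts]
        union = np.logical_or.reduce(part_masks)
        cells[union & (cells == 0)] = lab
        if len(parts) == 1:
            reference[part_masks[0] & (reference == 0)] = next_ref
            next_ref += 1
        else:
            # overlap pixels go to the nearer lobe center
            centers = np.array([c for c, _, _ in parts])
            yy, xx = np.nonzero(union)
            d2 = (yy[:, None] - centers[None, :, 0]) ** 2 + (
                xx[:, None] - centers[None, :, 1]
            ) ** 2
            owner = np.argmin(d2, axis=1)
            for k in range(len(parts)):
                sel = owner == k
                free = reference[yy[sel], xx[sel]] == 0
                reference[yy[sel][free], xx[sel][free]] = next_ref
                next_ref += 1
        for (cy, cx), (a, b), angle in parts:
            f = rng.uniform(*params.nucleus_fraction)
            nuc = _ellipse_mask(size, (cy, cx), (a * f, b * f), angle)
            nuclei[nuc & (nuclei == 0) & (cells == lab)] = next_nuc
            next_nuc += 1
            nucleolus_seeds.append((cy, cx))
    n_real_frag = 0
    for (cy, cx), (a, b), angle in fragments:
        frag = _ellipse_mask(size, (cy, cx), (a, b), angle)
        frag &= cells == 0
        if frag.any():
            cells[frag] = int(cells.max()) + 1
            n_real_frag += 1

    cell_fg = cells > 0
    nuc_fg = nuclei > 0
    cyto = cell_fg & ~nuc_fg

    tex = {name: _smooth_noise(rng, size, 3.0) for name in ("ER", "AGP", "Mito")}
    signal = {}
    signal["DNA"] = 200.0 + np.where(nuc_fg, 28000.0 + 6000.0 * _smooth_noise(rng, size, 2.0), 0.0)
    signal["RNA"] = (
        300.0
        + np.where(cyto, 11000.0, 0.0)
        + np.where(nuc_fg, 17000.0 + 5000.0 * _smooth_noise(rng, size, 1.5), 0.0)
    )
    for name in ("ER", "AGP", "Mito"):
        signal[name] = (
            250.0
            + np.where(cyto, 7000.0 + 6000.0 * tex[name], 0.0)
            + np.where(nuc_fg, 1500.0, 0.0)
        )
    edges = ndi.gaussian_filter(
        np.hypot(*np.gradient(ndi.gaussian_filter(cell_fg.astype(float), 1.5))), 1.0
    )
    emax = edges.max()
    edge_term = edges / emax if emax > 0 else edges
    for i, name in enumerate(("BF1", "BF2", "BF3"), start=1):
        signal[name] = 18000.0 + 14000.0 * edge_term + 800.0 * i

    planes = []
    for name in DEFAULT_CHANNELS:
        s = np.clip(signal[name], 0, None)
        noisy = rng.poisson(s).astype(float) if params.shot_noise else s.copy()
        if params.noise_sigma > 0:
            noisy += rng.normal(0.0, params.noise_sigma, size=(size, size))
        planes.append(np.clip(noisy, 0, 65535).astype(np.uint16))
    stack = ChannelStack(np.stack(planes, axis=-1), DEFAULT_CHANNELS, coord)

    outlines = {"cell": draw_outlines(cells), "nucleus": draw_outlines(nuclei)}
    confidence = {}
    for name, mask in (("cell", cells), ("nucleus", nuclei)):
        class_map = (mask > 0).astype(float)
        border_map = (draw_outlines(mask) > 0).astype(float)
        if params.confidence_blur > 0:
            class_map = np.clip(ndi.gaussian_filter(class_map, params.confidence_blur), 0, 1)
            border_map = ndi.gaussian_filter(border_map, params.confidence_blur)
            bmax = border_map.max()
            if bmax > 0:
                border_map = border_map / bmax
        confidence[name] = ConfidenceMaps(class_map, border_map)

    realized = replace(
        params, realized_cells=len(cells_parts), realized_fragments=n_real_frag
    )
    return SceneTruth(
        stack=stack,
        cells=cells,
        nuclei=nuclei,
        reference_cells=reference,
        outlines=outlines,
        confidence=confidence,
        params=realized,
        coord=coord,
    )


ORACLE_FEATURES = (
    "Area",
    "IntegratedIntensity",
    "MeanIntensity",
    "MaxIntensity",
    "Centroid",
    "PearsonCorrelation",
)


def oracle_features(
    scene: SceneTruth,
    subset: tuple[str, ...] = ORACLE_FEATURES,
    compartment: str = "cell",
    channel: str = "DNA",
    channel_b: str = "RNA",
):
    """Naive per-pixel-loop oracle for a small feature subset.

    Deliberately shares no code with :mod:`paintseg.features`: every value
    is accumulated in explicit Python loops over the object's pixels.
    Returns a plain dict ``{object_id: {feature: value}}``; ``Centroid``
    expands to ``Centroid_X`` / ``Centroid_Y``, ``PearsonCorrelation`` is
    computed between ``channel`` and ``channel_b``.
    """
    unknown = set(subset) - set(ORACLE_FEATURES)
    if unknown:
        raise ValueError(f"unsupported oracle feature(s): {sorted(unknown)}")
    mask = {"cell": scene.cells, "nucleus": scene.nuclei}[compartment]
    img = scene.stack.channel(channel)
    img_b = scene.stack.channel(channel_b)
    out: dict[int, dict[str, float]] = {}
    labels = sorted(int(v) for v in np.unique(mask) if v > 0)
    for lab in labels:
        rows, cols = np.nonzero(mask == lab)
        n = 0
        total = 0
        vmax = None
        sum_r = 0
        sum_c = 0
        vals_a = []
        vals_b = []
        for r, c in zip(rows.tolist(), cols.tolist()):
            v = int(img[r, c])
            n += 1
            total += v
            vmax = v if vmax is None or v > vmax else vmax
            sum_r += r
            sum_c += c
            vals_a.append(float(v))
            vals_b.append(float(img_b[r, c]))
        feats: dict[str, float] = {}
        if "Area" in subset:
            feats["Area"] = float(n)
        if "IntegratedIntensity" in subset:
            feats["IntegratedIntensity"] = float(total)
        if "MeanIntensity" in subset:
            feats["MeanIntensity"] = total / n
        if "MaxIntensity" in subset:
            feats["MaxIntensity"] = float(vmax)
        if "Centroid" in subset:
            feats["Centroid_X"] = sum_c / n
            feats["Centroid_Y"] = sum_r / n
        if "PearsonCorrelation" in subset:
            ma = sum(vals_a) / n
            mb = sum(vals_b) / n
            sab = sum((x - ma) * (y - mb) for x, y in zip(vals_a, vals_b))
            saa = sum((x - ma) ** 2 for x in vals_a)
            sbb = sum((y - mb) ** 2 for y in vals_b)
            if saa > 0 and sbb > 0:
                feats["PearsonCorrelation"] = sab / (saa * sbb) ** 0.5
            else:
                feats["PearsonCorrelation"] = 0.0
        out[lab] = feats
    return out
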