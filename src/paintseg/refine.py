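"""Nucleus-guided refinement of cell instance masks.

Two post-processing algorithms correct the dominant failure modes of
confidence-map cell segmentation, assuming predominantly mononuclear cells:

* **Splitting multi-nucleated cells** — a cell instance containing two or
  more nucleus centroids is partitioned by assigning each of its pixels to
  the nearest owned nucleus centroid (Euclidean distance).
* **Merging or removing anucleate fragments** — a cell with no nucleus
  centroid and area below a threshold is either deleted (when isolated) or
  merged into the neighboring cell with the weakest border evidence along
  the shared interface (low border confidence means the two regions likely
  belong to one object).

Compartment derivation (cytoplasm = cell minus nucleus) also lives here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

#: Fallback fragment-area threshold when an image has no nucleated cell.
FALLBACK_MIN_AREA = 100
#: Fraction of the median nucleated-cell area used as the default fragment
#: threshold.
DEFAULT_MIN_AREA_FRACTION = 0.4

_EIGHT = np.ones((3, 3), dtype=bool)


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")


def nucleus_centroids(nuclei: np.ndarray) -> dict[int, tuple[int, int]]:
    """Rounded centroid pixel (row, col) of every nucleus label."""
    nuclei = np.asarray(nuclei)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    centers = ndi.center_of_mass(nuclei > 0, nuclei, labels)
    out = {}
    h, w = nuclei.shape
    for lab, (r, c) in zip(labels, centers):
        # floor(x + 0.5): deterministic half-up rounding
        rr = min(h - 1, max(0, int(np.floor(r + 0.5))))
        cc = min(w - 1, max(0, int(np.floor(c + 0.5))))
        out[int(lab)] = (rr, cc)
    return out


def _centroids_per_cell(cells: np.ndarray, nuclei: np.ndarray) -> dict[int, list[tuple[int, tuple[int, int]]]]:
    """Map cell label -> [(nucleus label, centroid pixel), ...], sorted by
    nucleus label.  A nucleus belongs to the cell its rounded centroid
    pixel lies in; centroids on background belong to no cell."""
    owners: dict[int, list[tuple[int, tuple[int, int]]]] = {}
    for nuc_lab, (r, c) in sorted(nucleus_centroids(nuclei).items()):
        cell_lab = int(cells[r, c])
        if cell_lab > 0:
            owners.setdefault(cell_lab, []).append((nuc_lab, (r, c)))
    return owners


def split_multinucleated(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Split every cell containing two or more nucleus centroids.

    Each pixel of a multi-nucleated cell is assigned to the nearest owned
    centroid (Euclidean distance, ties to the lower nucleus label).  The
    resulting parts receive fresh labels above the current maximum; cells
    with at most one centroid, and the nuclei mask, are untouched.  For
    concave cells the nearest-centroid rule can yield geometrically
    disconnected parts; these are kept as one label.
    """
    cells = np.asarray(cells).astype(np.int32)
    nuclei = np.asarray(nuclei)
    _check_shapes(cells, nuclei)
    owners = _centroids_per_cell(cells, nuclei)
    out = cells.copy()
    next_label = int(cells.max()) + 1
    for cell_lab in sorted(owners):
        entries = owners[cell_lab]
        if len(entries) < 2:
            continue
        rows, cols = np.nonzero(cells == cell_lab)
        pts = np.stack([rows, cols], axis=1).astype(float)
        # centroids in ascending nucleus-label order; argmin takes the first
        # (lowest-label) centroid on exact distance ties
        cents = np.array([c for _, c in entries], dtype=float)
        d2 = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        for k in range(len(entries)):
            sel = assign == k
            out[rows[sel], cols[sel]] = next_label
            next_label += 1
    return out


def default_min_area(
    cells: np.ndarray,
    nuclei: np.ndarray,
    fraction: float = DEFAULT_MIN_AREA_FRACTION,
) -> float:
    """Fragment-area threshold: ``fraction`` of the median nucleated-cell
    area in the image (fallback 100 px when no nucleated cell exists)."""
    cells = np.asarray(cells)
    owners = _centroids_per_cell(cells, np.asarray(nuclei))
    areas = [int(np.count_nonzero(cells == lab)) for lab, ent in owners.items() if ent]
    if not areas:
        return float(FALLBACK_MIN_AREA)
    return fraction * float(np.median(areas))


def _interface(fragment: np.ndarray, neighbor: np.ndarray) -> np.ndarray:
    """Pixels on the shared interface between two disjoint regions: pixels
    of either region 8-adjacent to the other."""
    near_frag = ndi.binary_dilation(fragment, structure=_EIGHT)
    near_neigh = ndi.binary_dilation(neighbor, structure=_EIGHT)
    return (fragment & near_neigh) | (neighbor & near_frag)


def merge_or_remove_fragments(
    cells: np.ndarray,
    nuclei: np.ndarray,
    cell_border_map: np.ndarray,
    min_area: float | None = None,
) -> np.ndarray:
    """Remove or merge small anucleate cell fragments.

    A *fragment* is a cell with no owned nucleus centroid and area below
    ``min_area`` (default: :func:`default_min_area`).  An isolated fragment
    (no 8-connected neighboring cell) is noise and is deleted; otherwise the
    fragment is merged into the neighboring cell minimizing the mean border
    confidence over the shared interface (ties: longest interface, then
    lower label).  Fragments are processed in ascending label order against
    the evolving mask; passes repeat until no fragment remains, so the
    result is a fixpoint (idempotent) and contains no anucleate cell below
    ``min_area``.
    """
    cells = np.asarray(cells).astype(np.int32)
    nuclei = np.asarray(nuclei)
    cell_border_map = np.asarray(cell_border_map, dtype=float)
    _check_shapes(cells, nuclei, cell_border_map)
    if min_area is None:
        min_area = default_min_area(cells, nuclei)
    if min_area <= 0:
        raise ValueError(f"min_area must be positive, got {min_area}")

    out = cells.copy()
    for _ in range(int(cells.max()) + 1):  # bounded; each pass removes >= 1 fragment
        owners = _centroids_per_cell(out, nuclei)
        labels = np.unique(out)
        labels = labels[labels > 0]
        fragments = [
            int(lab)
            for lab in labels
            if not owners.get(int(lab)) and np.count_nonzero(out == lab) < min_area
        ]
        if not fragments:
            break
        changed = False
        for frag_lab in fragments:
            frag = out == frag_lab
            # re-check against the evolving mask: the fragment may have been
            # merged away, or grown past the threshold by absorbing others
            if not frag.any() or np.count_nonzero(frag) >= min_area:
                continue
            grown = ndi.binary_dilation(frag, structure=_EIGHT)
            neigh_labels = np.unique(out[grown & ~frag])
            neigh_labels = [int(v) for v in neigh_labels if v > 0 and v != frag_lab]
            if not neigh_labels:
                out[frag] = 0
                changed = True
                continue
            best = None
            for nl in sorted(neigh_labels):
                iface = _interface(frag, out == nl)
                size = int(iface.sum())
                mean_conf = float(cell_border_map[iface].mean()) if size else np.inf
                key = (mean_conf, -size, nl)
                if best is None or key < best[0]:
                    best = (key, nl)
            out[frag] = best[1]
            changed = True
        if not changed:
            break
    return out


def derive_cytoplasm(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Cytoplasm compartment: cell pixels not covered by nucleus foreground.

    Labels are copied from the cell mask, so cytoplasm object ids align
    with cell object ids; a cell fully covered by its nucleus yields an
    empty cytoplasm.  Per object, area(cell) = area(nucleus ∩ cell) +
    area(cytoplasm) by construction.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    _check_shapes(cells, nuclei)
    return np.where(nuclei > 0, 0, cells).astype(np.int32)
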