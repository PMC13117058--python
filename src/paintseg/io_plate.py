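"""Plate-aware I/O: naming convention, image stacks, feature tables, manifests.

The canonical image identifier is ``"<plate>-<well><site>"`` in the form
``"BR00116991-A02-5"``: plate id, a well on a 384-well plate (rows A-P,
columns 1-24), and a field-of-view (site) index.  All on-disk artifacts of
the pipeline are keyed by this coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Default channel order: five fluorescent stains followed by three
#: brightfield planes.  DNA marks nuclei, RNA (nucleoli + cytoplasmic RNA)
#: marks whole cells, ER / AGP / Mito are textured cytoplasmic stains.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "DNA", "ER", "RNA", "AGP", "Mito", "BF1", "BF2", "BF3",
)

#: Well counts per category of the standard compound-plate subset: 28 hit
#: wells, 19 phenotypically diverse non-hits, 10 positive and 64 negative
#: controls — 121 wells per plate.
DEFAULT_WELL_CATEGORIES: dict[str, int] = {
    "hit": 28,
    "diverse_nonhit": 19,
    "positive_control": 10,
    "negative_control": 64,
}

_ROWS = "ABCDEFGHIJKLMNOP"
_NAME_RE = re.compile(r"^(?P<plate>.+)-(?P<row>[A-P])(?P<col>\d{1,2})-(?P<site>\d+)$")

#: Key columns identifying one object row in a feature table.
KEY_COLUMNS = ("plate", "well", "site", "compartment", "object_id")

COMPARTMENTS = ("cell", "nucleus", "cytoplasm")


class PlateIOError(ValueError):
    """Raised for malformed names, missing channel files or bad tables."""


@dataclass(frozen=True, order=True)
class PlateCoordinate:
    """A (plate, well, site) address on a 384-well plate."""

    plate_id: str
    well_row: str
    well_col: int
    site: int

    def __post_init__(self) -> None:
        if not self.plate_id:
            raise PlateIOError("empty plate id")
        if self.well_row not in _ROWS:
            raise PlateIOError(f"well row {self.well_row!r} outside A-P")
        if not 1 <= self.well_col <= 24:
            raise PlateIOError(f"well column {self.well_col} outside 1-24")
        if self.site < 1:
            raise PlateIOError(f"site {self.site} must be >= 1")

    @property
    def well(self) -> str:
        """Zero-padded well name, e.g. ``"A02"``."""
        return f"{self.well_row}{self.well_col:02d}"

    @property
    def image_name(self) -> str:
        """Canonical fused name, e.g. ``"BR00116991-A02-5"``."""
        return f"{self.plate_id}-{self.well}-{self.site}"

    def __str__(self) -> str:
        return self.image_name


def parse_image_name(name: str) -> PlateCoordinate:
    """Parse a fused ``"PLATE-RowCol-Site"`` image name.

    Accepts 1- or 2-digit column numbers; the canonical form emitted by
    :attr:`PlateCoordinate.image_name` is always zero-padded to two digits.

    >>> parse_image_name("BR00116991-A02-5")
    PlateCoordinate(plate_id='BR00116991', well_row='A', well_col=2, site=5)
    """
    if not name:
        raise PlateIOError("empty image name")
    m = _NAME_RE.match(name)
    if m is None:
        raise PlateIOError(
            f"malformed image name {name!r}: expected '<plate>-<RowCol>-<site>' "
            "with row A-P, column 1-24 and a positive site index"
        )
    col = int(m.group("col"))
    site = int(m.group("site"))
    try:
        return PlateCoordinate(m.group("plate"), m.group("row"), col, site)
    except PlateIOError as exc:
        raise PlateIOError(f"malformed image name {name!r}: {exc}") from exc


@dataclass
class ChannelStack:
    """Ordered multi-channel intensity image (H, W, C), 16-bit range."""

    pixels: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    coord: PlateCoordinate | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise PlateIOError(f"pixels must be H x W x C, got shape {self.pixels.shape}")
        if self.pixels.shape[2] != len(self.channel_names):
            raise PlateIOError(
                f"{self.pixels.shape[2]} planes but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise PlateIOError("channel names must be unique")
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.min(initial=0) < 0 or self.pixels.max(initial=0) > 65535:
                raise PlateIOError("intensities outside the 16-bit range [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one 2-D channel plane by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise PlateIOError(
                f"channel {name!r} not in stack (have {list(self.channel_names)})"
            ) from None
        return self.pixels[:, :, idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def read_channel_stack(
    channel_paths: Mapping[str, str | Path],
    coord: PlateCoordinate | None = None,
) -> ChannelStack:
    """Read one grayscale TIFF per channel into a stack.

    ``channel_paths`` maps channel name to the file holding that plane; the
    mapping order defines the stack's channel order.  All planes must share
    one shape and be 8- or 16-bit single-channel images; intensities are
    preserved bit-exactly.
    """
    if not channel_paths:
        raise PlateIOError("no channels configured")
    missing = [n for n, p in channel_paths.items() if not Path(p).is_file()]
    if missing:
        raise PlateIOError(f"missing channel file(s) for: {', '.join(missing)}")
    planes = []
    shape = None
    for name, path in channel_paths.items():
        arr = tifffile.imread(str(path))
        if arr.ndim != 2:
            raise PlateIOError(f"channel {name!r} ({path}) is not single-channel grayscale")
        if arr.dtype not in (np.uint8, np.uint16):
            raise PlateIOError(f"channel {name!r} ({path}) is not 8- or 16-bit: {arr.dtype}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise PlateIOError(
                f"channel {name!r} shape {arr.shape} differs from {shape}"
            )
        planes.append(arr.astype(np.uint16))
    return ChannelStack(np.stack(planes, axis=-1), tuple(channel_paths), coord)


def write_channel_stack(stack: ChannelStack, directory: str | Path,
                        prefix: str | None = None) -> dict[str, Path]:
    """Write each channel as ``<prefix>-<channel>.tiff``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if prefix is None:
        prefix = stack.coord.image_name if stack.coord is not None else "stack"
    out: dict[str, Path] = {}
    for name in stack.channel_names:
        path = directory / f"{prefix}-{name}.tiff"
        tifffile.imwrite(str(path), stack.channel(name).astype(np.uint16))
        out[name] = path
    return out


@dataclass
class FeatureTable:
    """Per-object, per-compartment feature matrix.

    Backed by a :class:`pandas.DataFrame` whose first five columns are the
    object key (plate, well, site, compartment, object_id) followed by the
    feature columns in catalog order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise PlateIOError(f"feature table missing key column(s): {missing}")
        # canonical column order: keys first, features after in given order
        feats = [c for c in self.frame.columns if c not in KEY_COLUMNS]
        self.frame = self.frame[list(KEY_COLUMNS) + feats].reset_index(drop=True)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in KEY_COLUMNS]

    @property
    def n_objects(self) -> int:
        return len(self.frame)

    def values(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def keyed(self) -> pd.DataFrame:
        """Frame indexed by the object key, for alignment between tables."""
        return self.frame.set_index(list(KEY_COLUMNS))


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Persist a feature table as CSV (shortest-repr floats, lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV; non-numeric feature cells are an error."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PlateIOError(f"cannot read feature table {path}: {exc}") from exc
    missing = [c for c in KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateIOError(f"{path}: missing key column(s) {missing}")
    feats = [c for c in frame.columns if c not in KEY_COLUMNS]
    for col in feats:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PlateIOError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        frame[col] = coerced
    return FeatureTable(frame)


@dataclass
class SubsetManifest:
    """List of (coordinate, well category) entries defining a dataset subset."""

    entries: list[tuple[PlateCoordinate, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for coord, _cat in self.entries:
            key = (coord.plate_id, coord.well, coord.site)
            if key in seen:
                raise PlateIOError(f"duplicate manifest entry {coord}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate": c.plate_id,
                    "well": c.well,
                    "site": c.site,
                    "category": cat,
                }
                for c, cat in self.entries
            ],
            columns=["plate", "well", "site", "category"],
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SubsetManifest":
        frame = pd.read_csv(path, dtype={"plate": str, "well": str})
        entries = []
        for _, row in frame.iterrows():
            well = str(row["well"])
            entries.append(
                (
                    PlateCoordinate(str(row["plate"]), well[0], int(well[1:]), int(row["site"])),
                    str(row["category"]),
                )
            )
        return cls(entries)


def _well_sequence() -> list[tuple[str, int]]:
    """All 384 wells in row-major order A01, A02, ..., P24."""
    return [(r, c) for r in _ROWS for c in range(1, 25)]


def build_subset_manifest(
    plate_ids: Sequence[str],
    wells_per_category: Mapping[str, int] | None = None,
    site: int = 5,
) -> SubsetManifest:
    """Build the standard subset manifest: the same wells on every plate.

    Wells are assigned category-by-category in row-major plate order, one
    entry per (plate, well) at the given site (default 5, the central field
    of a 3 x 3 acquisition grid).  With the default categories this yields
    121 wells per plate.
    """
    if wells_per_category is None:
        wells_per_category = DEFAULT_WELL_CATEGORIES
    counts = {k: int(v) for k, v in wells_per_category.items()}
    if any(v < 0 for v in counts.values()):
        raise PlateIOError("negative well count")
    total = sum(counts.values())
    if total > 384:
        raise PlateIOError(f"{total} wells exceed the 384-well plate capacity")
    wells = _well_sequence()
    assignment: list[tuple[str, int, str]] = []
    pos = 0
    for cat, n in counts.items():
        for _ in range(n):
            row, col = wells[pos]
            assignment.append((row, col, cat))
            pos += 1
    entries = [
        (PlateCoordinate(plate, row, col, site), cat)
        for plate in plate_ids
        for row, col, cat in assignment
    ]
    return SubsetManifest(entries)
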