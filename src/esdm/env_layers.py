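"""Environmental covariate rasters on a single common grid.

Grid convention: row-major arrays, origin at the top-left *corner* of the
grid, rows increase southward, coordinates refer to cell centers, and
point-to-cell mapping uses half-open intervals ``[edge, edge + cell_size)``.
Missing cells are carried internally as NaN regardless of the on-disk
nodata sentinel.

Raster I/O is single-band GeoTIFF via :mod:`tifffile` with the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags, so files interoperate
with mainstream GIS readers without a GDAL dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from esdm.errors import ContractError, CoverageError, FormatError

Kind = Literal["continuous", "categorical"]

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid with square cells."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    crs_tag: str = ""
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ContractError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ContractError("cell_size must be positive")

    def aligned_with(self, other: "GridSpec") -> bool:
        """True iff all geometric fields match; crs_tag is ignored."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.cell_size == other.cell_size
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.nodata_value == other.nodata_value
        )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """Map coordinates of cell centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x, y):
        """(row, col) of the half-open cell containing each point.

        Points outside the grid get indices outside [0, n_rows) / [0, n_cols).
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def flat_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)


@dataclass
class Layer:
    """A single named raster band on a :class:`GridSpec`.

    ``values`` is float64 with NaN marking nodata. Categorical layers hold
    integer codes (stored as floats) at valid cells.
    """

    name: str
    kind: Kind
    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ContractError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match grid ({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ContractError(f"unknown layer kind {self.kind!r}")
        valid = self.valid_mask
        if self.kind == "categorical":
            codes = self.values[valid]
            if codes.size and not np.allclose(codes, np.round(codes)):
                raise ContractError(
                    f"categorical layer {self.name!r} has non-integer codes"
                )
        else:
            if not np.all(np.isfinite(self.values[valid])):
                raise ContractError(
                    f"continuous layer {self.name!r} has non-finite valid cells"
                )

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "Layer":
        return Layer(self.name, self.kind, values, self.grid)


@dataclass
class EnvStack:
    """Ordered collection of aligned layers sharing one grid."""

    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ContractError("stack must contain at least one layer")
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ContractError(f"duplicate layer names in stack: {names}")
        grid = self.layers[0].grid
        for lyr in self.layers[1:]:
            if not lyr.grid.aligned_with(grid):
                raise ContractError(f"layer {lyr.name!r} is not aligned with the stack")

    @property
    def grid(self) -> GridSpec:
        return self.layers[0].grid

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cell valid iff no layer is nodata there."""
        mask = np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for lyr in self.layers:
            mask &= lyr.valid_mask
        return mask

    def __getitem__(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(lyr.name == name for lyr in self.layers)

    def subset(self, names: Sequence[str]) -> "EnvStack":
        """New stack restricted to ``names``, preserving their order."""
        return EnvStack([self[n] for n in names])


# ---------------------------------------------------------------------------
# Raster I/O


def write_raster(layer: Layer, path) -> None:
    """Write a layer as a single-band GeoTIFF.

    Continuous layers go out as float32 with NaN replaced by the grid's
    nodata sentinel; categorical layers as int32.
    """
    grid = layer.grid
    nodata = grid.nodata_value
    vals = layer.values.copy()
    vals[np.isnan(vals)] = nodata
    if layer.kind == "categorical":
        data = vals.astype(np.int32)
        nodata_text = str(int(nodata))
    else:
        data = vals.astype(np.float32)
        nodata_text = repr(float(nodata))
    meta = json.dumps(
        {"name": layer.name, "kind": layer.kind, "crs_tag": grid.crs_tag}
    )
    cs = float(grid.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, nodata_text),
    ]
    if grid.crs_tag:
        extratags.append((_TAG_GEO_ASCII, "s", 0, grid.crs_tag))
    tifffile.imwrite(
        path, data, description=meta, extratags=extratags, photometric="minisblack"
    )


def read_raster(path) -> Layer:
    """Read a single-band GeoTIFF into a :class:`Layer`.

    Raises :class:`FormatError` for unreadable, multi-band, or
    non-square-cell files. Cells equal to the nodata tag become NaN.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise FormatError(f"{path}: expected a single-band raster")
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise FormatError(f"{path}: expected one sample per pixel")
            data = page.asarray()
            tags = {}
            for tag in page.tags.values():
                # keep the first occurrence; tifffile appends its own
                # shape metadata as a second ImageDescription tag
                tags.setdefault(tag.code, tag.value)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise FormatError(f"could not read raster {path}: {exc}") from exc

    if data.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D single-band raster")

    scale = tags.get(_TAG_PIXEL_SCALE)
    tiepoint = tags.get(_TAG_TIEPOINT)
    if scale is None or tiepoint is None:
        raise FormatError(f"{path}: missing georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy):
        raise FormatError(f"{path}: non-square cells ({sx} x {sy})")
    origin_x = float(tiepoint[3]) - float(tiepoint[0]) * sx
    origin_y = float(tiepoint[4]) + float(tiepoint[1]) * sy

    nodata = tags.get(_TAG_GDAL_NODATA)
    nodata_value = float(str(nodata)) if nodata is not None else -9999.0

    name = "band1"
    kind: Kind = "categorical" if np.issubdtype(data.dtype, np.integer) else "continuous"
    crs_tag = str(tags.get(_TAG_GEO_ASCII, "") or "")
    desc = tags.get(270)  # ImageDescription
    if desc:
        try:
            meta = json.loads(desc)
            name = meta.get("name", name)
            kind = meta.get("kind", kind)
            crs_tag = meta.get("crs_tag", crs_tag)
        except (json.JSONDecodeError, TypeError):
            pass

    grid = GridSpec(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size=sx,
        origin_x=origin_x,
        origin_y=origin_y,
        crs_tag=crs_tag,
        nodata_value=nodata_value,
    )
    values = np.asarray(data, dtype=float)
    values[values == nodata_value] = np.nan
    return Layer(name=name, kind=kind, values=values, grid=grid)


# ---------------------------------------------------------------------------
# Alignment / resampling


def align_stack(
    layers: Iterable[Layer],
    target: GridSpec,
    method: Literal["nearest", "bilinear"] = "nearest",
) -> EnvStack:
    """Resample layers onto ``target`` and stack them.

    ``nearest`` assigns each target cell center the value of the source
    cell containing it (half-open convention); ``bilinear`` interpolates
    between the four surrounding source cell centers and is only valid for
    continuous layers.
    """
    if method not in ("nearest", "bilinear"):
        raise ContractError(f"unknown resampling method {method!r}")
    out = []
    for lyr in layers:
        if method == "bilinear" and lyr.kind == "categorical":
            raise ContractError(
                f"categorical layer {lyr.name!r} requires nearest resampling"
            )
        if lyr.grid.aligned_with(target):
            out.append(Layer(lyr.name, lyr.kind, lyr.values.copy(), target))
            continue
        out.append(_resample(lyr, target, method))
    return EnvStack(out)


def _resample(layer: Layer, target: GridSpec, method: str) -> Layer:
    src = layer.grid
    rows, cols = np.meshgrid(
        np.arange(target.n_rows), np.arange(target.n_cols), indexing="ij"
    )
    x, y = target.cell_center(rows, cols)

    src_xmax = src.origin_x + src.n_cols * src.cell_size
    src_ymin = src.origin_y - src.n_rows * src.cell_size
    if (
        x.min() < src.origin_x
        or x.max() >= src_xmax
        or y.max() > src.origin_y
        or y.min() <= src_ymin
    ):
        raise CoverageError(
            f"layer {layer.name!r} does not cover the target grid extent"
        )

    if method == "nearest":
        r, c = src.point_to_cell(x, y)
        values = layer.values[r, c]
    else:
        # fractional source cell-center coordinates
        u = (src.origin_y - y) / src.cell_size - 0.5
        v = (x - src.origin_x) / src.cell_size - 0.5
        u = np.clip(u, 0, src.n_rows - 1)
        v = np.clip(v, 0, src.n_cols - 1)
        values = ndimage.map_coordinates(
            layer.values, [u, v], order=1, mode="nearest"
        )
    return Layer(layer.name, layer.kind, values, target)


# ---------------------------------------------------------------------------
# Terrain derivatives (Horn's 8-neighbor finite differences)


def _horn_gradients(dem: Layer) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward) with edge-replicated borders."""
    if dem.kind != "continuous":
        raise ContractError("terrain derivatives require a continuous elevation layer")
    z = np.pad(dem.values, 1, mode="edge")
    cs = dem.grid.cell_size
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    # rows increase southward, so the northward gradient is top minus bottom
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)
    return dzdx, dzdy


def compute_slope(dem: Layer, units: str = "degrees") -> Layer:
    """Slope raster in degrees from Horn's 3x3 kernel.

    Output is in [0, 90); NaN cells in the DEM propagate to the output.
    """
    if units != "degrees":
        raise ContractError("only degree output is supported")
    dzdx, dzdy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~dem.valid_mask] = np.nan
    return Layer("slope", "continuous", slope, dem.grid)


def compute_aspect(dem: Layer) -> Layer:
    """Aspect of the downslope direction, degrees clockwise from north.

    Flat cells are flagged with the sentinel -1.
    """
    dzdx, dzdy = _horn_gradients(dem)
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = -1.0
    aspect[~dem.valid_mask] = np.nan
    return Layer("aspect", "continuous", aspect, dem.grid)


# ---------------------------------------------------------------------------
# Distance to features


def distance_to_features(grid: GridSpec, feature_cells) -> Layer:
    """Exact Euclidean distance (map units) from every cell center to the
    nearest feature cell center.

    ``feature_cells`` is an iterable of (row, col) pairs or flat indices.
    """
    cells = list(feature_cells)
    if not cells:
        raise ContractError("feature set must be non-empty")
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for cell in cells:
        if np.isscalar(cell) or isinstance(cell, (int, np.integer)):
            r, c = divmod(int(cell), grid.n_cols)
        else:
            r, c = int(cell[0]), int(cell[1])
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            raise ContractError(f"feature cell ({r}, {c}) outside grid")
        mask[r, c] = True
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.cell_size)
    return Layer("distance", "continuous", dist.astype(float), grid)


def rasterize_segments(grid: GridSpec, segments: Iterable[Sequence[float]]) -> set:
    """Cells traversed by line segments ``(x1, y1, x2, y2)``.

    Endpoints are snapped to containing cells and connected by Bresenham
    traversal; segments entirely off-grid contribute nothing.
    """
    cells: set[tuple[int, int]] = set()
    for x1, y1, x2, y2 in segments:
        r1, c1 = (int(v) for v in grid.point_to_cell(x1, y1))
        r2, c2 = (int(v) for v in grid.point_to_cell(x2, y2))
        for r, c in _bresenham(r1, c1, r2, c2):
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                cells.add((r, c))
    return cells


def _bresenham(r0: int, c0: int, r1: int, c1: int):
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        yield r, c
        if r == r1 and c == c1:
            return
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr


def layer_like(grid: GridSpec, name: str, values: np.ndarray) -> Layer:
    """Convenience constructor for a continuous layer on ``grid``."""
    return Layer(name, "continuous", values, grid)


def copy_grid(grid: GridSpec, **changes) -> GridSpec:
    return replace(grid, **changes)
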