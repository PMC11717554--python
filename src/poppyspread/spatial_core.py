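"""Grid, raster and vector primitives shared by every analysis stage.

All coordinates are planar projected metres (UTM-like); there is no geodesy
anywhere in the package. Rasters are row-major with 0-based indices; the
cell centre of (row 0, col 0) sits at ``origin + cell_size/2`` on both axes,
so row index increases northward and column index eastward. Cell extents
are half-open: a point exactly on a boundary belongs to the higher-index
cell. Cell membership of points and polylines is decided by cell centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import LineString, MultiLineString, Point, mapping, shape

PLOT_CLASSES = ("trail", "off_trail", "unsystematic", "systematic_grid")

#: Width (m) of a trail plot; default band width for rasterize_trail.
DEFAULT_TRAIL_WIDTH = 2.0

# GeoTIFF / GDAL tag codes used for the minimal georeferencing we carry.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterParseError(ValueError):
    """A raster file failed to parse; the message names the offending part."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid in projected metres."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def x_centres(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def centre_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) holding cell-centre coords."""
        return np.meshgrid(self.x_centres(), self.y_centres())

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y + (row + 0.5) * self.cell_size,
        )

    def contains(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x < self.origin_x + self.width
            and self.origin_y <= y < self.origin_y + self.height
        )


@dataclass
class Raster:
    """A grid of values with its geometry and an optional nodata sentinel."""

    spec: GridSpec
    values: np.ndarray
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if self.values.dtype == bool and self.nodata is not None:
            raise ValueError("boolean rasters carry no nodata sentinel")

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where the cell holds the nodata sentinel."""
        if self.nodata is None:
            return np.zeros(self.values.shape, dtype=bool)
        if np.isnan(self.nodata):
            return np.isnan(self.values)
        return self.values == self.nodata

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy(), self.nodata)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One observed point: position, survey year, abundance and plot class.

    Abundance is the number of individuals within the 50-cm recording radius
    around the GPS position (>= 1).
    """

    x: float
    y: float
    year: int
    abundance: int = 1
    plot_class: str = "unsystematic"

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError(f"abundance must be >= 1, got {self.abundance}")
        if self.plot_class not in PLOT_CLASSES:
            raise ValueError(
                f"plot_class {self.plot_class!r} not one of {PLOT_CLASSES}"
            )


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid and (minimal) GeoTIFF
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd"):
        return "ascii_grid"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r}")


def read_raster(path: str | Path, format: str | None = None) -> Raster:
    """Read a square-celled raster from a GeoTIFF or ESRI ASCII grid."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        return _read_ascii_grid(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(raster: Raster, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        _write_ascii_grid(raster, path)
    elif fmt == "geotiff":
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _read_ascii_grid(path: Path) -> Raster:
    header: dict[str, float] = {}
    nodata: float | None = None
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASCII_HEADER_KEYS or key == "nodata_value":
                if len(parts) != 2:
                    raise RasterParseError(
                        f"{path}:{lineno}: malformed header line {line.strip()!r}"
                    )
                try:
                    value = float(parts[1])
                except ValueError as exc:
                    raise RasterParseError(
                        f"{path}:{lineno}: header {key!r} has non-numeric "
                        f"value {parts[1]!r}"
                    ) from exc
                if key == "nodata_value":
                    nodata = value
                else:
                    header[key] = value
            else:
                try:
                    rows.append(np.array([float(v) for v in parts]))
                except ValueError as exc:
                    raise RasterParseError(
                        f"{path}:{lineno}: non-numeric data record"
                    ) from exc
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise RasterParseError(f"{path}: missing header keys {missing}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if len(rows) != n_rows or any(len(r) != n_cols for r in rows):
        raise RasterParseError(
            f"{path}: data block is not {n_rows}x{n_cols} as the header states"
        )
    # File rows run north to south; internal row 0 is the southernmost.
    values = np.flipud(np.vstack(rows))
    if values.dtype.kind == "f" and np.all(values == np.floor(values)) and (
        np.all(np.isfinite(values))
    ):
        # Preserve integer grids bit-for-bit through the text round-trip.
        as_int = values.astype(np.int64)
        if np.array_equal(as_int.astype(values.dtype), values):
            values = as_int
    spec = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return Raster(spec, values, nodata)


def _format_value(v) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def _write_ascii_grid(raster: Raster, path: Path) -> None:
    spec = raster.spec
    values = raster.values
    if values.dtype == bool:
        values = values.astype(np.int64)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {_format_value(spec.origin_x)}\n")
        fh.write(f"yllcorner {_format_value(spec.origin_y)}\n")
        fh.write(f"cellsize {_format_value(spec.cell_size)}\n")
        if raster.nodata is not None:
            fh.write(f"NODATA_value {_format_value(raster.nodata)}\n")
        for row in np.flipud(values):
            fh.write(" ".join(_format_value(v) for v in row) + "\n")


def _read_geotiff(path: Path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterParseError(
                f"{path}: missing GeoTIFF ModelPixelScale/ModelTiepoint tags"
            )
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise RasterParseError(
                f"{path}: non-square cells ({sx} x {sy}) are not supported"
            )
        tie = tags[_TAG_MODEL_TIEPOINT].value
        top_left_x, top_left_y = tie[3], tie[4]
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if data.ndim != 2:
        raise RasterParseError(f"{path}: expected a single-band raster")
    n_rows, n_cols = data.shape
    spec = GridSpec(
        origin_x=top_left_x,
        origin_y=top_left_y - n_rows * sx,
        cell_size=float(sx),
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return Raster(spec, np.flipud(data), nodata)


def _write_geotiff(raster: Raster, path: Path) -> None:
    spec = raster.spec
    values = raster.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    top_left_y = spec.origin_y + spec.height
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, top_left_y, 0.0)),
    ]
    if raster.nodata is not None:
        extratags.append(
            (_TAG_GDAL_NODATA, "s", 0, _format_value(raster.nodata))
        )
    tifffile.imwrite(path, np.flipud(values), extratags=extratags)


# ---------------------------------------------------------------------------
# Point / trail I/O (CSV and GeoJSON in projected metres)
# ---------------------------------------------------------------------------


def read_points_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read occurrence records from CSV with header x,y,year,abundance,plot_class."""
    df = pd.read_csv(path)
    required = {"x", "y", "year", "abundance", "plot_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
    return [
        OccurrenceRecord(
            x=float(r.x), y=float(r.y), year=int(r.year),
            abundance=int(r.abundance), plot_class=str(r.plot_class),
        )
        for r in df.itertuples()
    ]


def write_points_csv(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_to_frame(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "year": [r.year for r in records],
            "abundance": [r.abundance for r in records],
            "plot_class": [r.plot_class for r in records],
        }
    )


def read_trails_geojson(path: str | Path) -> dict[str, LineString]:
    """Read named trail polylines from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    trails: dict[str, LineString] = {}
    for i, feature in enumerate(doc.get("features", [])):
        geom = shape(feature["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: feature {i} is not a LineString")
        name = feature.get("properties", {}).get("name", f"trail_{i}")
        trails[name] = geom
    if not trails:
        raise ValueError(f"{path}: no LineString features found")
    return trails


def write_trails_geojson(trails: Mapping[str, LineString], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(line),
        }
        for name, line in trails.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_station_geojson(path: str | Path) -> tuple[float, float]:
    with open(path) as fh:
        doc = json.load(fh)
    for feature in doc.get("features", []):
        geom = shape(feature["geometry"])
        if isinstance(geom, Point):
            return (geom.x, geom.y)
    raise ValueError(f"{path}: no Point feature found")


def write_station_geojson(station: tuple[float, float], path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": "station"},
                "geometry": mapping(Point(*station)),
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Distance fields and rasterization
# ---------------------------------------------------------------------------


def distance_to_point(spec: GridSpec, point: tuple[float, float]) -> Raster:
    """Euclidean distance (m) from every cell centre to a reference point."""
    px, py = point
    if not (np.isfinite(px) and np.isfinite(py)):
        raise ValueError("reference point must be finite")
    X, Y = spec.centre_mesh()
    return Raster(spec, np.hypot(X - px, Y - py))


def _as_linestrings(trails) -> list[LineString]:
    if isinstance(trails, Mapping):
        trails = list(trails.values())
    elif isinstance(trails, LineString):
        trails = [trails]
    lines = []
    for t in trails:
        line = t if isinstance(t, LineString) else LineString(t)
        if len(line.coords) < 2:
            raise ValueError("each trail polyline needs at least 2 vertices")
        lines.append(line)
    if not lines:
        raise ValueError("trail set is empty")
    return lines


def distance_to_trails(spec: GridSpec, trails) -> Raster:
    """Minimum Euclidean distance from each cell centre to any trail segment."""
    lines = _as_linestrings(trails)
    geom = MultiLineString(lines) if len(lines) > 1 else lines[0]
    X, Y = spec.centre_mesh()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, geom)
    return Raster(spec, d.reshape(spec.n_rows, spec.n_cols))


def rasterize_trail(
    spec: GridSpec, trail, width: float = DEFAULT_TRAIL_WIDTH
) -> Raster:
    """Boolean band: cell True iff its centre lies within width/2 of the trail.

    A narrow width on a coarse grid can miss every cell centre and return an
    empty mask; that is the documented behaviour of centre-based membership.
    """
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    dist = distance_to_trails(spec, trail)
    return Raster(spec, dist.values <= width / 2.0)


def points_to_cells(
    points: Sequence[OccurrenceRecord] | np.ndarray, spec: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Map point coordinates to (row, col) indices under the half-open rule.

    Returns ``(cells, inside)`` where ``cells`` is an (n, 2) integer array of
    (row, col) and ``inside`` flags points whose cell lies within the grid.
    Out-of-grid points keep their (possibly negative) floor indices so the
    caller can see where they fell; they are never silently dropped.
    """
    xy = _point_array(points)
    cols = np.floor((xy[:, 0] - spec.origin_x) / spec.cell_size).astype(np.int64)
    rows = np.floor((xy[:, 1] - spec.origin_y) / spec.cell_size).astype(np.int64)
    inside = (rows >= 0) & (rows < spec.n_rows) & (cols >= 0) & (cols < spec.n_cols)
    return np.column_stack([rows, cols]), inside


def _point_array(points) -> np.ndarray:
    """Coerce records / (n,2) arrays / sequences of pairs to an (n,2) float array."""
    if isinstance(points, np.ndarray):
        return np.atleast_2d(points).astype(float)
    if len(points) > 0 and isinstance(points[0], OccurrenceRecord):
        return np.array([[p.x, p.y] for p in points], dtype=float)
    return np.atleast_2d(np.asarray(points, dtype=float))
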