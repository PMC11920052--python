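"""Data model and I/O for population grids, reservoir polygons and attribute
tables, plus mass-preserving resolution changes.

All geometry lives on a planar Cartesian plane in metres. Rasters follow the
usual image convention: the origin is the upper-left corner and the row index
increases downward, so the centroid of cell ``(r, c)`` is at
``(origin_x + (c + 0.5) * cell_size, origin_y + (r + 0.5) * cell_size)``.
Counts are real-valued persons per cell: gridded population products store
fractional persons after dasymetric disaggregation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import tifffile

from .errors import GridValidationError, PolygonError, TableError

logger = logging.getLogger(__name__)

INCOME_LEVELS = ("low", "lower-middle", "upper-middle", "high")


@dataclass
class PopulationGrid:
    """A planar raster of person counts.

    Parameters
    ----------
    counts
        ``(n_rows, n_cols)`` array of persons per cell; finite and >= 0.
    cell_size
        Cell edge length in metres (> 0); cells are square.
    origin_x, origin_y
        Planar coordinates (metres) of the grid's upper-left corner.
    reference_year
        The population-map vintage this grid represents, or ``None`` if the
        caller has not supplied one.
    dataset_name
        Label of the producing dataset (e.g. a synthetic stand-in name).
    """

    counts: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    reference_year: int | None = None
    dataset_name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise GridValidationError(
                f"counts must be a non-empty 2-D array, got shape {self.counts.shape}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise GridValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise GridValidationError(
                f"counts contain {int(np.sum(self.counts < 0))} negative cells"
            )
        if not (self.cell_size > 0):
            raise GridValidationError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> float:
        """Total population of the grid."""
        return float(self.counts.sum())


@dataclass
class ReservoirPolygon:
    """A simple closed reservoir footprint (no holes), vertices in metres."""

    id: str
    ring: np.ndarray  # (n, 2) planar vertices

    def __post_init__(self) -> None:
        ring = np.asarray(self.ring, dtype=float)
        # drop an explicit closing vertex if present
        if ring.shape[0] >= 2 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
            raise PolygonError(f"polygon {self.id!r}: ring needs >= 3 (x, y) vertices")
        self.ring = ring
        geom = shapely.Polygon(ring)
        if not geom.is_valid:
            raise PolygonError(f"polygon {self.id!r}: ring is self-intersecting or degenerate")
        if geom.area <= 0:
            raise PolygonError(f"polygon {self.id!r}: zero area")

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.ring)

    @property
    def geometric_area_km2(self) -> float:
        return polygon_area_km2(self)


@dataclass
class ReservoirRecord:
    """One ICOLD-like attribute row keyed to a reservoir polygon.

    ``resettled_persons`` is ``None`` when no resettlement figure was
    reported; zero is a legitimate report and is kept distinct from missing.
    """

    id: str
    country: str
    income_level: str
    completion_year: int
    reported_area_km2: float
    resettled_persons: float | None
    excluded_transboundary: bool = False
    excluded_preexisting: bool = False

    def __post_init__(self) -> None:
        if self.income_level not in INCOME_LEVELS:
            raise TableError(
                f"record {self.id!r}: unknown income_level {self.income_level!r}; "
                f"allowed labels are {', '.join(INCOME_LEVELS)}"
            )
        if not (self.reported_area_km2 > 0):
            raise TableError(
                f"record {self.id!r}: reported_area_km2 must be > 0, "
                f"got {self.reported_area_km2}"
            )
        if self.resettled_persons is not None and self.resettled_persons < 0:
            raise TableError(
                f"record {self.id!r}: resettled_persons must be >= 0, "
                f"got {self.resettled_persons}"
            )


# ---------------------------------------------------------------------------
# Raster I/O (single-band square-pixel TIFF; grid metadata in a JSON tag)
# ---------------------------------------------------------------------------

def write_population_raster(grid: PopulationGrid, path) -> None:
    """Write a grid as a single-band float TIFF with metadata tags."""
    meta = {
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "cell_size_x": grid.cell_size,
        "cell_size_y": grid.cell_size,
        "reference_year": grid.reference_year,
        "dataset_name": grid.dataset_name,
    }
    tifffile.imwrite(
        str(path), grid.counts.astype(np.float64), description=json.dumps(meta)
    )


def read_population_raster(
    path, *, reference_year: int | None = None, dataset_name: str | None = None
) -> PopulationGrid:
    """Read a single-band raster written by :func:`write_population_raster`.

    ``reference_year`` and ``dataset_name`` override what the file carries;
    they are never guessed. Nodata cells (NaN) are zero-filled with a logged
    count.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = np.asarray(page.asarray(), dtype=float)
        desc = page.tags.get("ImageDescription")
        meta: dict = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if arr.ndim != 2:
        raise GridValidationError(f"{path}: raster must be single-band 2-D, got shape {arr.shape}")
    csx = float(meta.get("cell_size_x", meta.get("cell_size", 0)) or 0)
    csy = float(meta.get("cell_size_y", csx) or csx)
    if csx <= 0:
        raise GridValidationError(f"{path}: missing or non-positive cell size in metadata")
    if not np.isclose(csx, csy):
        raise GridValidationError(f"{path}: non-square cells ({csx} x {csy} m)")
    n_nodata = int(np.sum(~np.isfinite(arr)))
    if n_nodata:
        logger.info("%s: zero-filled %d nodata cells", path, n_nodata)
        arr = np.where(np.isfinite(arr), arr, 0.0)
    if np.any(arr < 0):
        raise GridValidationError(
            f"{path}: {int(np.sum(arr < 0))} negative count cells"
        )
    year = reference_year if reference_year is not None else meta.get("reference_year")
    name = dataset_name if dataset_name is not None else meta.get("dataset_name", "")
    return PopulationGrid(
        counts=arr,
        cell_size=csx,
        origin_x=float(meta.get("origin_x", 0.0)),
        origin_y=float(meta.get("origin_y", 0.0)),
        reference_year=int(year) if year is not None else None,
        dataset_name=str(name),
    )


# ---------------------------------------------------------------------------
# Vector and table I/O
# ---------------------------------------------------------------------------

def write_reservoir_polygons(polygons: list[ReservoirPolygon], path) -> None:
    """Write polygons as a GeoJSON FeatureCollection (one Polygon each)."""
    features = []
    for p in polygons:
        ring = np.vstack([p.ring, p.ring[:1]])
        features.append(
            {
                "type": "Feature",
                "properties": {"id": p.id},
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_reservoir_polygons(path) -> list[ReservoirPolygon]:
    """Read a GeoJSON FeatureCollection of simple Polygons with an ``id``."""
    with open(path) as fh:
        doc = json.load(fh)
    polygons: list[ReservoirPolygon] = []
    seen: set[str] = set()
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise PolygonError(f"feature geometry type {geom.get('type')!r} is not Polygon")
        rings = geom.get("coordinates") or []
        if len(rings) != 1:
            raise PolygonError("polygons with holes are not supported")
        pid = str((feat.get("properties") or {}).get("id"))
        if pid in seen:
            raise PolygonError(f"duplicate polygon id {pid!r}")
        seen.add(pid)
        polygons.append(ReservoirPolygon(id=pid, ring=np.asarray(rings[0], dtype=float)))
    return polygons


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False, "t": True, "f": False,
    "yes": True, "no": False, "": False,
}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise TableError(f"unparsable boolean {value!r}")
    return _BOOL_MAP[key]


def read_reservoir_table(path) -> list[ReservoirRecord]:
    """Read the ICOLD-like attribute CSV into validated records.

    The header must name every :class:`ReservoirRecord` field. A blank
    ``resettled_persons`` cell means "not reported" and becomes ``None``.
    """
    df = pd.read_csv(path, dtype={"id": str, "country": str, "income_level": str})
    required = {
        "id", "country", "income_level", "completion_year", "reported_area_km2",
        "resettled_persons", "excluded_transboundary", "excluded_preexisting",
    }
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise TableError(f"{path}: duplicate record ids {dupes}")
    records = []
    for row in df.itertuples(index=False):
        resettled = row.resettled_persons
        resettled = None if pd.isna(resettled) else float(resettled)
        records.append(
            ReservoirRecord(
                id=str(row.id),
                country=str(row.country),
                income_level=str(row.income_level),
                completion_year=int(row.completion_year),
                reported_area_km2=float(row.reported_area_km2),
                resettled_persons=resettled,
                excluded_transboundary=_parse_bool(row.excluded_transboundary),
                excluded_preexisting=_parse_bool(row.excluded_preexisting),
            )
        )
    return records


def write_reservoir_table(records: list[ReservoirRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "country": [r.country for r in records],
            "income_level": [r.income_level for r in records],
            "completion_year": [r.completion_year for r in records],
            "reported_area_km2": [r.reported_area_km2 for r in records],
            "resettled_persons": [r.resettled_persons for r in records],
            "excluded_transboundary": [r.excluded_transboundary for r in records],
            "excluded_preexisting": [r.excluded_preexisting for r in records],
        }
    ).to_csv(path, index=False)


def unmatched_record_ids(
    records: list[ReservoirRecord], polygons: list[ReservoirPolygon]
) -> list[str]:
    """Ids of records lacking a polygon — reported, never silently dropped."""
    have = {p.id for p in polygons}
    unmatched = [r.id for r in records if r.id not in have]
    for rid in unmatched:
        logger.warning("record %s has no matching polygon", rid)
    return unmatched


# ---------------------------------------------------------------------------
# Geometry and mass-preserving resolution changes
# ---------------------------------------------------------------------------

def polygon_area_km2(polygon: ReservoirPolygon) -> float:
    """Planar (shoelace) area of the footprint in km²; orientation-independent."""
    x = polygon.ring[:, 0]
    y = polygon.ring[:, 1]
    area_m2 = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area_m2 / 1e6)


def refine_grid(grid: PopulationGrid, factor: int) -> PopulationGrid:
    """Split every cell into ``factor²`` children, each carrying an equal
    share of the parent's count. Total population is conserved exactly."""
    factor = int(factor)
    if factor < 1:
        raise GridValidationError(f"refine factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(grid, counts=grid.counts.copy())
    fine = np.kron(grid.counts, np.full((factor, factor), 1.0 / factor**2))
    return replace(grid, counts=fine, cell_size=grid.cell_size / factor)


def aggregate_grid(grid: PopulationGrid, factor: int) -> PopulationGrid:
    """Sum ``factor × factor`` blocks into coarse cells; the inverse of
    :func:`refine_grid` at the same factor."""
    factor = int(factor)
    if factor < 1:
        raise GridValidationError(f"aggregation factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(grid, counts=grid.counts.copy())
    n_rows, n_cols = grid.counts.shape
    if n_rows % factor or n_cols % factor:
        raise GridValidationError(
            f"grid shape {grid.counts.shape} not divisible by factor {factor}"
        )
    coarse = (
        grid.counts.reshape(n_rows // factor, factor, n_cols // factor, factor)
        .sum(axis=(1, 3))
    )
    return replace(grid, counts=coarse, cell_size=grid.cell_size * factor)
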