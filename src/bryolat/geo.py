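"""Geospatial primitives: bounding boxes, band grids, gazetteer geocoding.

Sampling geometry follows the macroecological convention of latitudinal
bands subdivided into longitudinal sampling units.  Two band schemes are
supported: ``equal_angle`` (5-degree bands by default) and ``equal_area``
(band edges equally spaced in sin(latitude), so every band covers the same
fraction of the sphere).  Cells are half-open ``[lower, upper)`` intervals
with the top (+90) and east (+180) edges closed, so every point on the
globe falls in exactly one cell.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box as shapely_box

__all__ = [
    "GeoBox",
    "Gazetteer",
    "GeocodeResult",
    "NOT_FOUND",
    "BandGrid",
    "LandMask",
    "geocode",
    "box_area_fraction",
    "filter_oversized",
    "make_band_grid",
    "apply_land_mask",
    "assign_units",
    "heatmap_counts",
    "region_filter",
]


@dataclass(frozen=True)
class GeoBox:
    """Geographic bounding box in degrees.

    A box with ``min_lon > max_lon`` (or ``wraps_antimeridian=True``)
    crosses the +/-180 meridian and is treated as the union of two
    non-wrapping boxes.
    """

    min_lat: float
    max_lat: float
    min_lon: float
    max_lon: float
    wraps_antimeridian: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 <= self.min_lat <= self.max_lat <= 90.0):
            raise ValueError(f"invalid latitude range [{self.min_lat}, {self.max_lat}]")
        if not (-180.0 <= self.min_lon <= 180.0 and -180.0 <= self.max_lon <= 180.0):
            raise ValueError(f"longitudes out of [-180, 180]: [{self.min_lon}, {self.max_lon}]")
        if self.min_lon > self.max_lon and not self.wraps_antimeridian:
            object.__setattr__(self, "wraps_antimeridian", True)

    @property
    def lon_extent(self) -> float:
        if self.wraps_antimeridian:
            return (self.max_lon - self.min_lon) % 360.0
        return self.max_lon - self.min_lon

    def unwrap(self) -> list["GeoBox"]:
        """Split a wrapping box into one or two non-wrapping boxes."""
        if not self.wraps_antimeridian:
            return [self]
        return [
            GeoBox(self.min_lat, self.max_lat, self.min_lon, 180.0),
            GeoBox(self.min_lat, self.max_lat, -180.0, self.max_lon),
        ]

    def contains(self, lat: float, lon: float) -> bool:
        """Closed-boundary containment (edges count as inside)."""
        if not (self.min_lat <= lat <= self.max_lat):
            return False
        if self.wraps_antimeridian:
            return lon >= self.min_lon or lon <= self.max_lon
        return self.min_lon <= lon <= self.max_lon


#: Sentinel for an unresolvable gazetteer lookup.  NOT-FOUND is a value,
#: never an exception: unknown place names are logged and skipped.
NOT_FOUND = None


@dataclass(frozen=True)
class GeocodeResult:
    name: str
    box: GeoBox
    centroid_lat: float
    centroid_lon: float
    non_location: bool = False


_WS = re.compile(r"\s+")


def _normalize(name: str) -> str:
    return _WS.sub(" ", name.strip()).casefold()


class Gazetteer:
    """Place-name table mapping names to bounding boxes and centroids.

    Stands in for a live geocoding service so runs are reproducible and
    offline.  Lookup is case-insensitive and whitespace-normalized.
    Entries flagged ``non_location`` are author-surname lookalikes kept in
    the table to exercise the location-name verifier; they still geocode
    (the upstream generic NER would have tagged them).
    """

    def __init__(self, entries: Iterable[GeocodeResult]):
        self._entries: dict[str, GeocodeResult] = {}
        for e in entries:
            self._entries[_normalize(e.name)] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, name: str) -> GeocodeResult | None:
        return self._entries.get(_normalize(name))

    def names(self) -> list[str]:
        return [e.name for e in self._entries.values()]

    def to_json(self, path: str | Path) -> None:
        rows = []
        for e in self._entries.values():
            row = {
                "name": e.name,
                "min_lat": e.box.min_lat,
                "max_lat": e.box.max_lat,
                "min_lon": e.box.min_lon,
                "max_lon": e.box.max_lon,
                "centroid_lat": e.centroid_lat,
                "centroid_lon": e.centroid_lon,
            }
            if e.non_location:
                row["non_location"] = True
            rows.append(row)
        Path(path).write_text(json.dumps(rows, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Gazetteer":
        rows = json.loads(Path(path).read_text())
        return cls(
            GeocodeResult(
                name=r["name"],
                box=GeoBox(r["min_lat"], r["max_lat"], r["min_lon"], r["max_lon"]),
                centroid_lat=r["centroid_lat"],
                centroid_lon=r["centroid_lon"],
                non_location=bool(r.get("non_location", False)),
            )
            for r in rows
        )


def geocode(
    name: str, gazetteer: Gazetteer, cache: dict[str, GeocodeResult | None] | None = None
) -> GeocodeResult | None:
    """Look up a place name; returns NOT_FOUND (None) for unknown names.

    The cache maps the normalized key to the result (including NOT_FOUND),
    so repeated misses are recorded exactly once.
    """
    key = _normalize(name)
    if cache is not None and key in cache:
        return cache[key]
    result = gazetteer.get(name)
    if cache is not None:
        cache[key] = result
    return result


def box_area_fraction(geom: GeoBox) -> float:
    """Fraction of the Earth's surface covered by a box, spherical globe.

    fraction = (dlon / 360) * (sin(lat_max) - sin(lat_min)) / 2
    """
    dlon = geom.lon_extent
    s = math.sin(math.radians(geom.max_lat)) - math.sin(math.radians(geom.min_lat))
    return (dlon / 360.0) * s / 2.0


def filter_oversized(records: Sequence, max_fraction: float = 0.02):
    """Split records into (kept, removed) by bounding-box surface fraction.

    Point records have area zero and are always kept.  The default
    threshold removes boxes covering more than 2% of the Earth's surface;
    it is configurable because the choice is a judgment call about how
    much spatial imprecision to tolerate.
    """
    kept, removed = [], []
    for rec in records:
        geom = getattr(rec, "geometry", rec)
        if isinstance(geom, GeoBox) and box_area_fraction(geom) > max_fraction:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


@dataclass
class BandGrid:
    """Latitudinal bands x longitudinal sampling units with a retention mask.

    Bands are indexed 0 (southernmost) upward.  ``retained`` marks the
    ocean sampling units that enter richness estimation; landlocked units
    are dropped by :func:`apply_land_mask`.
    """

    scheme: str
    band_edges: np.ndarray  # (n_bands + 1,) ascending, -90 .. 90
    lon_unit_deg: float
    retained: np.ndarray = field(default=None)  # (n_bands, n_lon_units) bool

    def __post_init__(self) -> None:
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        if self.retained is None:
            self.retained = np.ones((self.n_bands, self.n_lon_units), dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.n_bands, self.n_lon_units):
            raise ValueError("retained mask shape does not match grid")

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1

    @property
    def n_lon_units(self) -> int:
        return int(round(360.0 / self.lon_unit_deg))

    @property
    def band_mids(self) -> np.ndarray:
        return (self.band_edges[:-1] + self.band_edges[1:]) / 2.0

    def units_per_band(self) -> np.ndarray:
        """N per band: number of retained sampling units."""
        return self.retained.sum(axis=1)

    def band_index(self, lat: float) -> int:
        """Band containing a latitude; [lower, upper) bands, +90 in the top band."""
        if lat >= self.band_edges[-1]:
            return self.n_bands - 1
        i = int(np.searchsorted(self.band_edges, lat, side="right")) - 1
        return max(i, 0)

    def lon_unit_index(self, lon: float) -> int:
        if lon >= 180.0:
            return self.n_lon_units - 1
        return int((lon + 180.0) // self.lon_unit_deg)

    def lon_unit_interval(self, j: int) -> tuple[float, float]:
        lo = -180.0 + j * self.lon_unit_deg
        return lo, lo + self.lon_unit_deg

    def band_fractions(self) -> np.ndarray:
        """Surface-area fraction per band (longitudes all included)."""
        s = np.sin(np.radians(self.band_edges))
        return (s[1:] - s[:-1]) / 2.0


def make_band_grid(
    scheme: str = "equal_angle", n_bands: int = 36, lon_unit_deg: float = 5.0
) -> BandGrid:
    """Build a global band grid.

    ``equal_angle``: edges at -90, -90 + 180/n, ..., 90.
    ``equal_area``: edge_k = arcsin(2k/n - 1), so every band covers 1/n of
    the sphere's surface.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if abs(360.0 / lon_unit_deg - round(360.0 / lon_unit_deg)) > 1e-9:
        raise ValueError("360 must be divisible by lon_unit_deg")
    if scheme == "equal_angle":
        edges = np.linspace(-90.0, 90.0, n_bands + 1)
    elif scheme == "equal_area":
        k = np.arange(n_bands + 1)
        edges = np.degrees(np.arcsin(2.0 * k / n_bands - 1.0))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return BandGrid(scheme=scheme, band_edges=edges, lon_unit_deg=lon_unit_deg)


@dataclass
class LandMask:
    """Boolean grid aligned with a BandGrid: True where a cell is entirely land."""

    land: np.ndarray  # (n_bands, n_lon_units) bool

    def __post_init__(self) -> None:
        self.land = np.asarray(self.land, dtype=bool)


def apply_land_mask(grid: BandGrid, mask: LandMask) -> BandGrid:
    """Return a copy of the grid with landlocked sampling units removed."""
    if mask.land.shape != grid.retained.shape:
        raise ValueError(
            f"land mask shape {mask.land.shape} does not match grid {grid.retained.shape}"
        )
    return BandGrid(
        scheme=grid.scheme,
        band_edges=grid.band_edges.copy(),
        lon_unit_deg=grid.lon_unit_deg,
        retained=grid.retained & ~mask.land,
    )


def _interval_indices(edges: np.ndarray, lo: float, hi: float) -> range:
    """Indices of [edges] intervals whose closed intersection with [lo, hi] is nonempty.

    Cells are half-open [edges[b], edges[b+1]) with the top cell closed,
    exactly as for point assignment, so a box touching only a cell's open
    upper edge does not claim the next cell.  The range is simply
    cell_index(lo) .. cell_index(hi).
    """
    n = len(edges) - 1

    def idx(v: float) -> int:
        return min(n - 1, max(0, int(np.searchsorted(edges, v, side="right")) - 1))

    return range(idx(lo), idx(hi) + 1)


def _lon_unit_indices(grid: BandGrid, lo: float, hi: float) -> set[int]:
    edges = -180.0 + grid.lon_unit_deg * np.arange(grid.n_lon_units + 1)
    return set(_interval_indices(edges, lo, hi))


def assign_units(
    geometry, grid: BandGrid, retained_only: bool = True
) -> set[tuple[int, int]]:
    """Map a point (lat, lon) or GeoBox to sampling-unit cells of the grid.

    Points land in exactly one cell by the half-open convention.  Boxes
    claim every half-open cell their closed rectangle intersects, so a box
    containing a point always claims at least that point's cell; wrapping
    boxes are split at the antimeridian and the results unioned.  With
    ``retained_only`` (the default, consistent with
    landlocked-bin removal) cells dropped by the land mask are excluded.
    """
    cells: set[tuple[int, int]] = set()
    if isinstance(geometry, GeoBox):
        for part in geometry.unwrap():
            bands = _interval_indices(grid.band_edges, part.min_lat, part.max_lat)
            units = _lon_unit_indices(grid, part.min_lon, part.max_lon)
            cells.update((b, j) for b in bands for j in units)
    else:
        lat, lon = geometry
        cells.add((grid.band_index(lat), grid.lon_unit_index(lon)))
    if retained_only:
        cells = {(b, j) for (b, j) in cells if grid.retained[b, j]}
    return cells


def heatmap_counts(records: Sequence, grid: BandGrid) -> np.ndarray:
    """Per-cell record counts; a box record adds 1 to every intersected cell."""
    counts = np.zeros((grid.n_bands, grid.n_lon_units), dtype=int)
    for rec in records:
        geom = getattr(rec, "geometry", rec)
        for b, j in assign_units(geom, grid, retained_only=False):
            counts[b, j] += 1
    return counts


def region_filter(records: Sequence, polygons: Sequence[Sequence[tuple[float, float]]]):
    """Keep records inside (points) or intersecting (boxes) any polygon.

    Polygons are (lon, lat) rings; self-intersecting rings are rejected.
    Used for ocean-basin subsets of the global record pool.
    """
    polys = []
    for ring in polygons:
        p = Polygon(ring)
        if not p.is_valid:
            raise ValueError("self-intersecting or otherwise invalid polygon ring")
        polys.append(p)
    kept = []
    for rec in records:
        geom = getattr(rec, "geometry", rec)
        if isinstance(geom, GeoBox):
            shapes = [
                shapely_box(part.min_lon, part.min_lat, part.max_lon, part.max_lat)
                for part in geom.unwrap()
            ]
            if any(p.intersects(s) for p in polys for s in shapes):
                kept.append(rec)
        else:
            lat, lon = geom
            pt = Point(lon, lat)
            if any(p.intersects(pt) for p in polys):
                kept.append(rec)
    return kept
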