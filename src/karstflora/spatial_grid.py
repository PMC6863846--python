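"""Equal-area projection, square gridding and karst extents.

All planar work happens in kilometres in an equal-area plane. Two
projections are provided: the South America Albers Equal Area Conic
(the standard choice for continental-scale biogeography of South
America) and a planar passthrough for data that is already expressed in
kilometres. Grid cells are half-open squares ``[x0+i*s, x0+(i+1)*s) x
[y0+j*s, y0+(j+1)*s)`` indexed by integer ``(col, row)``, so every
finite point belongs to exactly one cell and boundary points are never
double counted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from shapely.geometry import Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

__all__ = [
    "AlbersEqualArea",
    "PlanarKm",
    "EqualAreaGrid",
    "KarstExtent",
    "buffer_extent",
    "bounding_box",
    "assign_cells",
    "subcell_occupancy",
    "extent_to_geojson",
    "extent_from_geojson",
]

# Authalic Earth radius in km: the sphere with the same surface area as
# the WGS84 ellipsoid, the natural choice for an equal-area projection.
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on the authalic sphere.

    Defaults are the South America Albers Equal Area Conic parameters:
    central meridian -60°, standard parallels -5° and -42°, latitude of
    origin -32°. Output coordinates are kilometres.
    """

    lon_0: float = -60.0
    lat_0: float = -32.0
    lat_1: float = -5.0
    lat_2: float = -42.0
    radius_km: float = EARTH_RADIUS_KM

    @property
    def _constants(self) -> tuple[float, float, float]:
        phi0, phi1, phi2 = (math.radians(v) for v in (self.lat_0, self.lat_1, self.lat_2))
        n = 0.5 * (math.sin(phi1) + math.sin(phi2))
        c = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
        rho0 = self.radius_km * math.sqrt(c - 2.0 * n * math.sin(phi0)) / n
        return n, c, rho0

    def project(self, lon, lat):
        """Forward transform: degrees (lon, lat) -> km (x, y)."""
        n, c, rho0 = self._constants
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        phi = np.radians(lat)
        theta = n * (np.radians(lon) - math.radians(self.lon_0))
        rho = self.radius_km * np.sqrt(c - 2.0 * n * np.sin(phi)) / n
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def unproject(self, x, y):
        """Inverse transform: km (x, y) -> degrees (lon, lat)."""
        n, c, rho0 = self._constants
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.sign(n) * np.hypot(x, rho0 - y)
        # atan2 arguments flip sign with n so the azimuth is recovered on
        # cones opening southward (n < 0, as for South America).
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * (rho0 - y))
        sin_phi = np.clip((c - (rho * n / self.radius_km) ** 2) / (2.0 * n), -1.0, 1.0)
        lat = np.degrees(np.arcsin(sin_phi))
        lon = self.lon_0 + np.degrees(theta / n)
        return lon, lat

    def to_dict(self) -> dict:
        return {
            "type": "albers_equal_area",
            "lon_0": self.lon_0,
            "lat_0": self.lat_0,
            "lat_1": self.lat_1,
            "lat_2": self.lat_2,
            "radius_km": self.radius_km,
        }


@dataclass(frozen=True)
class PlanarKm:
    """Identity projection for data already expressed in planar km."""

    def project(self, x, y):
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)

    def unproject(self, x, y):
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)

    def to_dict(self) -> dict:
        return {"type": "planar_km"}


def projection_from_dict(d: Mapping) -> AlbersEqualArea | PlanarKm:
    kind = d.get("type", "planar_km")
    if kind == "planar_km":
        return PlanarKm()
    if kind == "albers_equal_area":
        return AlbersEqualArea(
            lon_0=d["lon_0"], lat_0=d["lat_0"], lat_1=d["lat_1"],
            lat_2=d["lat_2"], radius_km=d.get("radius_km", EARTH_RADIUS_KM),
        )
    raise ValueError(f"unknown projection spec: {kind!r}")


@dataclass(frozen=True)
class EqualAreaGrid:
    """Regular square tessellation of the projected plane.

    Cells are half-open: a point with ``x == origin_x + i*s`` lies in
    column ``i``, never in column ``i-1``. Indices are zero-based
    ``(col, row)`` relative to the grid origin and may be negative for
    points below/left of it.
    """

    origin_x: float
    origin_y: float
    cell_size_km: float
    projection: AlbersEqualArea | PlanarKm = field(default_factory=PlanarKm)

    def __post_init__(self):
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @classmethod
    def from_extent(cls, extent: "KarstExtent", cell_size_km: float,
                    projection=None) -> "EqualAreaGrid":
        """Anchor the grid at the floor of the extent's bounding box.

        Flooring to a multiple of the cell size makes indices
        reproducible across runs that share a projection.
        """
        minx, miny, _, _ = extent.geometry.bounds
        s = cell_size_km
        return cls(
            origin_x=math.floor(minx / s) * s,
            origin_y=math.floor(miny / s) * s,
            cell_size_km=s,
            projection=projection if projection is not None else extent.projection,
        )

    def cell_index(self, x, y):
        """Vectorised point -> (col, row). Raises on non-finite input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        bad = ~(np.isfinite(x) & np.isfinite(y))
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-finite coordinate at position {i}")
        col = np.floor((x - self.origin_x) / self.cell_size_km).astype(np.int64)
        row = np.floor((y - self.origin_y) / self.cell_size_km).astype(np.int64)
        return col, row

    def cell_bounds(self, col: int, row: int) -> tuple[float, float, float, float]:
        s = self.cell_size_km
        x0 = self.origin_x + col * s
        y0 = self.origin_y + row * s
        return x0, y0, x0 + s, y0 + s

    def cell_polygon(self, col: int, row: int) -> Polygon:
        return box(*self.cell_bounds(col, row))

    def cells_intersecting(self, geom: BaseGeometry) -> list[tuple[int, int]]:
        """All (col, row) whose square intersects ``geom`` (positive area)."""
        minx, miny, maxx, maxy = geom.bounds
        c0, r0 = self.cell_index(minx, miny)
        c1, r1 = self.cell_index(maxx, maxy)
        out = []
        for col in range(int(c0), int(c1) + 1):
            for row in range(int(r0), int(r1) + 1):
                cell = self.cell_polygon(col, row)
                if geom.intersects(cell) and geom.intersection(cell).area > 0:
                    out.append((col, row))
        return out

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size_km": self.cell_size_km,
            "projection": self.projection.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EqualAreaGrid":
        return cls(
            origin_x=d["origin_x"], origin_y=d["origin_y"],
            cell_size_km=d["cell_size_km"],
            projection=projection_from_dict(d.get("projection", {})),
        )


def assign_cells(x, y, grid: EqualAreaGrid):
    """Map projected points to grid cells; see ``EqualAreaGrid.cell_index``."""
    return grid.cell_index(x, y)


@dataclass(frozen=True)
class KarstExtent:
    """A labelled polygon set in the projected (km) plane.

    Labels follow the analysis conventions: ``NBZ`` (karst, no buffer),
    ``BZ5`` (karst with 5 km buffer), ``study_area`` (bounding box), or
    ``custom``.
    """

    label: str
    geometry: BaseGeometry
    buffer_km: float = 0.0
    projection: AlbersEqualArea | PlanarKm = field(default_factory=PlanarKm)

    def __post_init__(self):
        if self.buffer_km < 0:
            raise ValueError("buffer_km must be >= 0")
        if not self.geometry.is_valid:
            raise ValueError("extent geometry is not valid")

    @property
    def area_km2(self) -> float:
        return float(self.geometry.area)

    def contains_points(self, x, y) -> np.ndarray:
        """Vectorised point-in-extent test (boundary counts as inside)."""
        import shapely
        from shapely import points as shp_points

        pts = shp_points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        shapely.prepare(self.geometry)
        return np.atleast_1d(shapely.intersects(self.geometry, pts))


def buffer_extent(extent: KarstExtent, buffer_km: float) -> KarstExtent:
    """Euclidean buffer in projected space; ``buffer_km=5`` yields BZ5."""
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    if buffer_km == 0:
        return extent
    # quad_segs=256 keeps the circular-arc area error of a 5 km buffer
    # below 1e-3 km^2 (polygonal deficit scales as 1/n^2)
    geom = extent.geometry.buffer(buffer_km, quad_segs=256)
    label = "BZ5" if buffer_km == 5 else f"buffered_{buffer_km:g}km"
    return KarstExtent(label=label, geometry=geom,
                       buffer_km=extent.buffer_km + buffer_km,
                       projection=extent.projection)


def bounding_box(extent: KarstExtent) -> KarstExtent:
    """Axis-aligned study-area box enclosing all polygons of ``extent``."""
    if extent.geometry.is_empty:
        raise ValueError("cannot take the bounding box of an empty extent")
    return KarstExtent(label="study_area", geometry=box(*extent.geometry.bounds),
                       projection=extent.projection)


def subcell_occupancy(x, y, grid50: EqualAreaGrid, grid10: EqualAreaGrid
                      ) -> dict[tuple[int, int], int]:
    """Per 50 km cell, the number of non-empty 10 km subcells (1..25).

    The fine grid must be nested in the coarse grid: shared origin and an
    integer cell-size ratio. Cells with no records are absent from the
    mapping rather than reported as zero.
    """
    ratio = grid50.cell_size_km / grid10.cell_size_km
    if (grid50.origin_x != grid10.origin_x or grid50.origin_y != grid10.origin_y
            or abs(ratio - round(ratio)) > 1e-9):
        raise ValueError("grid10 is not nested in grid50 (origin or cell-size ratio)")
    c50, r50 = grid50.cell_index(x, y)
    c10, r10 = grid10.cell_index(x, y)
    seen: dict[tuple[int, int], set] = {}
    for a, b, c, d in zip(c50, r50, c10, r10):
        seen.setdefault((int(a), int(b)), set()).add((int(c), int(d)))
    return {k: len(v) for k, v in sorted(seen.items())}


def extent_to_geojson(extent: KarstExtent, path=None, to_wgs84: bool = True):
    """Serialise an extent as a GeoJSON Feature (WGS84 by default)."""
    geom = extent.geometry
    if to_wgs84 and isinstance(extent.projection, AlbersEqualArea):
        proj = extent.projection
        geom = shp_transform(lambda x, y: proj.unproject(x, y), geom)
    feature = {
        "type": "Feature",
        "properties": {
            "label": extent.label,
            "buffer_km": extent.buffer_km,
            "area_km2": extent.area_km2,
            "projection": extent.projection.to_dict(),
        },
        "geometry": mapping(geom),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(feature, fh)
    return feature


def extent_from_geojson(source) -> KarstExtent:
    """Load an extent written by :func:`extent_to_geojson`."""
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            feature = json.load(fh)
    elif hasattr(source, "read"):
        feature = json.load(source)
    else:
        feature = source
    props = feature.get("properties", {})
    projection = projection_from_dict(props.get("projection", {"type": "planar_km"}))
    geom = shape(feature["geometry"])
    if isinstance(projection, AlbersEqualArea):
        geom = shp_transform(lambda x, y: projection.project(x, y), geom)
    return KarstExtent(label=props.get("label", "custom"), geometry=geom,
                       buffer_km=props.get("buffer_km", 0.0), projection=projection)
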