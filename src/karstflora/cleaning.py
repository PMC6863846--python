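"""Coordinate-validity filtering and taxonomic name reconciliation.

Occurrence aggregators accumulate characteristic georeferencing
artefacts — (0, 0) points, swapped or truncated coordinates, records
snapped to country centroids — and their verbatim names mix taxonomies.
This module applies a fixed, individually switchable sequence of
coordinate checks with full per-step accounting, resolves verbatim names
against a pre-flattened taxonomic backbone, and quantifies how two
backbones disagree (shared / synonymous / not-found), the bookkeeping a
checklist comparison table is built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NameBackbone",
    "CleaningOptions",
    "CleanReport",
    "CongruenceReport",
    "clean_coordinates",
    "resolve_names",
    "backbone_congruence",
    "CLEANING_STEPS",
]

#: mean kilometres per degree of latitude (spherical)
KM_PER_DEGREE = 111.195


def round1(value: float) -> float:
    """Round half-up to 1 decimal, as printed summary tables do."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"),
                                                      rounding=ROUND_HALF_UP))


class NameBackbone:
    """A flattened name backbone: name -> (status, accepted_name).

    Statuses are ``accepted`` (maps to itself), ``synonym`` (maps to its
    accepted name in one hop) or ``not_found``. Chains must be
    pre-flattened: a synonym's target may not itself be a synonym.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries = dict(entries)
        for name, (status, accepted) in self._entries.items():
            if status == "accepted" and accepted != name:
                raise ValueError(f"accepted name {name!r} must map to itself")
            if status == "synonym":
                tgt = self._entries.get(accepted)
                if tgt is not None and tgt[0] == "synonym":
                    raise ValueError(
                        f"backbone not flattened: {name!r} -> {accepted!r} -> ...")

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return self._normalise(name) in self._entries

    @staticmethod
    def _normalise(name: str) -> str:
        return " ".join(str(name).split())

    def status(self, name: str) -> str:
        entry = self._entries.get(self._normalise(name))
        return entry[0] if entry is not None else "not_found"

    def resolve(self, name: str) -> str | None:
        """Accepted name for ``name``, or None when unresolvable."""
        entry = self._entries.get(self._normalise(name))
        if entry is None or entry[0] == "not_found":
            return None
        return entry[1]

    def names(self) -> Iterable[str]:
        return self._entries.keys()

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(n, s, a) for n, (s, a) in sorted(self._entries.items())],
            columns=["name", "status", "accepted_name"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NameBackbone":
        df = pd.read_csv(path, keep_default_na=False)
        return cls({str(r.name): (str(r.status), str(r.accepted_name))
                    for r in df.itertuples(index=False)})


#: the coordinate-cleaning steps, in the order they are applied
CLEANING_STEPS = (
    "missing_or_zero",
    "out_of_range",
    "lat_equals_lon",
    "country_mismatch",
    "not_on_land",
    "near_country_centroid",
)


@dataclass(frozen=True)
class CleaningOptions:
    """Switches for the individual coordinate checks."""

    missing_or_zero: bool = True
    out_of_range: bool = True
    lat_equals_lon: bool = True
    country_mismatch: bool = True
    not_on_land: bool = True
    near_country_centroid: bool = True
    centroid_km: float = 10.0


@dataclass
class CleanReport:
    """Per-step tallies; input = retained + sum(removed)."""

    n_input: int
    removed: dict = field(default_factory=dict)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def percent_lost(self) -> float:
        if self.n_input == 0:
            return 0.0
        return round1(100.0 * self.n_removed / self.n_input)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "input", "count": self.n_input}]
        rows += [{"step": f"removed:{s}", "count": c} for s, c in self.removed.items()]
        rows.append({"step": "retained", "count": self.n_retained})
        rows.append({"step": "percent_lost", "count": self.percent_lost})
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"records in:        {self.n_input}"]
        for s, c in self.removed.items():
            lines.append(f"  - {s:<22s} {c}")
        lines.append(f"records retained:  {self.n_retained} "
                     f"({self.percent_lost}% lost)")
        return "\n".join(lines)


def _contains_points(geometry, lon, lat) -> np.ndarray:
    import shapely

    shapely.prepare(geometry)
    return np.atleast_1d(shapely.intersects(geometry, shapely.points(lon, lat)))


def clean_coordinates(records: pd.DataFrame,
                      land_polygons=None,
                      country_polygons: Mapping[str, object] | None = None,
                      options: CleaningOptions = CleaningOptions(),
                      ) -> tuple[pd.DataFrame, CleanReport]:
    """Apply the coordinate checks in fixed order with per-step tallies.

    ``land_polygons`` is a single (multi)polygon in WGS84 degrees;
    ``country_polygons`` maps a country name to its polygon. Steps whose
    reference data is absent are skipped and tallied as removing zero
    records, so the report always names every enabled step.
    """
    report = CleanReport(n_input=len(records))
    df = records.copy()
    lon = df["decimal_longitude"].to_numpy(dtype=float)
    lat = df["decimal_latitude"].to_numpy(dtype=float)
    alive = np.ones(len(df), dtype=bool)

    def drop(step: str, mask: np.ndarray) -> None:
        mask = mask & alive
        report.removed[step] = int(mask.sum())
        alive[mask] = False

    if options.missing_or_zero:
        drop("missing_or_zero",
             np.isnan(lon) | np.isnan(lat) | ((lon == 0.0) & (lat == 0.0)))
    if options.out_of_range:
        with np.errstate(invalid="ignore"):
            drop("out_of_range", (np.abs(lon) > 180.0) | (np.abs(lat) > 90.0))
    if options.lat_equals_lon:
        drop("lat_equals_lon", lat == lon)
    if options.country_mismatch:
        mask = np.zeros(len(df), dtype=bool)
        if country_polygons:
            countries = df["country"].astype(str).to_numpy()
            for name, poly in country_polygons.items():
                sel = alive & (countries == name)
                if sel.any():
                    inside = _contains_points(poly, lon[sel], lat[sel])
                    idx = np.flatnonzero(sel)
                    mask[idx[~inside]] = True
        drop("country_mismatch", mask)
    if options.not_on_land:
        mask = np.zeros(len(df), dtype=bool)
        if land_polygons is not None:
            on_land = _contains_points(land_polygons, lon[alive], lat[alive])
            idx = np.flatnonzero(alive)
            mask[idx[~on_land]] = True
        drop("not_on_land", mask)
    if options.near_country_centroid:
        mask = np.zeros(len(df), dtype=bool)
        if country_polygons:
            for poly in country_polygons.values():
                c = poly.centroid
                dlat = (lat - c.y) * KM_PER_DEGREE
                dlon = (lon - c.x) * KM_PER_DEGREE * np.cos(np.radians(lat))
                mask |= np.hypot(dlat, dlon) <= options.centroid_km
        drop("near_country_centroid", mask)

    retained = df.loc[alive].copy()
    report.n_retained = len(retained)
    return retained, report


def resolve_names(records: pd.DataFrame, backbone: NameBackbone,
                  name_column: str = "verbatim_name",
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill ``accepted_name`` from the backbone.

    Accepted names map to themselves, synonyms to their accepted name in
    one hop; names absent from the backbone are routed to the unresolved
    frame (excluded from analysis but preserved for audit).
    """
    accepted = records[name_column].map(backbone.resolve)
    resolved = records.loc[accepted.notna()].copy()
    resolved["accepted_name"] = accepted[accepted.notna()]
    unresolved = records.loc[accepted.isna()].copy()
    return resolved, unresolved


@dataclass(frozen=True)
class CongruenceReport:
    """How a name list fares against a backbone (checklist comparison).

    ``shared`` = accepted in the backbone, ``synonymous`` = surplus names
    the backbone sinks into other accepted names, ``not_found`` = absent.
    Percentages are of the total, half-up to 1 decimal.
    """

    total: int
    shared: int
    synonymous: int
    not_found: int

    def __post_init__(self):
        if self.shared + self.synonymous + self.not_found != self.total:
            raise ValueError("congruence counts do not sum to the total")

    @property
    def shared_pct(self) -> float:
        return round1(100.0 * self.shared / self.total)

    @property
    def synonymous_pct(self) -> float:
        return round1(100.0 * self.synonymous / self.total)

    @property
    def not_found_pct(self) -> float:
        return round1(100.0 * self.not_found / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"class": "shared", "count": self.shared, "percent": self.shared_pct},
            {"class": "synonymous", "count": self.synonymous,
             "percent": self.synonymous_pct},
            {"class": "not_found", "count": self.not_found,
             "percent": self.not_found_pct},
            {"class": "total", "count": self.total, "percent": 100.0},
        ])


def backbone_congruence(names: Iterable[str], backbone: NameBackbone
                        ) -> CongruenceReport:
    """Classify each name as shared / synonymous / not-found."""
    names = list(names)
    if not names:
        raise ValueError("name list is empty")
    statuses = [backbone.status(n) for n in names]
    shared = sum(s == "accepted" for s in statuses)
    synonymous = sum(s == "synonym" for s in statuses)
    not_found = sum(s == "not_found" for s in statuses)
    return CongruenceReport(total=len(names), shared=shared,
                            synonymous=synonymous, not_found=not_found)
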