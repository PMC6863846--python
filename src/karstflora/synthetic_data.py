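"""Synthetic occurrence landscapes with the statistical structure the
analysis assumes.

The generator emulates, at desk scale, the kind of inputs a continental
occurrence-data analysis consumes: a species pool with a reversed-J
range-size distribution (most species rare and narrow-ranged), spatially
biased collecting effort clustered around "herbarium towns", coordinate
uncertainty of 5 km on about half the records, a karst polygon map
covering a stated fraction of the landscape, taxonomic backbones that
disagree through synonymy, and a red-list table. Everything is
deterministic given the single integer seed in :class:`LandscapeSpec`;
each sub-generator draws from its own seeded stream so stages can be
regenerated independently.

The landscape lives in a planar equal-area plane in kilometres. When
records are written to CSV the planar coordinates are mapped to WGS84
decimal degrees through the South America Albers projection, anchored in
central Brazil, so the downstream pipeline exercises the same projection
machinery it would use on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union

from .cleaning import NameBackbone
from .karst_validation import DEFAULT_RULES
from .spatial_grid import AlbersEqualArea, KarstExtent, PlanarKm

__all__ = [
    "LandscapeSpec",
    "SpeciesPool",
    "gen_species_pool",
    "gen_occurrences",
    "gen_karst_polygons",
    "gen_backbones",
    "gen_redlist",
    "realized_single_cell_fraction",
    "write_occurrences_csv",
    "read_occurrences_csv",
    "write_redlist_csv",
    "read_redlist_csv",
]

#: nominal coarse grid-cell size the pool is calibrated against (km)
CELL_KM = 50.0

#: SW corner of the synthetic landscape in WGS84 (central Brazil);
#: used only when converting planar km to decimal degrees for CSV output.
ANCHOR_LON, ANCHOR_LAT = -58.0, -22.0


def anchor_origin_km() -> tuple[float, float]:
    """Projected (Albers) coordinates of the landscape's SW corner,
    snapped to the 50 km grid lattice so that grid anchoring is
    consistent between the planar landscape frame and the projected
    frame."""
    ax, ay = AlbersEqualArea().project(ANCHOR_LON, ANCHOR_LAT)
    return (CELL_KM * round(float(ax) / CELL_KM),
            CELL_KM * round(float(ay) / CELL_KM))

# stream labels so each sub-generator owns an independent seeded stream
_STREAMS = {"karst": 1, "pool": 2, "occurrences": 3, "backbones": 4, "redlist": 5}

_GENERA = (
    "Calcicola", "Petrophila", "Dolinaria", "Carstium", "Rupestris",
    "Lapidosa", "Cavernula", "Saxifraga", "Litholepis", "Cerradoa",
    "Chapadea", "Serrania", "Gruta", "Planaltoa", "Sertaneja",
    "Campestris", "Matagalia", "Brejoa", "Tabuleiroa", "Veredia",
)

_NEUTRAL_NOTES = (
    "floresta de terra firme",
    "cerrado sensu stricto",
    "campo sujo com arbustos",
    "mata ciliar, solo argiloso",
    "vegetacao secundaria em pastagem",
    "borda de estrada, solo arenoso",
    "capoeira alta",
    "margem de corrego",
)

_KARST_NOTE_TEMPLATES = (
    "afloramento de {kw}",
    "solo {kw} raso",
    "vegetacao sobre {kw}",
    "encosta com {kw} exposto",
)


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its target after bounded retries."""


def _check_proportion(name: str, value: float, lo=0.0, hi=1.0,
                      lo_open=False, hi_open=False) -> None:
    bad = (value < lo or value > hi
           or (lo_open and value == lo) or (hi_open and value == hi))
    if bad:
        raise ValueError(f"{name}={value!r} outside the allowed interval")


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic occurrence landscape.

    Defaults are the study conditions of the analysis: a 1000 x 800 km
    landscape (20 x 16 cells of 50 km), karst covering 6.5% of it, half
    the records carrying 5 km coordinate uncertainty, 40% of species
    narrow enough to fit a single 50 km cell, and a 16.6% synonym load in
    the second taxonomic backbone.
    """

    width_km: float = 1000.0
    height_km: float = 800.0
    n_species: int = 400
    n_records: int = 30_000
    single_cell_fraction: float = 0.40
    karst_fraction: float = 0.065
    effort_bias: float = 1.0
    coord_error_fraction: float = 0.5
    synonym_fraction: float = 0.166
    seed: int = 0
    n_effort_towns: int = 8
    effort_sigma_km: float = 60.0
    keyword_probability: float = 0.5
    min_records_per_species: int = 6

    def __post_init__(self):
        if self.width_km < 2 * CELL_KM or self.height_km < 2 * CELL_KM:
            raise ValueError("width_km and height_km must be >= 100 km (2x2 cells)")
        if self.n_species <= 0:
            raise ValueError(f"n_species={self.n_species} must be positive")
        if self.n_records < 0:
            raise ValueError(f"n_records={self.n_records} must be >= 0")
        _check_proportion("single_cell_fraction", self.single_cell_fraction)
        # blob placement becomes infeasible long before 1; cap at 0.5
        _check_proportion("karst_fraction", self.karst_fraction, 0.0, 0.5, lo_open=True)
        _check_proportion("coord_error_fraction", self.coord_error_fraction)
        _check_proportion("synonym_fraction", self.synonym_fraction)
        if self.effort_bias < 0:
            raise ValueError(f"effort_bias={self.effort_bias} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SpeciesPool:
    """True (unobserved) ranges behind the synthetic records.

    Ranges are discs: simple, and sufficient to induce a reversed-J
    distribution of occupied-cell counts once sampled.
    """

    names: tuple[str, ...]
    centre_x: np.ndarray
    centre_y: np.ndarray
    radius_km: np.ndarray
    abundance: np.ndarray
    karst_endemic: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.names,
            "centre_x_km": self.centre_x,
            "centre_y_km": self.centre_y,
            "radius_km": self.radius_km,
            "abundance": self.abundance,
            "karst_endemic": self.karst_endemic,
        })


def gen_karst_polygons(spec: LandscapeSpec) -> KarstExtent:
    """Random convex karst blobs covering ``karst_fraction`` of the landscape.

    Blobs are convex hulls of point clouds; they are unioned and clipped
    to the landscape until total area is within +-0.02 of the target
    fraction. Raises :class:`GenerationError` after 1,000 attempts.
    """
    rng = spec.rng("karst")
    landscape = box(0.0, 0.0, spec.width_km, spec.height_km)
    target = spec.karst_fraction * landscape.area
    tol = 0.02 * landscape.area
    blobs = []
    union = None
    for _ in range(1000):
        area = 0.0 if union is None else union.area
        if abs(area - target) <= tol and union is not None:
            break
        remaining = target - area
        if remaining <= 0:  # overshoot beyond tolerance cannot be undone
            raise GenerationError("karst blob placement overshot the target area")
        # blob radius aimed at the remaining deficit, capped for texture
        r = min(60.0, max(8.0, math.sqrt(remaining / math.pi) / 1.5))
        cx = rng.uniform(0, spec.width_km)
        cy = rng.uniform(0, spec.height_km)
        ang = rng.uniform(0, 2 * math.pi, 10)
        rad = r * np.sqrt(rng.uniform(0.3, 1.0, 10))
        blob = MultiPoint(np.column_stack([cx + rad * np.cos(ang),
                                           cy + rad * np.sin(ang)])).convex_hull
        blob = blob.intersection(landscape)
        if blob.is_empty or blob.area == 0:
            continue
        blobs.append(blob)
        union = unary_union(blobs)
    else:
        raise GenerationError(
            f"could not reach karst fraction {spec.karst_fraction} in 1,000 attempts")
    return KarstExtent(label="NBZ", geometry=union, projection=PlanarKm())


def gen_species_pool(spec: LandscapeSpec) -> SpeciesPool:
    """Draw the species pool: disc ranges plus log-skewed abundances.

    With probability ``single_cell_fraction`` a species is narrow: its
    disc is placed wholly inside one 50 km cell (radius < 25 km).
    Otherwise it is wide (radius 30-150 km), which cannot fit a single
    cell. The realised single-cell fraction therefore matches the target
    up to binomial noise.
    """
    rng = spec.rng("pool")
    n = spec.n_species
    karst = gen_karst_polygons(spec)

    names = tuple(
        f"{_GENERA[i % len(_GENERA)]} sp{i:04d}" for i in range(n)
    )
    narrow = rng.random(n) < spec.single_cell_fraction
    radius = np.empty(n)
    cx = np.empty(n)
    cy = np.empty(n)

    ncols = int(spec.width_km // CELL_KM)
    nrows = int(spec.height_km // CELL_KM)
    for i in range(n):
        if narrow[i]:
            r = rng.uniform(0.5, 20.0)
            col = rng.integers(0, ncols)
            row = rng.integers(0, nrows)
            # margin of r + 5 km keeps the whole disc, and any record
            # jittered by the 5 km coordinate error, inside one cell
            m = r + 5.0
            cx[i] = col * CELL_KM + rng.uniform(m, CELL_KM - m)
            cy[i] = row * CELL_KM + rng.uniform(m, CELL_KM - m)
            radius[i] = r
        else:
            radius[i] = rng.uniform(30.0, 150.0)
            cx[i] = rng.uniform(0, spec.width_km)
            cy[i] = rng.uniform(0, spec.height_km)

    # log-skewed relative abundances: few common, many rare
    weights = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    abundance = weights / weights.sum()

    import shapely

    shapely.prepare(karst.geometry)
    discs = shapely.buffer(shapely.points(cx, cy), radius, quad_segs=16)
    endemic = shapely.contains(karst.geometry, discs)

    return SpeciesPool(names=names, centre_x=cx, centre_y=cy,
                       radius_km=radius, abundance=abundance,
                       karst_endemic=np.asarray(endemic, dtype=bool))


def realized_single_cell_fraction(pool: SpeciesPool, cell_km: float = CELL_KM) -> float:
    """Fraction of species whose true disc lies within a single grid cell."""
    lo_col = np.floor((pool.centre_x - pool.radius_km) / cell_km)
    hi_col = np.floor((pool.centre_x + pool.radius_km) / cell_km)
    lo_row = np.floor((pool.centre_y - pool.radius_km) / cell_km)
    hi_row = np.floor((pool.centre_y + pool.radius_km) / cell_km)
    single = (lo_col == hi_col) & (lo_row == hi_row)
    return float(single.mean())


def _effort_weight(x, y, towns_x, towns_y, sigma, bias):
    w = np.ones_like(np.asarray(x, dtype=float))
    if bias > 0 and len(towns_x):
        for tx, ty in zip(towns_x, towns_y):
            d2 = (x - tx) ** 2 + (y - ty) ** 2
            w = w + bias * np.exp(-d2 / (2.0 * sigma**2))
    return w


def gen_occurrences(pool: SpeciesPool, spec: LandscapeSpec) -> pd.DataFrame:
    """Sample occurrence records from the pool under biased effort.

    Returns a DataFrame in the occurrence-CSV dialect plus planar-km
    helper columns (``x_km``/``y_km`` final coordinates, ``true_x_km``/
    ``true_y_km`` pre-jitter). Exactly ``round(coord_error_fraction * n)``
    records carry 5,000 m uncertainty with coordinates jittered by at
    most 5 km; records whose true point falls in karst carry, with
    probability ``keyword_probability``, one karst keyword in their
    habitat notes.
    """
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    rng = spec.rng("occurrences")
    n = spec.n_records
    cols = ["record_id", "verbatim_name", "decimal_longitude", "decimal_latitude",
            "coordinate_uncertainty_m", "country", "habitat_notes", "source",
            "x_km", "y_km", "true_x_km", "true_y_km"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    karst = gen_karst_polygons(spec)
    towns_x = rng.uniform(0, spec.width_km, spec.n_effort_towns)
    towns_y = rng.uniform(0, spec.height_km, spec.n_effort_towns)

    # per-species record counts: a guaranteed floor so the recorded
    # footprint reflects the true range, remainder multinomial by abundance
    floor = min(spec.min_records_per_species, n // len(pool))
    counts = np.full(len(pool), floor, dtype=np.int64)
    remainder = n - int(counts.sum())
    if remainder > 0:
        counts += rng.multinomial(remainder, pool.abundance)

    sp_idx = np.repeat(np.arange(len(pool)), counts)
    m = len(sp_idx)

    # candidate points uniform in each species' disc, thinned by the
    # effort surface through weighted subsampling of 4x candidates
    k = 4
    cand_sp = np.repeat(sp_idx, k)
    theta = rng.uniform(0, 2 * math.pi, m * k)
    rad = pool.radius_km[cand_sp] * np.sqrt(rng.uniform(0, 1, m * k))
    px = pool.centre_x[cand_sp] + rad * np.cos(theta)
    py = pool.centre_y[cand_sp] + rad * np.sin(theta)
    w = _effort_weight(px, py, towns_x, towns_y, spec.effort_sigma_km,
                       spec.effort_bias)
    x = np.empty(m)
    y = np.empty(m)
    pos = 0
    for i, c in enumerate(counts):
        if c == 0:
            continue
        sl = slice(np.searchsorted(cand_sp, i, "left"),
                   np.searchsorted(cand_sp, i, "right"))
        p = w[sl] / w[sl].sum()
        pick = rng.choice(np.arange(sl.start, sl.stop), size=c, replace=False, p=p)
        x[pos:pos + c] = px[pick]
        y[pos:pos + c] = py[pick]
        pos += c

    true_x, true_y = x.copy(), y.copy()

    # coordinate error: exact count, jitter within the declared 5 km
    n_err = round(spec.coord_error_fraction * m)
    uncertainty = np.zeros(m)
    if n_err:
        err_idx = rng.choice(m, size=n_err, replace=False)
        uncertainty[err_idx] = 5000.0
        jr = 5.0 * np.sqrt(rng.uniform(0, 1, n_err))
        ja = rng.uniform(0, 2 * math.pi, n_err)
        x[err_idx] = x[err_idx] + jr * np.cos(ja)
        y[err_idx] = y[err_idx] + jr * np.sin(ja)

    # habitat notes: karst keyword seeding at the true locality
    import shapely

    shapely.prepare(karst.geometry)
    in_karst = shapely.intersects(karst.geometry, shapely.points(true_x, true_y))
    keywords = [r.keyword for r in DEFAULT_RULES]
    notes = np.array([_NEUTRAL_NOTES[j] for j in rng.integers(0, len(_NEUTRAL_NOTES), m)],
                     dtype=object)
    seeded = in_karst & (rng.random(m) < spec.keyword_probability)
    for i in np.flatnonzero(seeded):
        kw = keywords[rng.integers(0, len(keywords))]
        tpl = _KARST_NOTE_TEMPLATES[rng.integers(0, len(_KARST_NOTE_TEMPLATES))]
        notes[i] = tpl.format(kw=kw)

    ax0, ay0 = anchor_origin_km()
    lon, lat = AlbersEqualArea().unproject(ax0 + x, ay0 + y)

    df = pd.DataFrame({
        "record_id": [f"syn{j:07d}" for j in range(m)],
        "verbatim_name": [pool.names[j] for j in sp_idx],
        "decimal_longitude": lon,
        "decimal_latitude": lat,
        "coordinate_uncertainty_m": uncertainty,
        "country": "Brazil",
        "habitat_notes": notes,
        "source": "synthetic",
        "x_km": x,
        "y_km": y,
        "true_x_km": true_x,
        "true_y_km": true_y,
    })
    return df


def gen_backbones(pool: SpeciesPool, spec: LandscapeSpec
                  ) -> tuple[NameBackbone, NameBackbone]:
    """Two taxonomic backbones over the pool's names.

    Backbone A accepts every generated name. Backbone B treats a random
    ``synonym_fraction`` of names as synonyms of other accepted names and
    a further 5% as not found, mirroring how independent checklists
    disagree through synonymy and coverage.
    """
    names = list(pool.names)
    backbone_a = NameBackbone({n: ("accepted", n) for n in names})
    if not names:
        return backbone_a, NameBackbone({})
    rng = spec.rng("backbones")
    n = len(names)
    perm = rng.permutation(n)
    n_syn = round(spec.synonym_fraction * n)
    n_nf = round(0.05 * n)
    syn_idx = set(int(i) for i in perm[:n_syn])
    nf_idx = set(int(i) for i in perm[n_syn:n_syn + n_nf])
    accepted = [names[i] for i in range(n) if i not in syn_idx and i not in nf_idx]
    entries = {}
    for i, name in enumerate(names):
        if i in syn_idx and accepted:
            entries[name] = ("synonym", accepted[rng.integers(0, len(accepted))])
        elif i in nf_idx or (i in syn_idx and not accepted):
            entries[name] = ("not_found", "")
        else:
            entries[name] = ("accepted", name)
    return backbone_a, NameBackbone(entries)


IUCN_CATEGORIES = ("EX", "EW", "CR", "EN", "VU", "NT", "LC")

#: per-species evaluation probabilities at the study conditions: the
#: relative frequencies of the red-list categories among all species
#: (most species are simply not evaluated).
DEFAULT_CATEGORY_PROBS: Mapping[str, float] = {
    "EX": 0.00015, "EW": 0.00006, "CR": 0.0016, "EN": 0.0046,
    "VU": 0.0079, "NT": 0.0013, "LC": 0.0217,
}


def gen_redlist(pool: SpeciesPool,
                category_probs: Mapping[str, float] = DEFAULT_CATEGORY_PROBS,
                seed: int | None = None,
                spec: LandscapeSpec | None = None) -> dict[str, str]:
    """Independently assign IUCN categories; unassigned = not evaluated."""
    probs = dict(category_probs)
    for cat, p in probs.items():
        if cat not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {cat!r}")
        if p < 0 or p > 1:
            raise ValueError(f"probability for {cat} out of range: {p}")
    total = sum(probs.values())
    if total > 1 + 1e-12:
        raise ValueError(f"category probabilities sum to {total} > 1")
    if spec is not None:
        rng = spec.rng("redlist")
    else:
        rng = np.random.default_rng(seed)
    cats = [c for c in IUCN_CATEGORIES if probs.get(c, 0) > 0]
    p = np.array([probs[c] for c in cats] + [max(0.0, 1.0 - total)])
    p = p / p.sum()
    out: dict[str, str] = {}
    draws = rng.choice(len(cats) + 1, size=len(pool), p=p)
    for name, d in zip(pool.names, draws):
        if d < len(cats):
            out[name] = cats[d]
    return out


# ---------------------------------------------------------------------------
# CSV dialect

OCCURRENCE_COLUMNS = (
    "record_id", "verbatim_name", "decimal_longitude", "decimal_latitude",
    "coordinate_uncertainty_m", "country", "habitat_notes", "source",
)


def write_occurrences_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, list(OCCURRENCE_COLUMNS)].to_csv(path, index=False)


def read_occurrences_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"record_id": str, "verbatim_name": str,
                                    "country": str, "habitat_notes": str,
                                    "source": str})


def write_redlist_csv(redlist: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(redlist.items()),
                 columns=["accepted_name", "category"]).to_csv(path, index=False)


def read_redlist_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["accepted_name"], df["category"]))
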