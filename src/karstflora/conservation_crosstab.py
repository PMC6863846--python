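"""Cross-tabulation of species lists against IUCN Red List categories.

Given species sets per spatial extent (country total, study area, karst
with and without buffer) and a table of assessed species, this module
builds the two summary tables a conservation overview rests on: a
per-category cross-tab with a "Conservation concern" roll-up, and a
general extent-comparison table (area, records, taxa, endemics, maximum
cell richness), each expressed as counts plus percentages of the
country-total column.
"""

from __future__ import annotations

from typing import Mapping, Set

import pandas as pd

from .cleaning import round1

__all__ = ["iucn_crosstab", "summary_table", "CONCERN_CATEGORIES", "IUCN_ORDER"]

IUCN_ORDER = ("EX", "EW", "CR", "EN", "VU", "NT")

#: "conservation concern" is every assessed category above LC; NT is
#: included by default (the roll-up equals the sum of the six category
#: rows), with a switch for the stricter EX-VU-only reading.
CONCERN_CATEGORIES = IUCN_ORDER


def iucn_crosstab(species_sets: Mapping[str, Set[str]],
                  redlist: Mapping[str, str],
                  include_nt: bool = True) -> pd.DataFrame:
    """Counts and percentages of red-listed species per extent.

    ``species_sets`` maps extent name -> species set; the first entry is
    the reference column (country total) all percentages are computed
    against. Returns one row per category plus the "Conservation
    concern" roll-up, LC, and the evaluated "Total". Empty extents yield
    zero rows, not errors.
    """
    extents = list(species_sets)
    if not extents:
        raise ValueError("no extents given")
    reference = extents[0]
    concern = CONCERN_CATEGORIES if include_nt else tuple(
        c for c in CONCERN_CATEGORIES if c != "NT")

    per_cat: dict[str, dict[str, int]] = {}
    for extent, species in species_sets.items():
        cats = [redlist[s] for s in species if s in redlist]
        for cat in IUCN_ORDER + ("LC",):
            per_cat.setdefault(cat, {})[extent] = sum(c == cat for c in cats)

    rows = list(IUCN_ORDER) + ["Conservation concern", "LC", "Total"]
    data: dict[tuple, list] = {}
    for extent in extents:
        counts = []
        for cat in IUCN_ORDER:
            counts.append(per_cat[cat][extent])
        concern_count = sum(per_cat[c][extent] for c in concern)
        lc = per_cat["LC"][extent]
        total = sum(per_cat[c][extent] for c in IUCN_ORDER) + lc
        counts += [concern_count, lc, total]
        data[(extent, "count")] = counts
    for extent in extents:
        ref = data[(reference, "count")]
        data[(extent, "percent")] = [
            round1(100.0 * c / r) if r else 0.0
            for c, r in zip(data[(extent, "count")], ref)
        ]
    df = pd.DataFrame(data, index=rows)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["extent", "measure"])
    df.index.name = "category"
    df.attrs["include_nt"] = include_nt
    df.attrs["footer"] = (
        "Conservation concern = EX+EW+CR+EN+VU" + ("+NT" if include_nt else "") +
        "; percentages are of the first (reference) column."
    )
    return df


SUMMARY_ROWS = ("area_km2", "n_records", "n_taxa", "n_endemics",
                "max_cell_richness")


def summary_table(extent_metrics: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Extent comparison table: each metric as value and % of the first
    (reference) column.

    ``extent_metrics`` maps extent name -> {area_km2, n_records, n_taxa,
    n_endemics, max_cell_richness}; missing metrics are reported as NaN.
    """
    extents = list(extent_metrics)
    if not extents:
        raise ValueError("no extents given")
    reference = extents[0]
    data: dict[tuple, list] = {}
    for extent in extents:
        data[(extent, "value")] = [extent_metrics[extent].get(k, float("nan"))
                                   for k in SUMMARY_ROWS]
    ref = data[(reference, "value")]
    for extent in extents:
        data[(extent, "percent")] = [
            round1(100.0 * v / r) if r else float("nan")
            for v, r in zip(data[(extent, "value")], ref)
        ]
    df = pd.DataFrame(data, index=list(SUMMARY_ROWS))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["extent", "measure"])
    df.index.name = "parameter"
    return df


def format_table(df: pd.DataFrame) -> str:
    """Aligned-text rendering of a crosstab/summary table."""
    return df.to_string(float_format=lambda v: f"{v:.1f}")
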