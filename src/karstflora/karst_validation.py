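"""Validation of a karst map against collection-label metadata.

Herbarium labels often mention the substrate ("solo calcário", "afloramento
de limestone", "gruta"). Filtering occurrence records on such keywords gives
an independent line of evidence on where karst actually outcrops, which can
be overlaid on a geological karst map to check its completeness.

Keywords fall in three classes with different reliability:

* ``carbonate`` — terms exclusively associated with carbonate substrate
  (limestone, dolomite, 'calcário' and spelling variants, 'karst'/'carste'
  and adjectives). Records are retained unconditionally.
* ``doline`` — sinkhole terms ('dolina'/'doline'); dolines occur in other
  rock types, so records are retained only when they fall inside mapped
  karst polygons.
* ``cave`` — cave terms ('cave', 'caverna', 'gruta'); caves also occur in
  e.g. sandstone, so records are retained only within 1 km of a
  carbonate-class record or of mapped karst.

Matching is case-insensitive, accent-folded and on word boundaries, so
'Calcário' and 'calcario' are the same token and 'cave' does not match
inside 'excavation'.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .spatial_grid import KarstExtent

__all__ = [
    "KeywordRule",
    "DEFAULT_RULES",
    "KARST_KEYWORDS",
    "ValidationReport",
    "keyword_filter",
    "proximity_filter",
    "overlay_congruence",
    "fold",
]

#: class precedence when one label matches several keywords: the class
#: carrying the strongest evidence of carbonate substrate wins.
CLASS_PRIORITY = ("carbonate", "doline", "cave")


@dataclass(frozen=True)
class KeywordRule:
    keyword: str
    keyword_class: str  # carbonate | doline | cave

    def __post_init__(self):
        if self.keyword_class not in CLASS_PRIORITY:
            raise ValueError(f"unknown keyword class {self.keyword_class!r}")


# The karst keyword list used to mine collection labels. Spelling variants
# (masculine/feminine, accented/unaccented, Portuguese/Spanish/English) are
# kept explicit even though accent folding collapses some of them.
DEFAULT_RULES: tuple[KeywordRule, ...] = tuple(
    KeywordRule(k, "carbonate")
    for k in (
        "calcario", "calcário", "calcaria", "calcária",
        "calcareo", "calcáreo", "calcarea", "calcárea",
        "calcareous", "caliza", "limestone",
        "dolomito", "dolomite",
        "carste", "karst", "carstica", "cárstica", "carstico", "cárstico",
    )
) + tuple(
    KeywordRule(k, "doline") for k in ("dolina", "doline")
) + tuple(
    KeywordRule(k, "cave") for k in ("cave", "caverna", "gruta")
)

KARST_KEYWORDS: tuple[str, ...] = tuple(r.keyword for r in DEFAULT_RULES)


def fold(text: str) -> str:
    """Lower-case and strip combining accents (NFKD fold)."""
    decomposed = unicodedata.normalize("NFKD", str(text))
    return "".join(c for c in decomposed if not unicodedata.combining(c)).lower()


def _compile(rules) -> list[tuple[KeywordRule, re.Pattern]]:
    compiled = []
    for rule in rules:
        pat = re.compile(r"(?<!\w)" + re.escape(fold(rule.keyword)) + r"(?!\w)")
        compiled.append((rule, pat))
    return compiled


@dataclass
class ValidationReport:
    """Bookkeeping for the keyword/proximity validation of a karst map."""

    matched_per_keyword: dict = field(default_factory=dict)
    retained_per_class: dict = field(default_factory=dict)
    excluded_per_class: dict = field(default_factory=dict)
    congruence_inside: float = float("nan")
    congruence_within_threshold: float = float("nan")
    distance_threshold_km: float = float("nan")
    candidate_records: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"matched[{k}]", "value": v}
            for k, v in sorted(self.matched_per_keyword.items())
        ]
        for cls in CLASS_PRIORITY:
            rows.append({"metric": f"retained[{cls}]",
                         "value": self.retained_per_class.get(cls, 0)})
            rows.append({"metric": f"excluded[{cls}]",
                         "value": self.excluded_per_class.get(cls, 0)})
        rows.append({"metric": "congruence_inside", "value": self.congruence_inside})
        rows.append({"metric": "congruence_within_threshold",
                     "value": self.congruence_within_threshold})
        rows.append({"metric": "n_candidate_outcrops",
                     "value": len(self.candidate_records)})
        return pd.DataFrame(rows)


def keyword_filter(records: pd.DataFrame, rules=DEFAULT_RULES,
                   notes_column: str = "habitat_notes") -> pd.DataFrame:
    """Tag records whose habitat notes mention a karst keyword.

    Returns the matching subset with two added columns:
    ``matched_keywords`` (comma-joined, accent-folded, in rule order) and
    ``keyword_class`` (the highest-priority class among the matches).
    """
    compiled = _compile(rules)
    folded = records[notes_column].fillna("").map(fold)
    matched_lists: list[str] = []
    classes: list[str] = []
    keep = np.zeros(len(records), dtype=bool)
    for i, text in enumerate(folded):
        hits = [rule for rule, pat in compiled if pat.search(text)]
        if not hits:
            continue
        # folding collapses spelling variants; report each folded form once
        seen: dict[str, None] = {}
        for r in hits:
            seen.setdefault(fold(r.keyword))
        keep[i] = True
        matched_lists.append(",".join(seen))
        classes.append(min((r.keyword_class for r in hits),
                           key=CLASS_PRIORITY.index))
    out = records.loc[keep].copy()
    out["matched_keywords"] = matched_lists
    out["keyword_class"] = classes
    return out


def proximity_filter(tagged: pd.DataFrame, karst: KarstExtent | None,
                     x_column: str = "x_km", y_column: str = "y_km",
                     anchor_radius_km: float = 1.0,
                     ) -> tuple[pd.DataFrame, ValidationReport]:
    """Apply the class-specific retention rules to keyword-tagged records.

    carbonate: always retained. cave: retained iff within
    ``anchor_radius_km`` (projected distance) of a carbonate record or of
    mapped karst. doline: retained iff inside mapped karst. Every excluded
    record is annotated with the rule that excluded it.
    """
    report = ValidationReport()
    for kws in tagged.get("matched_keywords", pd.Series(dtype=str)):
        for k in str(kws).split(","):
            if k:
                report.matched_per_keyword[k] = report.matched_per_keyword.get(k, 0) + 1

    cls = tagged["keyword_class"].to_numpy()
    x = tagged[x_column].to_numpy(dtype=float)
    y = tagged[y_column].to_numpy(dtype=float)
    pts = shapely.points(x, y)

    carb = cls == "carbonate"
    retained = carb.copy()
    reason = np.array([""] * len(tagged), dtype=object)

    if karst is not None and not karst.geometry.is_empty:
        shapely.prepare(karst.geometry)
        inside = shapely.intersects(karst.geometry, pts)
        near_karst = shapely.dwithin(karst.geometry, pts, anchor_radius_km)
    else:
        inside = np.zeros(len(tagged), dtype=bool)
        near_karst = np.zeros(len(tagged), dtype=bool)

    anchors = shapely.multipoints(np.column_stack([x[carb], y[carb]])) if carb.any() else None
    if anchors is not None:
        shapely.prepare(anchors)
        near_anchor = shapely.dwithin(anchors, pts, anchor_radius_km)
    else:
        near_anchor = np.zeros(len(tagged), dtype=bool)

    cave = cls == "cave"
    retained |= cave & (near_anchor | near_karst)
    reason[cave & ~(near_anchor | near_karst)] = (
        f"cave-class beyond {anchor_radius_km:g} km of carbonate record or mapped karst"
    )
    doline = cls == "doline"
    retained |= doline & inside
    reason[doline & ~inside] = "doline-class outside mapped karst (AUTO polygon check)"

    if karst is None and not carb.any():
        # no anchors, no polygons: nothing conditional can be confirmed
        import warnings

        warnings.warn("no carbonate anchors and no karst polygons; "
                      "all conditional records excluded", stacklevel=2)

    for c in CLASS_PRIORITY:
        m = cls == c
        report.retained_per_class[c] = int((m & retained).sum())
        report.excluded_per_class[c] = int((m & ~retained).sum())

    out = tagged.loc[retained].copy()
    excluded = tagged.loc[~retained].copy()
    excluded["exclusion_rule"] = reason[~retained]
    out.attrs["excluded"] = excluded
    return out, report


def overlay_congruence(retained: pd.DataFrame, karst: KarstExtent,
                       distance_threshold_km: float = 5.0,
                       x_column: str = "x_km", y_column: str = "y_km",
                       ) -> ValidationReport:
    """Overlay retained keyword records on the karst map.

    Reports the fraction inside the mapped extent, the fraction within a
    distance threshold of it, and the records beyond the threshold — the
    candidate undocumented outcrops.
    """
    if len(retained) == 0:
        raise ValueError("retained record set is empty")
    pts = shapely.points(retained[x_column].to_numpy(dtype=float),
                         retained[y_column].to_numpy(dtype=float))
    shapely.prepare(karst.geometry)
    inside = shapely.intersects(karst.geometry, pts)
    within = shapely.dwithin(karst.geometry, pts, distance_threshold_km)
    report = ValidationReport(
        congruence_inside=float(inside.mean()),
        congruence_within_threshold=float(within.mean()),
        distance_threshold_km=distance_threshold_km,
        candidate_records=list(retained.loc[~within, "record_id"])
        if "record_id" in retained else list(retained.index[~within]),
    )
    return report


def rules_to_csv(path, rules=DEFAULT_RULES) -> None:
    pd.DataFrame([{"keyword": r.keyword, "class": r.keyword_class}
                  for r in rules]).to_csv(path, index=False)


def rules_from_csv(path) -> tuple[KeywordRule, ...]:
    df = pd.read_csv(path)
    return tuple(KeywordRule(str(k), str(c))
                 for k, c in zip(df["keyword"], df["class"]))
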