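"""End-to-end orchestration of the karst-flora analysis.

Stages communicate only through files in the output directory (CSV,
GeoJSON, JSON), never by in-memory handoff, so any stage can be rerun,
audited or swapped in isolation. Every stage writes a manifest recording
its seed and the SHA-256 of each input it consumed; identical config and
seed reproduce byte-identical outputs.

Stage order: simulate -> clean -> grid -> richness -> endemism ->
validate_karst -> conservation -> report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import cleaning, conservation_crosstab, endemism_range
from . import karst_validation as kv
from . import richness_sar, spatial_grid, synthetic_data
from .spatial_grid import AlbersEqualArea, EqualAreaGrid, KarstExtent
from .synthetic_data import LandscapeSpec

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES", "DependencyError"]

STAGES = ("simulate", "clean", "grid", "richness", "endemism",
          "validate_karst", "conservation", "report")


class DependencyError(RuntimeError):
    """An upstream stage output required by this stage is missing."""


@dataclass
class PipelineConfig:
    """Resolved settings for a full run; defaults are the analysis
    defaults (5 km buffer, 1,000 richness draws, 2,000 endemism draws,
    1,000 resampling samples, alpha 0.05)."""

    outdir: str = "karstflora_run"
    seed: int = 0
    synthetic: LandscapeSpec = field(default_factory=LandscapeSpec)
    buffer_km: float = 5.0
    cell_km: float = 50.0
    subcell_km: float = 10.0
    n_permutations: int = 100
    n_draws_richness: int = 1000
    n_draws_we: int = 2000
    n_samples_ttest: int = 1000
    alpha: float = 0.05
    congruence_threshold_km: float = 5.0

    def __post_init__(self):
        if self.seed != self.synthetic.seed:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        syn = d.pop("synthetic", {})
        cfg = cls(**{k: v for k, v in d.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if syn:
            cfg.synthetic = LandscapeSpec(**syn)
            cfg.seed = d.get("seed", cfg.synthetic.seed)
            cfg.__post_init__()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: PipelineConfig, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = config.out / name
        if not p.exists():
            raise DependencyError(
                f"missing upstream output {p}; run the producing stage first")
        paths.append(p)
    return paths


def _manifest(config: PipelineConfig, stage: str, inputs: list[Path],
              outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    with open(config.out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig) -> list[Path]:
    spec = config.synthetic
    out = config.out
    pool = synthetic_data.gen_species_pool(spec)
    records = synthetic_data.gen_occurrences(pool, spec)
    karst = synthetic_data.gen_karst_polygons(spec)
    backbone_a, backbone_b = synthetic_data.gen_backbones(pool, spec)
    redlist = synthetic_data.gen_redlist(pool, spec=spec)

    # the karst map is exported in WGS84, as a real geological map would be
    albers = AlbersEqualArea()
    ax0, ay0 = synthetic_data.anchor_origin_km()
    from shapely import affinity

    geo = affinity.translate(karst.geometry, xoff=ax0, yoff=ay0)
    karst_albers = KarstExtent(label="NBZ", geometry=geo, projection=albers)

    outputs = []
    synthetic_data.write_occurrences_csv(records, out / "occurrences.csv")
    outputs.append(out / "occurrences.csv")
    spatial_grid.extent_to_geojson(karst_albers, out / "karst_nbz.geojson")
    outputs.append(out / "karst_nbz.geojson")
    backbone_a.to_csv(out / "backbone_a.csv")
    backbone_b.to_csv(out / "backbone_b.csv")
    synthetic_data.write_redlist_csv(redlist, out / "redlist.csv")
    pool.to_frame().to_csv(out / "species_pool.csv", index=False)
    outputs += [out / "backbone_a.csv", out / "backbone_b.csv",
                out / "redlist.csv", out / "species_pool.csv"]
    return outputs


def _land_polygon(config: PipelineConfig):
    """Generous land box around the synthetic landscape, in degrees."""
    albers = AlbersEqualArea()
    ax0, ay0 = synthetic_data.anchor_origin_km()
    spec = config.synthetic
    margin = 300.0
    corners_x = np.array([-margin, spec.width_km + margin,
                          spec.width_km + margin, -margin]) + ax0
    corners_y = np.array([-margin, -margin,
                          spec.height_km + margin, spec.height_km + margin]) + ay0
    lon, lat = albers.unproject(corners_x, corners_y)
    return box(float(lon.min()), float(lat.min()), float(lon.max()), float(lat.max()))


def _stage_clean(config: PipelineConfig) -> list[Path]:
    out = config.out
    (occ_path, bb_path) = _require(config, "occurrences.csv", "backbone_b.csv")
    records = synthetic_data.read_occurrences_csv(occ_path)
    backbone_b = cleaning.NameBackbone.from_csv(bb_path)
    backbone_a = cleaning.NameBackbone.from_csv(
        *_require(config, "backbone_a.csv"))

    land = _land_polygon(config)
    retained, clean_report = cleaning.clean_coordinates(
        records, land_polygons=land, country_polygons={"Brazil": land})
    resolved, unresolved = cleaning.resolve_names(retained, backbone_b)

    names = sorted(pd.unique(records["verbatim_name"]))
    congruence = {
        "backbone_a": cleaning.backbone_congruence(names, backbone_a),
        "backbone_b": cleaning.backbone_congruence(names, backbone_b),
    }

    resolved.to_csv(out / "occurrences_clean.csv", index=False)
    unresolved.to_csv(out / "occurrences_unresolved.csv", index=False)
    clean_report.to_frame().to_csv(out / "clean_report.csv", index=False)
    cong = pd.concat({k: v.to_frame() for k, v in congruence.items()},
                     names=["backbone"]).reset_index(level=0)
    cong.to_csv(out / "congruence_report.csv", index=False)
    return [out / "occurrences_clean.csv", out / "occurrences_unresolved.csv",
            out / "clean_report.csv", out / "congruence_report.csv"]


def _stage_grid(config: PipelineConfig) -> list[Path]:
    out = config.out
    (clean_path, karst_path) = _require(config, "occurrences_clean.csv",
                                        "karst_nbz.geojson")
    records = pd.read_csv(clean_path)
    nbz = spatial_grid.extent_from_geojson(karst_path)
    bz5 = spatial_grid.buffer_extent(nbz, config.buffer_km)
    study = spatial_grid.bounding_box(bz5)

    grid50 = EqualAreaGrid.from_extent(study, config.cell_km)
    ratio = int(round(config.cell_km / config.subcell_km))
    grid10 = EqualAreaGrid(grid50.origin_x, grid50.origin_y,
                           config.cell_km / ratio, grid50.projection)

    proj = nbz.projection
    x, y = proj.project(records["decimal_longitude"].to_numpy(dtype=float),
                        records["decimal_latitude"].to_numpy(dtype=float))
    records["x_km"] = x
    records["y_km"] = y
    records = richness_sar.add_cell_indices(records, grid50)
    c10, r10 = grid10.cell_index(x, y)
    records["subcell_col"] = c10
    records["subcell_row"] = r10
    records["in_nbz"] = nbz.contains_points(x, y)
    records["in_bz5"] = bz5.contains_points(x, y)
    records["in_study"] = study.contains_points(x, y)

    records.to_csv(out / "occurrences_gridded.csv", index=False)
    spatial_grid.extent_to_geojson(bz5, out / "karst_bz5.geojson")
    spatial_grid.extent_to_geojson(study, out / "study_area.geojson")
    with open(out / "grid.json", "w") as fh:
        json.dump({"grid50": grid50.to_dict(), "grid10": grid10.to_dict(),
                   "areas_km2": {"NBZ": nbz.area_km2, "BZ5": bz5.area_km2,
                                 "study_area": study.area_km2}},
                  fh, indent=2, sort_keys=True)
    return [out / "occurrences_gridded.csv", out / "karst_bz5.geojson",
            out / "study_area.geojson", out / "grid.json"]


def _load_gridded(config: PipelineConfig) -> pd.DataFrame:
    (path,) = _require(config, "occurrences_gridded.csv")
    return pd.read_csv(path)


def _grids(config: PipelineConfig) -> tuple[EqualAreaGrid, EqualAreaGrid]:
    (path,) = _require(config, "grid.json")
    with open(path) as fh:
        d = json.load(fh)
    return (EqualAreaGrid.from_dict(d["grid50"]), EqualAreaGrid.from_dict(d["grid10"]))


_EXTENT_FLAGS = {"study_area": "in_study", "NBZ": "in_nbz", "BZ5": "in_bz5"}


def _stage_richness(config: PipelineConfig) -> list[Path]:
    out = config.out
    records = _load_gridded(config)
    grid50, grid10 = _grids(config)
    rng = np.random.default_rng([config.seed, 101])
    outputs = []

    cells = {}
    for extent, flag in _EXTENT_FLAGS.items():
        sub = records.loc[records[flag]]
        cm = richness_sar.cell_richness(sub)
        cells[extent] = cm
        reg = (richness_sar.effort_regression(cm)
               if (cm["record_count"] > 0).sum() >= 3 else None)
        cm = cm.copy()
        cm.attrs["effort_regression"] = reg
        path = out / f"cell_metrics_{extent}.csv"
        cm.reset_index().to_csv(path, index=False)
        outputs.append(path)

    regs = []
    for extent in _EXTENT_FLAGS:
        cm = cells[extent]
        if (cm["record_count"] > 0).sum() >= 3:
            r = richness_sar.effort_regression(cm)
            regs.append({"extent": extent, "slope": r.slope,
                         "intercept": r.intercept, "r_squared": r.r_squared,
                         "n_cells": r.n_cells})
    pd.DataFrame(regs).to_csv(out / "effort_regression.csv", index=False)
    outputs.append(out / "effort_regression.csv")

    curve = richness_sar.accumulation_curve(
        records.loc[records["in_study"]], n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31)))
    curve.to_frame().to_csv(out / "accumulation_study.csv", index=False)
    outputs.append(out / "accumulation_study.csv")

    null_rows = []
    tt_rows = []
    for extent in ("NBZ", "BZ5"):
        sub = records.loc[records[_EXTENT_FLAGS[extent]]]
        if len(sub) == 0:
            continue
        null = richness_sar.null_richness(
            sub, grid50, grid10, n_draws=config.n_draws_richness,
            seed=int(rng.integers(2**31)))
        observed = cells[extent]["richness"]
        classes = richness_sar.classify_outliers(observed, null)
        nf = null.to_frame()
        nf["observed_richness"] = [
            int(observed.get(c, 0)) for c in null.cells]
        nf["outlier_class"] = [classes.get(c, 0) for c in null.cells]
        nf.insert(0, "extent", extent)
        null_rows.append(nf)
        null_rows_summary = {
            "extent": extent,
            "z_mean": null.z_mean, "z_sd": null.z_sd,
            "mean_expected_mean": float(np.nanmean(null.mean_expected_per_draw)),
            "mean_expected_sd": float(np.nanstd(null.mean_expected_per_draw, ddof=1)),
        }
        pd.DataFrame([null_rows_summary]).to_csv(
            out / f"null_summary_{extent}.csv", index=False)
        outputs.append(out / f"null_summary_{extent}.csv")

        test = richness_sar.resample_extent_test(
            cells["study_area"]["richness"].to_numpy(dtype=float),
            observed.to_numpy(dtype=float),
            n_samples=config.n_samples_ttest, seed=int(rng.integers(2**31)))
        row = {"comparison": f"richness:{extent}-vs-study_area",
               "observed": test.observed,
               "replicate_mean": float(test.replicates.mean()),
               "t": test.t, "df": test.df, "p_value": test.p_value,
               "p_empirical": test.p_empirical}
        tt_rows.append(row)

    if null_rows:
        pd.concat(null_rows).to_csv(out / "null_richness_cells.csv", index=False)
        outputs.append(out / "null_richness_cells.csv")
    pd.DataFrame(tt_rows).to_csv(out / "richness_ttests.csv", index=False)
    outputs.append(out / "richness_ttests.csv")
    return outputs


def _stage_endemism(config: PipelineConfig) -> list[Path]:
    out = config.out
    records = _load_gridded(config)
    _require(config, "cell_metrics_study_area.csv")
    rng = np.random.default_rng([config.seed, 202])
    outputs = []

    ranges = {}
    we_cells = {}
    for extent, flag in _EXTENT_FLAGS.items():
        sub = records.loc[records[flag]]
        if len(sub) == 0:
            continue
        rt = endemism_range.range_sizes(sub, extent_label=extent)
        ranges[extent] = rt
        rt.to_frame().to_csv(out / f"range_sizes_{extent}.csv", index=False)
        outputs.append(out / f"range_sizes_{extent}.csv")
        cells = endemism_range.weighted_endemism(sub, rt)
        cells = endemism_range.we_randomization(
            cells, rt.sizes.to_numpy(dtype=float), n_draws=config.n_draws_we,
            alpha=config.alpha, seed=int(rng.integers(2**31)))
        we_cells[extent] = cells
        cells.reset_index().to_csv(out / f"endemism_cells_{extent}.csv", index=False)
        outputs.append(out / f"endemism_cells_{extent}.csv")

    # small-range statistics, on both range-size bases
    sr_rows = []
    for extent, rt in ranges.items():
        count, prop = endemism_range.small_range_stats(rt)
        sr_rows.append({"extent": extent, "basis": "extent-restricted",
                        "n_small_range": count, "proportion": prop})
    study_rt = ranges.get("study_area")
    if study_rt is not None:
        for extent in ("NBZ", "BZ5"):
            if extent not in ranges:
                continue
            karst_species = ranges[extent].sizes.index
            wide = study_rt.sizes.loc[study_rt.sizes.index.isin(karst_species)]
            sr_rows.append({
                "extent": extent, "basis": "study-area ranges",
                "n_small_range": int((wide == 1).sum()),
                "proportion": float((wide == 1).mean()),
            })
    pd.DataFrame(sr_rows).to_csv(out / "small_range_stats.csv", index=False)
    outputs.append(out / "small_range_stats.csv")

    # resampling test on the per-sample proportion of small-range species
    tt_rows = []
    if study_rt is not None:
        study_cells = records.loc[records["in_study"]].groupby(
            ["cell_col", "cell_row"])["accepted_name"].agg(set)
        sizes = study_rt.sizes

        def prop_small(cell_sets) -> float:
            species = set().union(*cell_sets) if len(cell_sets) else set()
            if not species:
                return 0.0
            r = sizes.loc[sorted(species)]
            return float((r == 1).mean())

        for extent in ("NBZ", "BZ5"):
            if extent not in ranges:
                continue
            karst_cells = records.loc[records[_EXTENT_FLAGS[extent]]].groupby(
                ["cell_col", "cell_row"])["accepted_name"].agg(set)
            test = richness_sar.resample_extent_test(
                study_cells.to_numpy(dtype=object),
                karst_cells.to_numpy(dtype=object),
                n_samples=config.n_samples_ttest,
                seed=int(rng.integers(2**31)), statistic=prop_small)
            tt_rows.append({"comparison": f"small_range_prop:{extent}-vs-study_area",
                            "observed": test.observed,
                            "replicate_mean": float(test.replicates.mean()),
                            "t": test.t, "df": test.df, "p_value": test.p_value,
                            "p_empirical": test.p_empirical})
    pd.DataFrame(tt_rows).to_csv(out / "small_range_ttests.csv", index=False)
    outputs.append(out / "small_range_ttests.csv")

    # extent endemics and the log-log endemics-vs-area comparison
    with open(*_require(config, "grid.json")) as fh:
        areas = json.load(fh)["areas_km2"]
    end_rows = []
    pairs, labels = [], []
    for extent, flag in _EXTENT_FLAGS.items():
        endemics = endemism_range.extent_endemics(records, inside=records[flag])
        end_rows.append({"extent": extent, "n_endemics": len(endemics)})
        if len(endemics) > 0:
            pairs.append((areas[extent], len(endemics)))
            labels.append(extent)
    pd.DataFrame(end_rows).to_csv(out / "extent_endemics.csv", index=False)
    outputs.append(out / "extent_endemics.csv")
    lae = endemism_range.log_area_endemics(pairs, labels)
    lae.to_csv(out / "log_area_endemics.csv", index=False)
    outputs.append(out / "log_area_endemics.csv")
    return outputs


def _stage_validate_karst(config: PipelineConfig) -> list[Path]:
    out = config.out
    records = _load_gridded(config)
    (karst_path,) = _require(config, "karst_nbz.geojson")
    nbz = spatial_grid.extent_from_geojson(karst_path)
    tagged = kv.keyword_filter(records)
    retained, report = kv.proximity_filter(tagged, nbz)
    if len(retained):
        overlay = kv.overlay_congruence(retained, nbz,
                                        config.congruence_threshold_km)
        report.congruence_inside = overlay.congruence_inside
        report.congruence_within_threshold = overlay.congruence_within_threshold
        report.distance_threshold_km = overlay.distance_threshold_km
        report.candidate_records = overlay.candidate_records
    retained.to_csv(out / "karst_keyword_records.csv", index=False)
    report.to_frame().to_csv(out / "validation_report.csv", index=False)
    return [out / "karst_keyword_records.csv", out / "validation_report.csv"]


def _stage_conservation(config: PipelineConfig) -> list[Path]:
    out = config.out
    records = _load_gridded(config)
    (redlist_path,) = _require(config, "redlist.csv")
    redlist = synthetic_data.read_redlist_csv(redlist_path)
    with open(*_require(config, "grid.json")) as fh:
        areas = json.load(fh)["areas_km2"]

    species_sets = {"Brazil": set(records["accepted_name"])}
    for extent, flag in _EXTENT_FLAGS.items():
        species_sets[extent] = set(records.loc[records[flag], "accepted_name"])
    # reference column first, then nested extents small to large
    ordered = {k: species_sets[k] for k in
               ("Brazil", "NBZ", "BZ5", "study_area")}
    crosstab = conservation_crosstab.iucn_crosstab(ordered, redlist)
    crosstab.to_csv(out / "conservation_crosstab.csv")

    metrics = {}
    total_area = config.synthetic.width_km * config.synthetic.height_km
    for extent in ("Brazil", "study_area", "NBZ", "BZ5"):
        if extent == "Brazil":
            sub = records
            area = total_area
        else:
            sub = records.loc[records[_EXTENT_FLAGS[extent]]]
            area = areas[extent]
        cm = richness_sar.cell_richness(sub) if len(sub) else None
        endemics = endemism_range.extent_endemics(
            records, inside=(records[_EXTENT_FLAGS[extent]]
                             if extent != "Brazil"
                             else np.ones(len(records), dtype=bool)))
        metrics[extent] = {
            "area_km2": area,
            "n_records": len(sub),
            "n_taxa": sub["accepted_name"].nunique() if len(sub) else 0,
            "n_endemics": len(endemics),
            "max_cell_richness": int(cm["richness"].max()) if cm is not None and len(cm) else 0,
        }
    summary = conservation_crosstab.summary_table(metrics)
    summary.to_csv(out / "summary_table.csv")
    return [out / "conservation_crosstab.csv", out / "summary_table.csv"]


def _stage_report(config: PipelineConfig) -> list[Path]:
    out = config.out
    needed = ["clean_report.csv", "congruence_report.csv", "richness_ttests.csv",
              "small_range_stats.csv", "validation_report.csv",
              "summary_table.csv", "conservation_crosstab.csv"]
    _require(config, *needed)
    report: dict = {"seed": config.seed}
    for name in needed:
        df = pd.read_csv(out / name)
        report[name.removesuffix(".csv")] = df.to_dict(orient="records")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    lines = [f"karstflora run (seed={config.seed})", ""]
    for name in needed:
        lines.append(f"== {name} ==")
        lines.append((out / name).read_text().strip())
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))
    return [out / "report.json", out / "report.txt"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "clean": _stage_clean,
    "grid": _stage_grid,
    "richness": _stage_richness,
    "endemism": _stage_endemism,
    "validate_karst": _stage_validate_karst,
    "conservation": _stage_conservation,
    "report": _stage_report,
}

_STAGE_INPUTS = {
    "simulate": [],
    "clean": ["occurrences.csv", "backbone_a.csv", "backbone_b.csv"],
    "grid": ["occurrences_clean.csv", "karst_nbz.geojson"],
    "richness": ["occurrences_gridded.csv", "grid.json"],
    "endemism": ["occurrences_gridded.csv", "grid.json",
                 "cell_metrics_study_area.csv"],
    "validate_karst": ["occurrences_gridded.csv", "karst_nbz.geojson"],
    "conservation": ["occurrences_gridded.csv", "redlist.csv", "grid.json"],
    "report": ["clean_report.csv", "summary_table.csv"],
}


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one pipeline stage; returns the paths it wrote."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    config.out.mkdir(parents=True, exist_ok=True)
    inputs = _require(config, *_STAGE_INPUTS[stage]) if _STAGE_INPUTS[stage] else []
    outputs = _STAGE_FUNCS[stage](config)
    _manifest(config, stage, inputs, outputs)
    return outputs


def run_all(config: PipelineConfig, dry_run: bool = False) -> dict[str, list[Path]]:
    """Run every stage in order; writes the resolved config beside outputs."""
    if dry_run:
        for stage in STAGES:
            print(f"would run: {stage} -> {config.out}")
        return {}
    config.out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(config.out / "config_resolved.yaml")
    results = {}
    for stage in STAGES:
        results[stage] = run_stage(stage, config)
    return results
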