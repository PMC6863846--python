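"""Range sizes, weighted endemism and endemics-vs-area comparisons.

Range size is cell-based: the number of 50 km grid cells a species
occupies within a stated extent (an Area-of-Occupancy-like measure).
Weighted endemism (WE) of a cell is the sum over the species present of
the inverse of their range sizes, so narrow-ranged species contribute
more; corrected weighted endemism (CWE) divides WE by the cell's
richness and is the proportion-of-endemics analogue. Summed over all
cells WE returns exactly the number of species (each species contributes
``r * (1/r) = 1``), a conservation law used as a correctness check.

Significance of a cell's WE is judged against a randomisation null: draw
the cell's richness worth of species from the pool (without replacement)
many times and compare the observed WE to the empirical two-tailed
quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .richness_sar import add_cell_indices
from .spatial_grid import EqualAreaGrid, KarstExtent

__all__ = [
    "RangeSizeTable",
    "range_sizes",
    "weighted_endemism",
    "we_randomization",
    "small_range_stats",
    "extent_endemics",
    "log_area_endemics",
]


@dataclass(frozen=True)
class RangeSizeTable:
    """species -> occupied 50 km cell count, within a named extent."""

    extent_label: str
    sizes: pd.Series  # index species, values int >= 1

    def __len__(self) -> int:
        return len(self.sizes)

    def __getitem__(self, species: str) -> int:
        return int(self.sizes[species])

    def to_frame(self) -> pd.DataFrame:
        return self.sizes.rename("range_cells").rename_axis("species").reset_index()


def range_sizes(records: pd.DataFrame, grid: EqualAreaGrid | None = None,
                extent_label: str = "study_area",
                name_column: str = "accepted_name",
                x_column: str = "x_km", y_column: str = "y_km") -> RangeSizeTable:
    """Count distinct occupied cells per species."""
    df = records
    if "cell_col" not in df.columns:
        if grid is None:
            raise ValueError("grid is required when records lack cell indices")
        df = add_cell_indices(df, grid, x_column, y_column)
    pairs = df[[name_column, "cell_col", "cell_row"]].drop_duplicates()
    sizes = pairs.groupby(name_column).size().sort_index()
    return RangeSizeTable(extent_label=extent_label, sizes=sizes)


def weighted_endemism(records: pd.DataFrame, ranges: RangeSizeTable,
                      grid: EqualAreaGrid | None = None,
                      name_column: str = "accepted_name",
                      x_column: str = "x_km", y_column: str = "y_km",
                      ) -> pd.DataFrame:
    """Per-cell WE and CWE.

    ``WE(cell) = sum over species present of 1 / r_s``; ``CWE = WE / S``.
    Every species in the records must appear in the range table.
    """
    df = records
    if "cell_col" not in df.columns:
        if grid is None:
            raise ValueError("grid is required when records lack cell indices")
        df = add_cell_indices(df, grid, x_column, y_column)
    present = pd.unique(df[name_column])
    missing = set(present) - set(ranges.sizes.index)
    if missing:
        example = sorted(missing)[:5]
        raise KeyError(f"{len(missing)} species missing from the range table, "
                       f"e.g. {example}")
    pairs = df[[name_column, "cell_col", "cell_row"]].drop_duplicates()
    pairs = pairs.assign(inv_range=1.0 / ranges.sizes.loc[pairs[name_column]].to_numpy())
    g = pairs.groupby(["cell_col", "cell_row"])
    out = pd.DataFrame({"richness": g[name_column].size(),
                        "WE": g["inv_range"].sum()})
    out["CWE"] = out["WE"] / out["richness"]
    out.index.names = ["col", "row"]
    return out.sort_index()


def we_randomization(cells: pd.DataFrame, pool_ranges,
                     n_draws: int = 2000, alpha: float = 0.05,
                     seed: int | None = 0) -> pd.DataFrame:
    """Randomisation null for per-cell WE.

    For every observed richness S, draws S species from the pool
    (without replacement, a cell cannot hold a species twice) ``n_draws``
    times and records the WE of each draw. The observed WE is flagged
    ``higher`` above the (1 - alpha/2) empirical quantile, ``lower``
    below the alpha/2 quantile, else ``ns``. Draw streams are shared
    across cells with equal richness.
    """
    r = np.asarray(pool_ranges, dtype=float)
    if np.any(r < 1):
        raise ValueError("range sizes must be >= 1")
    inv = 1.0 / r
    pool_n = len(r)
    rng = np.random.default_rng(seed)
    uniq = sorted(set(int(s) for s in cells["richness"]))
    if uniq and uniq[-1] > pool_n:
        raise ValueError(f"cell richness {uniq[-1]} exceeds pool size {pool_n}")
    lo_q, hi_q = {}, {}
    for s in uniq:
        keys = rng.random((n_draws, pool_n))
        picks = np.argpartition(keys, s - 1, axis=1)[:, :s] if s < pool_n else \
            np.tile(np.arange(pool_n), (n_draws, 1))
        wes = inv[picks].sum(axis=1)
        lo_q[s] = float(np.quantile(wes, alpha / 2.0))
        hi_q[s] = float(np.quantile(wes, 1.0 - alpha / 2.0))
    out = cells.copy()
    out["we_null_lo"] = [lo_q[int(s)] for s in out["richness"]]
    out["we_null_hi"] = [hi_q[int(s)] for s in out["richness"]]
    out["we_significance"] = np.where(
        out["WE"] > out["we_null_hi"], "higher",
        np.where(out["WE"] < out["we_null_lo"], "lower", "ns"))
    return out


def small_range_stats(ranges: RangeSizeTable) -> tuple[int, float]:
    """Count and proportion of species restricted to a single cell."""
    if len(ranges) == 0:
        raise ValueError("range-size table is empty")
    count = int((ranges.sizes == 1).sum())
    return count, count / len(ranges)


def extent_endemics(records: pd.DataFrame, extent: KarstExtent | None = None,
                    inside: np.ndarray | None = None,
                    name_column: str = "accepted_name",
                    x_column: str = "x_km", y_column: str = "y_km") -> set[str]:
    """Species whose every record lies inside the extent."""
    if inside is None:
        if extent is None:
            raise ValueError("provide an extent or an inside mask")
        inside = extent.contains_points(records[x_column].to_numpy(dtype=float),
                                        records[y_column].to_numpy(dtype=float))
    inside = np.asarray(inside, dtype=bool)
    names = records[name_column]
    all_inside = pd.Series(inside).groupby(names.to_numpy()).all()
    has_any = pd.Series(inside).groupby(names.to_numpy()).any()
    return set(all_inside.index[all_inside & has_any])


def log_area_endemics(pairs, labels=None) -> pd.DataFrame:
    """log10-log10 endemics-vs-area points with an OLS line and residuals.

    ``pairs`` is a sequence of (area_km2, endemic_count); zero counts are
    skipped with a warning. With fewer than 2 usable points the points
    are echoed without a regression (fit columns are NaN).
    """
    rows = []
    for i, (area, count) in enumerate(pairs):
        label = labels[i] if labels is not None else f"p{i}"
        if area <= 0:
            raise ValueError(f"non-positive area for {label}")
        if count <= 0:
            warnings.warn(f"skipping {label}: zero endemic count", stacklevel=2)
            continue
        rows.append({"label": label, "area_km2": float(area),
                     "endemics": float(count),
                     "log10_area": float(np.log10(area)),
                     "log10_endemics": float(np.log10(count))})
    df = pd.DataFrame(rows)
    df["fitted"] = np.nan
    df["residual"] = np.nan
    df.attrs["slope"] = np.nan
    df.attrs["intercept"] = np.nan
    if len(df) >= 2:
        x = sm.add_constant(df["log10_area"].to_numpy())
        model = sm.OLS(df["log10_endemics"].to_numpy(), x).fit()
        df["fitted"] = model.fittedvalues
        df["residual"] = model.resid
        df.attrs["slope"] = float(model.params[1])
        df.attrs["intercept"] = float(model.params[0])
    return df
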