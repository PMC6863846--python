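"""Gridded species richness, species-area null models and resampling tests.

The analytical sequence implemented here:

1. richness per 50 km cell (distinct accepted names) with record counts;
2. an OLS regression of sqrt(richness) on sqrt(record count) to quantify
   how much apparent richness is sampling effort;
3. species accumulation curves over grid cells, by random permutation or
   by the exact hypergeometric closed form
   ``E[S(n)] = sum_s 1 - C(N - m_s, n) / C(N, n)``, where ``m_s`` is the
   number of cells occupied by species *s* and ``N`` the number of cells;
4. the Arrhenius power law ``S = k * A**z`` fitted to accumulation
   curves by nonlinear least squares on the raw scale, initialised from
   a log-log linear fit;
5. a bootstrap null for per-cell expected richness: resample records,
   rebuild the 10 km accumulation curve, refit the power law, and
   predict each 50 km cell's richness from its count of occupied 10 km
   subcells — observed richness is then classed against the null's
   25th/75th quantiles (-1 lower outlier / 1 non-outlier / 2 upper);
6. a resampling comparison of a cell statistic between a focal extent
   and the surrounding study area: equal-size samples of study-area
   cells, a one-sample two-sided t-test of the replicate sample means
   against the observed focal value (df = n_replicates - 1), plus a
   rank-based empirical p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

from .spatial_grid import EqualAreaGrid, subcell_occupancy

__all__ = [
    "cell_richness",
    "effort_regression",
    "EffortRegression",
    "AccumulationCurve",
    "accumulation_curve",
    "SARFit",
    "SARFitError",
    "fit_arrhenius",
    "NullRichness",
    "null_richness",
    "classify_outliers",
    "ResampleTest",
    "resample_extent_test",
]


def add_cell_indices(records: pd.DataFrame, grid: EqualAreaGrid,
                     x_column: str = "x_km", y_column: str = "y_km",
                     prefix: str = "cell") -> pd.DataFrame:
    """Return a copy with ``{prefix}_col``/``{prefix}_row`` columns."""
    out = records.copy()
    col, row = grid.cell_index(out[x_column].to_numpy(dtype=float),
                               out[y_column].to_numpy(dtype=float))
    out[f"{prefix}_col"] = col
    out[f"{prefix}_row"] = row
    return out


def cell_richness(records: pd.DataFrame, grid: EqualAreaGrid | None = None,
                  name_column: str = "accepted_name",
                  x_column: str = "x_km", y_column: str = "y_km",
                  ) -> pd.DataFrame:
    """Richness and record count per occupied cell.

    Richness is the number of distinct accepted names, so duplicated
    records never inflate it. Returns a frame indexed by ``(col, row)``
    with columns ``record_count`` and ``richness``; empty cells are
    absent.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["record_count", "richness"],
                            index=pd.MultiIndex.from_arrays([[], []],
                                                            names=["col", "row"]))
    df = records
    if "cell_col" not in df.columns or "cell_row" not in df.columns:
        if grid is None:
            raise ValueError("grid is required when records lack cell indices")
        df = add_cell_indices(df, grid, x_column, y_column)
    g = df.groupby(["cell_col", "cell_row"])[name_column]
    out = pd.DataFrame({"record_count": g.size(), "richness": g.nunique()})
    out.index.names = ["col", "row"]
    return out.sort_index()


@dataclass(frozen=True)
class EffortRegression:
    """OLS of sqrt(richness) on sqrt(record count)."""

    slope: float
    intercept: float
    r_squared: float
    n_cells: int


def effort_regression(cells: pd.DataFrame) -> EffortRegression:
    """Fit sqrt(S) ~ sqrt(record_count) across cells by OLS."""
    df = cells.loc[cells["record_count"] > 0]
    if len(df) < 3:
        raise ValueError("effort regression needs >= 3 cells with records")
    x = np.sqrt(df["record_count"].to_numpy(dtype=float))
    y = np.sqrt(df["richness"].to_numpy(dtype=float))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return EffortRegression(slope=float(model.params[1]),
                            intercept=float(model.params[0]),
                            r_squared=float(model.rsquared),
                            n_cells=len(df))


# ---------------------------------------------------------------------------
# accumulation curves


def _incidence(records: pd.DataFrame, name_column: str,
               col_column: str = "cell_col", row_column: str = "cell_row"
               ) -> np.ndarray:
    """Boolean cells x species incidence matrix."""
    cell_codes, _ = pd.factorize(
        pd.Series(list(zip(records[col_column], records[row_column]))), sort=True)
    sp_codes, sp_index = pd.factorize(records[name_column], sort=True)
    inc = np.zeros((cell_codes.max() + 1, len(sp_index)), dtype=bool)
    inc[cell_codes, sp_codes] = True
    return inc


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean cumulative species count as cells accumulate in random order."""

    n_sites: np.ndarray
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n_permutations: int
    method: str = "permute"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_sites": self.n_sites, "mean_richness": self.mean,
                             "ci95_halfwidth": self.ci_halfwidth})


def exact_accumulation_mean(incidence: np.ndarray,
                            at: np.ndarray | None = None) -> np.ndarray:
    """Closed-form E[S(n)] for sampling cells without replacement.

    For species occupying ``m`` of ``N`` cells, the chance it is missed
    by a random draw of ``n`` cells is hypergeometric:
    ``C(N-m, n) / C(N, n)``. Computed in log space for stability.
    """
    n_cells, _ = incidence.shape
    m = incidence.sum(axis=0).astype(float)
    n = np.arange(1, n_cells + 1, dtype=float) if at is None else np.asarray(at, float)

    def log_comb(a, b):
        return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)

    # miss probability; exactly 0 where n > N - m (log C undefined there)
    nn = n[:, None]
    mm = m[None, :]
    with np.errstate(invalid="ignore"):
        log_miss = log_comb(n_cells - mm, nn) - log_comb(float(n_cells), nn)
    miss = np.where(nn > n_cells - mm, 0.0, np.exp(log_miss))
    return (1.0 - miss).sum(axis=1)


def accumulation_curve(records: pd.DataFrame,
                       grid: EqualAreaGrid | None = None,
                       n_permutations: int = 100,
                       seed: int | None = None,
                       name_column: str = "accepted_name",
                       x_column: str = "x_km", y_column: str = "y_km",
                       method: str = "permute") -> AccumulationCurve:
    """Species accumulation over grid cells.

    ``method="permute"`` accumulates cells in ``n_permutations`` random
    orders and reports the per-n mean with a normal-approximation 95% CI;
    ``method="exact"`` evaluates the hypergeometric closed form (no CI).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = records
    if "cell_col" not in df.columns:
        if grid is None:
            raise ValueError("grid is required when records lack cell indices")
        df = add_cell_indices(df, grid, x_column, y_column)
    if len(df) == 0:
        raise ValueError("no records to accumulate")
    inc = _incidence(df, name_column)
    n_cells, n_species = inc.shape
    sites = np.arange(1, n_cells + 1)

    if method == "exact":
        mean = exact_accumulation_mean(inc)
        return AccumulationCurve(n_sites=sites, mean=mean,
                                 ci_halfwidth=np.full(n_cells, np.nan),
                                 n_permutations=0, method="exact")

    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n_cells))
    cell_rank = np.empty(n_cells, dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_cells)
        cell_rank[order] = np.arange(n_cells)
        # first accumulation step at which each species appears
        first = np.where(inc, cell_rank[:, None], n_cells).min(axis=0)
        counts = np.bincount(first, minlength=n_cells + 1)[:n_cells]
        curves[p] = np.cumsum(counts)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n_cells)
    ci = 1.96 * sd
    return AccumulationCurve(n_sites=sites, mean=mean, ci_halfwidth=ci,
                             n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Arrhenius power law


class SARFitError(RuntimeError):
    """Nonlinear species-area fit failed; carries the optimizer diagnostics."""


@dataclass(frozen=True)
class SARFit:
    """Fitted Arrhenius power law S = k * A**z."""

    k: float
    z: float
    rss: float
    n_points: int

    def predict(self, area) -> np.ndarray:
        return self.k * np.asarray(area, dtype=float) ** self.z


def fit_arrhenius(area: Sequence[float], richness: Sequence[float]) -> SARFit:
    """Nonlinear least squares on the raw scale, log-log initialised."""
    a = np.asarray(area, dtype=float)
    s = np.asarray(richness, dtype=float)
    if len(a) < 3:
        raise ValueError("Arrhenius fit needs >= 3 curve points")
    if np.any(a <= 0) or np.any(s <= 0):
        raise ValueError("Arrhenius fit needs positive areas and richness")

    slope, intercept = np.polyfit(np.log(a), np.log(s), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda A, k, z: k * A**z, a, s, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise SARFitError(f"power-law fit did not converge: {exc}; "
                          f"init k={p0[0]:.4g} z={p0[1]:.4g}, "
                          f"n={len(a)}") from exc
    k, z = float(popt[0]), float(popt[1])
    if k <= 0:
        raise SARFitError(f"power-law fit returned non-positive k={k:.4g}")
    rss = float(np.sum((s - k * a**z) ** 2))
    return SARFit(k=k, z=z, rss=rss, n_points=len(a))


# ---------------------------------------------------------------------------
# bootstrap null richness


@dataclass(frozen=True)
class NullRichness:
    """Per-cell bootstrap null distribution of expected richness."""

    cells: tuple
    expected: np.ndarray        # (n_draws, n_cells)
    q25: np.ndarray
    q75: np.ndarray
    occupied_subcells: np.ndarray
    z_values: np.ndarray
    k_values: np.ndarray
    n_draws: int

    @property
    def z_mean(self) -> float:
        return float(self.z_values.mean())

    @property
    def z_sd(self) -> float:
        return float(self.z_values.std(ddof=1))

    @property
    def mean_expected_per_draw(self) -> np.ndarray:
        return self.expected.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "col": [c[0] for c in self.cells],
            "row": [c[1] for c in self.cells],
            "occupied_subcells": self.occupied_subcells,
            "expected_mean": self.expected.mean(axis=0),
            "expected_q25": self.q25,
            "expected_q75": self.q75,
        })


def null_richness(records: pd.DataFrame, grid50: EqualAreaGrid,
                  grid10: EqualAreaGrid, n_draws: int = 1000,
                  seed: int | None = 0,
                  name_column: str = "accepted_name",
                  x_column: str = "x_km", y_column: str = "y_km",
                  draw_unit: str = "records",
                  max_curve_points: int = 80) -> NullRichness:
    """Bootstrap null for per-cell expected richness.

    Each draw resamples the records with replacement at full size
    (``draw_unit="records"``, the default) or resamples the occupied
    10 km cells (``draw_unit="cells"``), builds the exact accumulation
    curve over 10 km cells, fits the power law, and predicts each 50 km
    cell's expected richness from its observed number of occupied 10 km
    subcells. The curve is evaluated at up to ``max_curve_points``
    log-spaced site counts for the fit.
    """
    if len(records) == 0:
        raise ValueError("no records in the extent")
    if draw_unit not in ("records", "cells"):
        raise ValueError(f"unknown draw_unit {draw_unit!r}")
    df = records.sort_values("record_id" if "record_id" in records else
                             list(records.columns[:1]), kind="mergesort")
    x = df[x_column].to_numpy(dtype=float)
    y = df[y_column].to_numpy(dtype=float)
    c50, r50 = grid50.cell_index(x, y)
    c10, r10 = grid10.cell_index(x, y)
    sp_codes, _ = pd.factorize(df[name_column].to_numpy(), sort=True)
    cell10_codes, _ = pd.factorize(pd.Series(list(zip(c10, r10))), sort=True)
    occ = subcell_occupancy(x, y, grid50, grid10)
    cells = tuple(sorted(occ))
    a_obs = np.array([occ[c] for c in cells], dtype=float)

    n = len(df)
    n_species = sp_codes.max() + 1
    n_cells10 = cell10_codes.max() + 1
    rng = np.random.default_rng(seed)

    expected = np.empty((n_draws, len(cells)))
    zs = np.empty(n_draws)
    ks = np.empty(n_draws)
    for b in range(n_draws):
        if draw_unit == "records":
            take = rng.integers(0, n, n)
        else:
            chosen = rng.integers(0, n_cells10, n_cells10)
            take = np.flatnonzero(np.isin(cell10_codes, chosen))
        inc = np.zeros((n_cells10, n_species), dtype=bool)
        inc[cell10_codes[take], sp_codes[take]] = True
        nonempty = inc.any(axis=1)
        inc = inc[nonempty][:, inc.any(axis=0)]
        n10 = inc.shape[0]
        if n10 < 3 or inc.shape[1] == 0:
            expected[b] = np.nan
            zs[b] = np.nan
            ks[b] = np.nan
            continue
        at = np.unique(np.round(np.geomspace(1, n10, min(max_curve_points, n10)))
                       ).astype(float)
        es = exact_accumulation_mean(inc, at=at)
        fit = fit_arrhenius(at, es)
        ks[b] = fit.k
        zs[b] = fit.z
        expected[b] = fit.predict(a_obs)

    q25 = np.nanquantile(expected, 0.25, axis=0)
    q75 = np.nanquantile(expected, 0.75, axis=0)
    return NullRichness(cells=cells, expected=expected, q25=q25, q75=q75,
                        occupied_subcells=a_obs, z_values=zs, k_values=ks,
                        n_draws=n_draws)


def classify_outliers(observed: Mapping[tuple, float] | pd.Series,
                      null: NullRichness) -> dict[tuple, int]:
    """Class each cell against the null quantiles: strictly below the
    25th quantile -> -1, strictly above the 75th -> 2, else 1. Cells
    without a null are skipped with a warning."""
    if isinstance(observed, pd.Series):
        observed = dict(observed.items())
    out: dict[tuple, int] = {}
    index = {c: i for i, c in enumerate(null.cells)}
    for cell, s in observed.items():
        i = index.get(tuple(cell))
        if i is None or not np.isfinite(null.q25[i]):
            warnings.warn(f"no null distribution for cell {cell}; skipped",
                          stacklevel=2)
            continue
        out[tuple(cell)] = -1 if s < null.q25[i] else (2 if s > null.q75[i] else 1)
    return out


def classify_against_quantiles(observed, q25, q75) -> np.ndarray:
    """Vectorised quantile classification (strict inequalities)."""
    obs = np.asarray(observed, dtype=float)
    return np.where(obs < np.asarray(q25), -1,
                    np.where(obs > np.asarray(q75), 2, 1))


# ---------------------------------------------------------------------------
# resampling extent comparison


@dataclass(frozen=True)
class ResampleTest:
    """Equal-size resampling comparison of an extent against its backdrop.

    ``p_value`` is the two-sided one-sample t-test of the replicate
    sample statistics against the observed value, with
    df = n_replicates - 1. Because the observed value fluctuates like a
    single replicate while the test's standard error shrinks with the
    number of replicates, this construction yields very large |t| for
    any real difference (and is anti-conservative under the null);
    ``p_empirical`` is the rank-based two-sided probability of a
    replicate at least as extreme as the observed value, which is
    calibrated under exchangeability.
    """

    observed: float
    replicates: np.ndarray
    t: float
    df: int
    p_value: float
    p_empirical: float

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"quantity": "observed", "value": self.observed},
            {"quantity": "replicate_mean", "value": float(self.replicates.mean())},
            {"quantity": "replicate_sd", "value": float(self.replicates.std(ddof=1))},
            {"quantity": "t", "value": self.t},
            {"quantity": "df", "value": self.df},
            {"quantity": "p_value", "value": self.p_value},
            {"quantity": "p_empirical", "value": self.p_empirical},
        ])


def one_sample_t(replicates: np.ndarray, observed: float
                 ) -> tuple[float, int, float]:
    """Two-sided one-sample t of the replicates against ``observed``;
    returns (t, df, p) with df = n - 1."""
    reps = np.asarray(replicates, dtype=float)
    t_stat, p = stats.ttest_1samp(reps, float(observed))
    return float(t_stat), len(reps) - 1, float(p)


def resample_extent_test(study_values: Sequence, karst_values: Sequence | None = None,
                         *, observed: float | None = None,
                         sample_size: int | None = None,
                         n_samples: int = 1000, seed: int | None = 0,
                         statistic: Callable | None = None) -> ResampleTest:
    """Compare a focal-extent statistic against equal-size random samples.

    Draws ``n_samples`` samples (without replacement within a sample) of
    ``sample_size`` study-area cells, applies ``statistic`` (default:
    mean) to each, then tests the replicate statistics against the
    observed focal value. Either pass ``karst_values`` (observed and
    sample size are derived) or ``observed`` + ``sample_size``.
    """
    study = np.asarray(study_values, dtype=object)
    if statistic is None:
        statistic = lambda v: float(np.mean(np.asarray(v, dtype=float)))
    if karst_values is not None:
        sample_size = len(karst_values)
        observed = statistic(karst_values)
    if observed is None or sample_size is None:
        raise ValueError("provide karst_values, or observed and sample_size")
    if sample_size > len(study):
        raise ValueError(f"sample size {sample_size} exceeds the "
                         f"{len(study)} study-area cells")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_samples)
    idx = np.arange(len(study))
    for i in range(n_samples):
        take = rng.choice(idx, size=sample_size, replace=False)
        reps[i] = statistic(study[take])

    t_stat, dof, p_t = one_sample_t(reps, float(observed))
    p_lo = (1 + np.sum(reps <= observed)) / (n_samples + 1)
    p_hi = (1 + np.sum(reps >= observed)) / (n_samples + 1)
    p_emp = min(1.0, 2.0 * min(p_lo, p_hi))
    return ResampleTest(observed=float(observed), replicates=reps,
                        t=t_stat, df=dof, p_value=p_t, p_empirical=p_emp)
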