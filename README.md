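# karstflora

Macroecological analysis of karst floras from plant occurrence records:
gridded species richness, species–area null models, weighted endemism
with randomisation nulls, range-size statistics, keyword-based
validation of karst maps, and IUCN Red List cross-tabulation — exercised
end-to-end on synthetic occurrence landscapes so every stage is testable
without any data download.

## The problem

Karst (landscapes on soluble rock — limestone, dolomite, gypsum) is
associated in some regions with exceptional plant endemism, yet its
floristic value elsewhere is poorly quantified. Given a large but noisy
set of georeferenced herbarium records, a geological map of karst
extent, one or more taxonomic backbones and a red list, the questions
are: does karst hold more species, more small-ranged species, and more
threatened species than the surrounding landscape, once sampling effort
and coordinate error are accounted for? This package implements the
full analytical chain for that comparison, aimed at biodiversity
informaticians and macroecologists working with aggregated collection
data.

## The methods at its core

* **Gridded richness.** Records are projected with the South America
  Albers Equal Area Conic projection and binned into half-open 50 × 50 km
  cells; richness *S* is the count of distinct accepted names per cell.
  Because ~half of aggregated records carry 5 km coordinate error, the
  karst extent is analysed both as mapped (NBZ) and with a 5 km buffer
  (BZ5).
* **Effort control.** OLS of √S on √(record count) across cells
  quantifies how much apparent richness is collecting effort.
* **Species–area null model.** Bootstrap draws of the occurrence data
  (1,000×) each yield a species accumulation curve over 10 × 10 km cells
  (exact hypergeometric form,
  E[S(n)] = Σₛ 1 − C(N−mₛ, n)/C(N, n)), to which the Arrhenius power law
  *S = kA^z* is fitted by nonlinear least squares. Each 50 km cell's
  expected richness is k·(occupied 10 km subcells)^z; observed richness
  below/above the null's 25th/75th quantiles marks the cell a lower
  (−1) / upper (2) outlier.
* **Weighted endemism.** WE(cell) = Σₛ 1/rₛ over species present, where
  rₛ is the species' range size in occupied 50 km cells (an
  AOO-like, cell-based measure); CWE = WE/S. Significance comes from
  2,000 random draws of S species from the pool. Summed over all cells
  WE equals the species total exactly — a conservation law the tests
  enforce.
* **Extent comparisons.** Karst cells are compared against 1,000
  equal-size random samples of study-area cells with a two-sided
  one-sample t-test of the replicate means against the observed karst
  value (df = 999), reported alongside a rank-based empirical p (see
  `docs/methods.md` for why the t-form is anti-conservative).
* **Karst-map validation.** Habitat notes are mined for karst keywords
  ('calcário', 'limestone', 'dolina', 'gruta', …; accent-folded,
  word-boundary matching). Carbonate terms are accepted outright;
  doline terms require polygon membership; cave terms require a
  carbonate record or mapped karst within 1 km. Retained records are
  overlaid on the map to measure congruence and flag candidate
  undocumented outcrops.
* **Conservation cross-tabs.** Species sets per extent are crossed with
  IUCN categories (EX/EW/CR/EN/VU/NT/LC), with a "conservation concern"
  roll-up and percentages against the country-total column.

## Worked example

The numbered drivers under `analysis/` run the pipeline stage by stage;
equivalently, one call runs everything from a single config and seed:

```python
from karstflora.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(outdir="results/pipeline", seed=1)
run_all(cfg)
```

At the default study conditions (1000 × 800 km landscape, 400 species,
30,000 records, karst ≈ 6.5% of the landscape, half the records with
5 km coordinate error, a backbone with a 16.6% synonym load) the seed-1
run prints, among others:

```
backbone_b  synonymous   66   16.5      # checklist congruence (% of 400 names)
backbone_b  not_found    20    5.0

extent      n_taxa  pct   n_records  pct
study_area     283  90.1      22395  77.4
NBZ             90  28.7       1853   6.4
BZ5             96  30.6       2432   8.4

NBZ bootstrap SAR: mean z = 0.475 (SD 0.007)
richness:NBZ-vs-study_area  t = 138.92  df = 999  p_empirical = 0.002
```

Reading: the karst extent (≈5% of the land) holds ≈29% of the taxa, but
its per-cell richness is significantly *below* equal-area samples of
the surrounding study area (negative t: the observed karst mean sits
under the replicate mean), and most karst cells fall below the 25th
quantile of the bootstrap species–area null — the signature of
under-sampling. Buffering the karst by 5 km (BZ5) recovers ~31% more
records and four times the extent endemics, showing how strongly
coordinate error shapes these estimates. The fitted species–area
exponent z ≈ 0.48 is in the usual range for regional floras.

A CLI wraps the same stages: `karstflora all --outdir out --seed 1`,
or stage by stage (`karstflora simulate`, `karstflora clean`, …).

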