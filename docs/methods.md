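# Methods

This note documents the models, the synthetic data the pipeline is
exercised on, the numerical choices, and the known limitations.

## Spatial frame

All analysis happens in an equal-area plane in kilometres. For
geographic inputs the South America Albers Equal Area Conic projection
is used (central meridian −60°, standard parallels −5° and −42°,
latitude of origin −32°, authalic sphere R = 6371.0072 km); these
parameters are the standard continental configuration and are
configurable. The projection is implemented from the spherical closed
forms; tests verify the forward/inverse round trip to 1e−6 degrees and
the areal Jacobian (R²·cos φ, the defining property of an equal-area
map) to 0.5%. Purely synthetic data can use a planar-km passthrough
instead.

Grids are regular square tessellations with half-open cells
[x₀+i·s, x₀+(i+1)·s) × [y₀+j·s, y₀+(j+1)·s), so boundary points belong
to exactly one cell (the higher index). The grid origin is the floor of
the study-area bounding-box minimum to the nearest cell multiple, which
makes cell indices reproducible; anchoring is configurable because cell
membership near extent edges depends on it. The two operational sizes
are 50 km (analysis cells) and a nested 10 km subgrid (area proxy for
the species–area model: a 50 km cell's "area" is its count of
non-empty 10 km subcells, 1–25).

Extents: NBZ is the karst map as given; BZ5 is its 5 km Euclidean
buffer (compensating the 5 km coordinate uncertainty typical of about
half of aggregated records); the study area is the bounding box of the
karst. Buffers use 256 segments per quadrant so the polygonal area
error of a 5 km buffer stays below 1e−3 km².

## Cleaning and names

Coordinate checks run in fixed order, each switchable, each tallied:
(1) missing or exactly-(0,0) coordinates; (2) out-of-range; (3)
lat == lon exactly; (4) country-attribute vs containing polygon; (5)
not on land; (6) within 10 km of a country centroid (a common
georeferencing default). Duplicates are deliberately retained: richness
and range sizes count distinct names per cell and are idempotent to
duplication.

Name resolution is exact string lookup (after whitespace
normalisation) against a pre-flattened backbone: accepted → itself,
synonym → its accepted name in one hop, absent → an unresolved list
that is preserved but excluded from analysis. No fuzzy matching and no
author-string parsing. Backbone congruence classifies a name list as
shared / synonymous (surplus) / not-found with percentages rounded
half-up to one decimal, the bookkeeping of a checklist-comparison
table.

## Richness and the species–area null

Richness S per cell is the count of distinct accepted names; the
effort regression is OLS of √S on √(records) across cells (square-root
transforms stabilise the counts).

Accumulation curves accumulate cells in random order. The default is
permutation (100 permutations, configurable; mean and a
normal-approximation 95% CI per step). The exact expectation is also
implemented: a species occupying m of N cells is missed by a random
draw of n cells with hypergeometric probability C(N−m, n)/C(N, n), so
E[S(n)] = Σₛ (1 − C(N−mₛ, n)/C(N, n)), computed with log-gamma for
stability. Tests check the permutation mean against this closed form
(and the closed form itself against brute-force subset enumeration on a
5-cell fixture).

The Arrhenius power law S = kA^z is fitted by nonlinear least squares
on the raw scale, initialised from the log–log linear fit; noise-free
power laws are recovered to 1e−6 across k > 0, z ∈ [0.1, 1.5].

The bootstrap null for per-cell expected richness resamples the records
with replacement at full size (1,000 draws by default; resampling of
10 km cells is available behind a switch). "Draw size = input size,
with replacement" is a design choice recorded in the run config. Each
draw's 10 km accumulation curve is summarised by the exact form — the
expectation the permutation estimate converges to — evaluated at ≤80
log-spaced site counts, and fitted; the draw's expected richness for a
50 km cell is k·A^z with A the cell's observed occupied-subcell count.
Observed richness strictly below the null's 25th quantile (linear
interpolation, type-7) classes the cell −1, strictly above the 75th
classes it 2, otherwise 1. This classification is calibrated
(25/50/25%) only when the observed value is exchangeable with the null
draws; on real data the null concentrates near the fitted species–area
curve, so a dominance of −1 cells is the under-sampling signal, not a
calibration defect.

## The extent resampling test

To compare a cell statistic (mean richness, small-range proportion)
between karst and the study area, 1,000 equal-size samples of
study-area cells are drawn (without replacement within a sample) and a
two-sided one-sample t-test of the replicate sample statistics against
the observed karst value is reported with df = n_replicates − 1.

This construction deserves a caveat that the package surfaces
explicitly: under the null the observed karst value fluctuates like a
*single* replicate, while the t denominator is the standard error of
the replicate *mean of means*, which shrinks with the number of
replicates. |t| therefore grows like √n_replicates for any real
difference and the t-based p is sharply anti-conservative under the
null. `ResampleTest` consequently also reports `p_empirical`, the
rank-based two-sided probability of a replicate at least as extreme as
the observed value (with add-one correction), which is exactly
calibrated under exchangeability — the acceptance suite verifies a
5% ± 2% type-I rate for it over 200 null datasets. Consumers should
treat t as a descriptive effect-size-like quantity and use
`p_empirical` for inference.

## Endemism and range size

Range size r is the number of occupied 50 km cells within a stated
extent (cell-based, Area-of-Occupancy-like). WE(cell) = Σₛ 1/rₛ,
CWE = WE/S. Two bases are always computed side by side:
extent-restricted ranges (which overestimate endemism, since a
wide-ranged species clipped by the extent looks narrow) and study-area
ranges (the conservative measure). The randomisation null for WE draws
the cell's richness worth of species from the pool without replacement
(a cell cannot hold a species twice), 2,000 draws by default, and flags
the observed WE outside the two-tailed empirical α = 0.05 band;
both the draw count and α are configurable. Small-range species are
those with r = 1; extent endemics are species whose every record falls
inside the extent. The endemics-vs-area comparison takes base-10 logs
of (area, endemic count) pairs and fits a simple OLS line, flagging
residual outliers; zero counts are skipped with a warning. The
small-range distributions can be bimodal, which the t-form of the
resampling test does not model; the empirical p is again the robust
quantity.

## Karst-map validation

Keyword matching accent-folds (NFKD, combining marks stripped) and
lower-cases both the notes and the keyword, and matches on word
boundaries to avoid hits inside other words. A record matching several
keywords is classed by the strongest evidence: carbonate > doline >
cave — a label mentioning limestone is direct substrate evidence even
if it also mentions a cave. Retention: carbonate unconditional; doline
only inside mapped karst polygons (an automated stand-in, tagged AUTO,
for a manual plausibility check); cave only within 1 km (planar
distance in the equal-area projection; the error at 1 km scale is
negligible) of a carbonate record or mapped karst. The anchor set is
computed before any conditional rule, so the filter is
order-independent, and every excluded record carries the rule that
excluded it. Overlay congruence reports the fraction of retained
records inside the extent and within a distance threshold (default
5 km, matching the coordinate error), and lists the records beyond it
as candidate undocumented outcrops.

## Conservation tables

The cross-tab counts evaluated species per IUCN category per extent,
with percentages against the first (country-total) column, rounded
half-up to one decimal. "Conservation concern" sums EX+EW+CR+EN+VU+NT
by default — the definition under which the roll-up equals the sum of
its category rows — with a switch for the stricter EX–VU-only reading;
the table footer states which definition was used.

## Synthetic landscapes

The generator produces the statistical structure the analysis assumes,
not Brazilian geography:

* **Species ranges are discs.** With probability `single_cell_fraction`
  (default 0.40) a species is narrow: radius U(0.5, 20) km, centre
  placed so that the disc *plus the 5 km jitter margin* lies inside one
  50 km cell — the declared coordinate error can then never spill a
  single-cell species across a border. Otherwise the species is wide
  (radius U(30, 150) km, diameter > 50 km), so the realised single-cell
  fraction tracks the target up to binomial noise. Abundances are
  lognormal (σ = 1.2): few common, many rare, yielding the reversed-J
  range-size distribution downstream.
* **Karst** is a union of random convex blobs grown until total area is
  within ±2% (of landscape area) of `karst_fraction` (default 0.065,
  bounded to (0, 0.5] because blob placement saturates); generation
  fails loudly after 1,000 attempts.
* **Effort bias** is a mixture of Gaussian bumps (default 8 "herbarium
  towns", σ = 60 km) whose height scales with `effort_bias`; records
  are thinned by weighted subsampling of 4× candidate points per
  species. Bias 0 reduces to uniform sampling within ranges.
* **Records**: every species receives a floor of 6 records (so the
  recorded footprint reflects the true range; otherwise every
  singleton species is spuriously single-celled), the remainder
  multinomial by abundance. Exactly round(`coord_error_fraction`·n)
  records (default half) get 5,000 m uncertainty and a jitter uniform
  in a 5 km disc. Records whose true point lies in karst carry, with
  probability 0.5 (configurable), one karst keyword in an otherwise
  neutral Portuguese-style habitat note.
* **Backbones**: backbone A accepts every generated name; backbone B
  remaps an exact `synonym_fraction` (default 0.166) of names onto
  other accepted names and marks a further 5% not-found.
* **Red list**: independent per-species category assignment; default
  probabilities make ~3.7% of species evaluated, matching the sparse
  coverage typical of megadiverse floras.

All randomness flows from one integer seed through a named stream per
sub-generator, so any stage regenerates independently and bit-identically.

Defaults were chosen once as the package's study conditions: a
1000 × 800 km landscape (20 × 16 analysis cells), 400 species and
30,000 records — large enough that every statistic is exercised with
realistic spread, small enough that the full pipeline runs in seconds.
What the synthetic landscape does **not** emulate: real phytogeographic
structure, climate, spatially autocorrelated ranges beyond discs,
taxonomic error correlated with geography, or continental-scale data
volumes (millions of records); passing tests demonstrate correctness and calibration of the
machinery, not ecological conclusions about any real flora.

## Numerical choices

* Quantiles everywhere are linear-interpolation (type 7); outlier and
  significance rules use strict inequalities at the band edges (a value
  equal to the quantile is not an outlier).
* Percentages in report tables round half-up to one decimal (`Decimal`,
  not banker's rounding), matching how summary tables are printed.
* `curve_fit` failures raise a fit error carrying the initialisation
  and problem size; non-positive areas/richness are rejected before
  fitting; bootstrap draws with fewer than 3 occupied subcells yield
  NaN columns that quantile summaries skip.
* Degenerate inputs: empty record sets yield empty frames (not errors)
  where a sum is meaningful, and explicit errors where a statistic is
  undefined (empty range table, empty retained set, richness beyond
  pool size).

## Pipeline

Stages (simulate → clean → grid → richness → endemism → validate_karst
→ conservation → report) communicate only through files (CSV, GeoJSON,
JSON) in the output directory; each stage writes a manifest with its
seed and the SHA-256 of every input consumed, and the resolved config
is written beside the outputs. Identical config + seed reproduce
byte-identical files. Missing upstream outputs raise a dependency
error naming the file. Defaults: 5 km buffer, 1,000 richness draws,
2,000 endemism draws, 1,000 resampling samples, α = 0.05.

## Known limitations

* The country-centroid distance check uses an equirectangular
  approximation in degrees; adequate at the 10 km scale it serves.
* The bootstrap null treats records as independent; spatial
  autocorrelation within collections (one collector, one day) is not
  modelled.
* WE significance draws species without replacement from a pool that
  ignores abundance structure; a frequency-weighted null is not
  implemented.
* The t-form of the resampling test is reported for comparability but
  is anti-conservative (see above); only `p_empirical` is calibrated.
* Keyword matching is lexical; it cannot catch labels that describe
  karst without using any listed term, nor misapplied terms.
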