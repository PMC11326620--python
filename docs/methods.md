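# Methods

## The production panel

All analyses operate on a tidy panel of annual records keyed by
`(year, country, species, environment)` with quantity in tonnes live weight
and optional value in thousand US$. Years are restricted to [1900, 2100],
quantities must be non-negative, and at most one record may exist per key.
FishStatJ-style wide exports (descriptor columns followed by one column per
year) are melted into this form with the FAO sentinel conventions: `...` or
an empty cell is a missing observation, `-` is a true zero, and a trailing
whitespace-separated single-letter flag (`F` FAO estimate, `E` expert
estimate, …) is stripped before the numeric parse and noted in the log.
Duplicate keys are summed by default because FAO splits some series by
sub-environment; a strict mode rejects them for QC. Missing quantities are
excluded from sums, so aggregation conserves the total of non-missing
inputs under any key subset.

National totals cannot be split below country level (e.g. to a single
coastline); scope restriction is done with an include/exclude country
filter, and species/country regroupings (superspecies, historic boundary
changes) with a user-supplied alias map.

## Diversity and dominance

For each year and axis (species or countries), volumes are aggregated and
shares `p_i` computed over entities with positive production. The Shannon
index is `H = −Σ p_i ln p_i` (natural log), bounded by `0 ≤ H ≤ ln S`.

The dominance decomposition sorts entities by volume descending, ties
broken by label ascending so results are deterministic. `relevant` is the
size of the smallest prefix whose cumulative share reaches 99 % of the
**annual total**, `dominant` the smallest prefix reaching 80 %, `minor =
total − relevant`, and the Pareto index is `100 × dominant / relevant`.
Measuring the dominant prefix against the annual total, rather than against
the relevant subset's subtotal, is a deliberate choice: it is the reading
under which the canonical worked example (shares 50, 30, 8, 4, 3, 2, 2,
0.4, 0.3, 0.3 → 7 relevant, 2 dominant, 3 minor, index 28.6 %) comes out
exactly; the subset-based variant is available via `dominant_base=
"relevant"`. Likewise `minor` is defined by the difference rule, not by a
per-entity <1 % share test — the two can disagree and the difference rule
is the one the worked example uses. Threshold comparisons carry a 1e-9
relative tolerance so a prefix landing exactly on a threshold in exact
arithmetic is not missed to float round-off.

## Expansion profiling

*Persistence* counts distinct years with positive production (gaps do not
count; a first-to-last span option exists for sensitivity). *Diffusiveness*
is the number of countries with positive production of a species, reported
both per year (`C_t`, zero-filled across the panel's year range) and
cumulatively ("ever", the default for classification — whether quadrant
plots should use ever- or currently-farmed counts is genuinely open, so
both are exposed). The geographical expansion rate is

    rate_t = 100 (C_t − C_{t−1}) / C_{t−1},   GER = mean of rate_t over the
                                              trailing window (default 10 y)

skipping years whose previous count is zero; an empty window yields an
undefined result (`None`), not an error. The arithmetic mean is the
default ("average" is otherwise underspecified); a geometric-mean variant
is provided. Quadrant classification crosses persistence > 60 years against
diffusiveness > 20 countries, both strict ("more than"), giving
core_widespread / core_localized / emergent / transient. Relative
productivity divides the trailing-window (default 5 y) production sum by a
user-supplied national area in km²; areas are inputs, not bundled data.

## Trends

Fits are ordinary least squares on years centered at the window start —
uncentered powers of calendar years (~2000³) are numerically
ill-conditioned. `linear` is degree-1 polynomial; `polynomial` defaults to
degree 2 (degree is user-chosen; no degree is canonical); `exponential`
fits a line to log values, so its slope is the continuous growth rate per
year, and requires strictly positive values. R² and the Pearson r of
fitted-vs-observed are reported on the original scale. Forecasting
evaluates the fitted curve with no clamping and warns when extrapolating
beyond the fit window; no uncertainty band is attached by default.

Growth rates are year-over-year percent changes (years following a zero are
skipped). Windowed mean growth is either the arithmetic mean of those
rates, or CAGR with the exponent `1/span` where span is the elapsed years
between the first and last observation in the window — robust to gap years
and consistent with the year-over-year definition on consecutive data.
"Carrying capacity" as used here is simply the arithmetic mean of a
capture-fishery series over a closed year window (default 1985–2020 in the
CLI): with wild landings flat for decades, their long-run mean is read as
the basin's ceiling of wild extraction. It is a descriptive summary, not a
population-dynamic estimate.

Correlation utilities align series on their year intersection and require
≥ 3 aligned points and nonzero variance; the matrix form uses
pairwise-complete observations (pairs with fewer than 3 complete rows are
flagged NaN) and supports excluding listed rows, e.g. one outlier country
that would otherwise dominate every coefficient. Covariate tables (GDP,
consumption, coastline …) are user-supplied CSVs; nothing is retrieved.

## Succession

The species × year matrix holds total production per cell, columns spanning
the panel's full year range with absent combinations filled with 0 (nothing
farmed). Row z-scaling uses each row's own mean and *sample* standard
deviation (ddof = 1); rows with zero variance map to all zeros rather than
NaN. Clustering of rows uses Euclidean distances with Ward linkage in the
Lance–Williams "Ward.D2" convention (scipy's `linkage(..., "ward")`), the
update

    d(i∪j, k)² = [(nᵢ+nₖ) d(i,k)² + (nⱼ+nₖ) d(j,k)² − nₖ d(i,j)²] / (nᵢ+nⱼ+nₖ)

with centroid linkage offered as an alternative; merge ties resolve to the
smallest cluster ids so dendrograms are reproducible. The dendrogram
exports to Newick with merge heights as cumulative branch lengths.
Succession phases are extracted purely by argmax-and-run-length: per year
the maximum row (ties by label order, all-zero columns labelled `none`) and
its share of the column total, with consecutive runs of the same label
reported as phases. Any ecological staging narrative (pioneer →
intermediate → climax) is an interpretation laid over this output, not a
separate algorithm.

## Synthetic panels

The generator emulates the regularities long-run production panels show,
so downstream code is testable without any download:

| parameter | default | meaning |
|---|---|---|
| `n_species`, `n_countries` | 25, 25 | basin-scale species pool and country set |
| `years` | (1950, 2020) | the seven-decade horizon of FAO series |
| `share_model`, `share_param` | geometric, k = 0.72 | rank-abundance of species shares; k = 0.72 makes ~5 species carry 80 % and ~14 carry 99 % of volume, the observed order of magnitude of dominance |
| `total_capacity` | 1 Mt | logistic saturation level of the basin |
| `growth_rate` | 0.15 /yr | logistic r of every species trajectory |
| `midpoint_offset` | 40 y | logistic midpoint t₀ = intro year + offset |
| `intro_span` | 50 y | introductions staggered over the first decades, dominant species first |
| `adoption_rate` | 0.5 /yr | expected new adopting countries per species-year (exponential waiting times; the first adopter farms at the intro year) |
| `country_decay` | 0.6 | geometric rank-abundance of country weights among adopters — production is country-concentrated too |
| `noise_cv` | 0.05 | multiplicative log-normal noise, mean-one parameterisation |

A national quantity is `share_s × logistic_s(t) × weight_c × noise`, with
country weights renormalised over the adopters present in year *t*, so at
zero noise species totals equal `share_s × logistic_s(t)` exactly and the
generator's ground truth (introduction years, growth rate, persistence) is
recoverable by the analysis modules — the basis of the parameter-recovery
tests. Noise is log-normal with `σ² = ln(1 + cv²)` and mean one, so
expected totals equal the deterministic skeleton. All randomness descends
from one seed through per-(species, country) substreams; adding a species
does not perturb existing series.

What the generator does **not** emulate: reporting artifacts (revisions,
breaks, flags beyond the parser fixtures), country exits/re-entries,
correlated shocks across species or countries, value series, and
non-logistic boom–bust dynamics. Tests passing on synthetic panels
therefore demonstrate correctness of the computations, not robustness to
every pathology of real FAO data.

## Problem sizes and verification

The test suite checks each statistic against an independent oracle: full
prefix enumeration for the dominance decomposition (1000 random vectors,
n ≤ 50), a naive O(n³) greedy agglomeration for Ward clustering (100 random
5–8-row matrices), direct summation for Shannon, hand-computed values for
growth rates, CAGR, GER and productivity, and the generator's closed-form
ground truth for recovery (zero-noise persistence exact; logistic r within
1e-3 from an early-window exponential fit, the window placed ≥ 45 years
before the midpoint where the logistic is exponential to ~0.1 %; median
relative error < 10 % across 20 seeds at 5 % noise). Synthetic panels in
tests use 1–25 species over ≤ 71 years, sizes at which every check runs in
seconds while still exercising the full pipeline.

`scripts/acceptance.py` recomputes the reference quantities of the
dominance decomposition on the canonical 10-species share vector and writes
them as JSON; see the README for invocation.
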