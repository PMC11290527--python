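# Methods

`stratodyn` quantifies how the Ediacaran–Cambrian (~580–510 Ma) record of
fossil biodiversity relates to the sedimentary rocks that host it, to
sampling effort, and to chemostratigraphic proxy series, under explicit age
uncertainty. This note records the models, conventions, numerical choices,
and limitations behind each component.

## Age conventions and the time grid

Ages are Ma before present; larger is older. All intervals are stored as
`(older_bound, younger_bound)`. Two grids share one `TimeGrid` object:

* **Moving windows** for biotic and correlation series: windows stepped by
  100 ka. Under the default `printed_example` convention the window
  labelled `L` spans `(L + 0.4, L − 0.5)` Ma — label 570.5 covers
  570.9–570.0 Ma, label 570.4 covers 570.8–569.9 Ma — a 0.9-Ma span even
  though such windows are conventionally called "1-Ma" bins. The worked
  label example is the only bit-exact anchor available for the convention,
  so it is the default; `window_convention="symmetric_1ma"` exposes the
  symmetric 1.0-Ma alternative. Window arithmetic is done in integer
  1-ka ticks so labels and edges are exact.
* **Flux bins** for the rock record: half-open 50-ka bins `[older,
  younger)`; a boundary exactly on a grid line belongs to the older bin,
  so nothing is double-counted.

Per-capita rates divide by the window span actually used (0.9 Ma by
default), so they are in per-Ma units regardless of convention.

## Occurrence resampling under age uncertainty

Each occurrence carries a permitted interval `(max_age, min_age)` and an
uncertainty category 1–4 (1 = radiometrically/age-depth constrained, 4 =
poorly constrained correlation). Category-1 records are prescribed their
full interval; for categories 2–4 one age per occurrence is drawn
**uniformly** within the permitted interval. The source convention says
only "randomly generated"; uniform is the maximum-entropy choice for an
interval constraint and is the documented default. Draws are at the
occurrence level (not per taxon endpoint), and a taxon's realized range is
the envelope (oldest draw, youngest draw) over its records, so a taxon with
several occurrences narrows its uncertainty naturally.

Replicate datasets (default 100 here; 10,000 in full-scale studies) derive
their streams from a master seed via `numpy.random.SeedSequence.spawn`, so
replicates are independent and the whole sequence is reproducible.
Replicates stream to the diversity module without being materialized
(`--dump-replicates` writes them if wanted).

**Diversity filters** (each an independent toggle): trace fossils,
holdfast-only records, taxa flagged `excluded_taxon`, and Lagerstätte
records are removed before diversity and turnover estimation. The
sampling-intensity series deliberately uses a different filter set (see
below).

## Diversity metrics

Richness is range-through: a taxon is present in a window when its closed
realized range `[lad, fad]` intersects the window. Whether the source
analyses intersect ranges as closed or half-open intervals is not stated;
the closed-interval rule is this package's documented choice, applied
consistently with the boundary-crosser edge rules (`fad ≥ older ∧ lad <
older` crosses the older edge; `lad ≤ younger ∧ fad > younger` the
younger). Those rules make the four Foote classes an exact partition of
the taxa present in a window — a property-tested invariant.

Per-capita rates: `p = ln((N_bt + N_Ft)/N_bt)/Δt`, `q = ln((N_bt +
N_bL)/N_bt)/Δt`; both are missing, not zero, when no taxon ranges through.
Because the young edge of a compilation truncates ranges, extinction rates
are reported only for labels ≥ 530 Ma and richness only for labels ≥ 522 Ma
by default (both configurable); origination keeps the full grid.
Replicates are summarized by element-wise mean/min/max with pairwise
missing-value handling.

Genus density divides (mean) richness by a rock quantity — total volume
flux, or the volume/area of the hosting lithology — on the same window
grid; zero-rock windows are missing and excluded from any unit-max
normalization.

## Rock-record budgeting

A unit's volume is `area (km²) × mean thickness (km)`; deposition is
assumed continuous over its age span, so volume is spread uniformly and
allocated to 50-ka bins by proportional overlap. Conservation (allocated
volume sums to area × thickness) and linearity over disjoint unit sets are
tested invariants. Lithofacies percentages are taken over the marine
nonevaporitic universe only (numerator and denominator); whether
phosphorite and diamictite belong in that universe is genuinely open, so
both are included by default and togglable.

Area is presence/absence: a region contributes its full terrane area to
every bin in which at least one of its marine nonevaporitic units is
present, reflecting compilations in which per-unit outcrop areas are
unavailable and area largely tracks the presence of preserved marine rock.
The nondeposition fraction is the complementary share of total terrane
area. Region areas are constant through time; a per-unit area column can
override this where a region's record supports it.

`leave_region_out` removes one region from every table so any downstream
statistic can be re-run as a sensitivity test (the classic case being a
single region — e.g. a large, complete platform record — dominating
area/volume trends).

For correlations against window series, 50-ka bins are averaged within
each moving window (bin midpoint membership), matching the
group-and-average convention for lithostratigraphic data.

## Sampling intensity

The count of fossiliferous surfaces (or sites/sections — whatever one row
represents) per window, with a surface counted in **every** window its
permitted interval intersects: for poorly constrained surfaces this is the
maximum possible sampling intensity across the host unit's duration.
Counts retain holdfast-only and taxonomically excluded body-fossil records
that the diversity filters remove; trace-only surfaces are excluded at
data preparation. First differences are deliberately not offered for this
series: stretching surfaces across maximal ranges flattens differences
around zero and makes the transform uninformative.

## Correlation suite

Spearman's rank correlation (average ranks for ties; p-values from the
large-sample t approximation with n − 2 df, via `scipy.stats.spearmanr`)
measures monotonic association, with pairwise deletion of incomplete
pairs and a minimum of three complete pairs. Because moving-window series
are autoregressive, every window-series test is also run on first
differences (`x_{i+1} − x_i`, old → young; missing values propagate).

Isotope series are compared three ways: raw same-sample pairs; 10-point
moving mean of δ¹³C against 10-point moving mean of δ²³⁸U; and moving mean
against 10-point moving **minimum** of δ²³⁸U, the minimum tracking the
reliable baseline through a gappy uranium record. Smoothed points are
reported at the mean age of each k-run and paired by nearest smoothed age
within 0.5 Ma (the pairing rule is not fixed by convention; the gap is
configurable).

Biotic subsets split at the onset age of the basal Cambrian carbon-isotope
excursion (BACE, default 535 Ma); rock units split Ediacaran/Cambrian at
538.8 Ma. A window label (or record midpoint) equal to the cutoff goes to
the older side, matching the ">535 Ma" phrasing of pre-excursion subsets.
How ranges straddling the cutoff should be assigned is not documented
anywhere authoritative; the label/midpoint rule is this package's choice.

## Synthetic data generator

The generator produces datasets with the statistical structure the
analysis assumes, plus a truth record for parameter-recovery tests. It is
a study-condition simulator: it does **not** reproduce real geography,
real isotope curve shapes, or the empirical abundance structure of any
database, so passing recovery tests demonstrates correctness of the
machinery under the stated model, not fidelity to any particular basin.

Defaults chosen once as study conditions: 332 genera split 27/30/24/251
across Avalon (575–559 Ma), White Sea (560–550 Ma), Nama (550.5–538 Ma)
and Cambrian (535–522 Ma) assemblages (81 Ediacaran + 251 Cambrian);
24 regions with log-spaced terrane areas (10⁴–10⁶ km²); uncertainty
category mixture 0.25/0.35/0.25/0.15 with symmetric half-widths
0/0.5/1.5/3.0 Ma. True ranges are (origin uniform in the assemblage
window, duration exponential with 4-Ma mean truncated to the window) —
the simplest right-skewed range model. A category-1 taxon is emitted as a
single full-range record; categories 2–4 are emitted as two endpoint
occurrence records (FAD and LAD occurrence), each carrying its widened
permitted interval, so occurrence-level resampling and the envelope rule
operate as in the real workflow. Rock stacks are built old → young with a
0.3 per-step hiatus probability, lognormal thicknesses (median 200 m) and
exponential unit durations (mean 2 Ma). The geochemical model uses a
smooth sum-of-sinusoids δ¹³C latent plus an antithetic δ²³⁸U latent mixed
to a target Spearman anticorrelation (−0.7 default, the observed scale of
the record), additive Gaussian noise, irregular ages, and a 35% paired
fraction. No distributional statement for any of these exists in the
public record; all are configurable stand-ins.

All randomness flows from `master_seed` through four named SeedSequence
streams (occurrences, rock, geochem, surfaces).

## Problem sizes used in the shipped checks

The test suite and the reproduction script run scaled-down study
conditions chosen as representative defaults: 100 Monte Carlo replicates
(envelope and recovery checks), 200 taxa (50 per assemblage) for
parameter recovery, 100 seeded runs for sign-recovery rates, and
1,000 random range sets (≤50 taxa) for the enumeration oracle. The
replicate count trades envelope width against runtime; at 100 replicates
the min–max envelope already brackets the true richness curve in >95% of
reported windows under the default mixed-uncertainty conditions.

## Known limitations

* The package takes ages, areas and thicknesses as given; it builds no
  age–depth models and estimates no outcrop areas.
* Presence/absence area logic cannot express partial flooding of a
  terrane; with per-unit area overrides absent, area trends reflect
  presence of marine rock only.
* Range-through richness and Foote rates inherit edge effects near the
  grid boundaries; the truncation defaults mitigate but do not remove
  them.
* No occurrence-frequency information is modeled, so coverage-based
  subsampling (e.g. shareholder-quorum) is out of scope by design.
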