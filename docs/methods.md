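# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `gapregen`, and what the synthetic-data tests do and do
not demonstrate about field data.

## Census and coordinate conventions

A stem map is a complete census of woody stems taller than 0.1 m in one
plot, each with species, growth form (tree/shrub), shade-tolerance class
(light-demanding / intermediate / shade-tolerant), local metric coordinates
(+X east, +Y north, origin at the gap or plot centre), height (m) and a
diameter (cm): DBH for stems at or above breast height (1.3 m), root-collar
diameter below it. Three vertical layers partition the censused heights
with half-open bounds — lower [0.1, 5), medium [5, 10), upper [10, ∞) m.
The customary "0–5 / 5–10 / >10" phrasing does not say which layer owns a
boundary height; the half-open convention guarantees every stem exactly one
layer, and is asserted by a property test.

Observation windows are axis-aligned rectangles (30 m × 30 m closed-canopy
controls) or ellipses (gaps). Gap shape is rarely parameterised in field
reports beyond an area, so gaps are modelled as ellipses with a
configurable semi-axis ratio (presets use b/a = 0.8); a circle is the
special case b/a = 1. Gap candidates enter a census when their
diameter-to-canopy-height ratio strictly exceeds 0.73 (the conventional
medium/large-gap threshold), they are undisturbed, and their age is
datable from tree-ring release.

## Importance values, diversity, height comparisons

`IV_i = (RD_i + RF_i + RC_i)/3` with the three components computed from
stem counts, quadrat occupancy on a 3 m grid, and basal area
`a_i = Σ π (d/200)²` m² (d in cm). The three terms are often labelled
relative dominance / frequency / coverage with varying assignments; the
implementation names them by what they are (count-, occupancy- and
area-based) and computes the formula literally. Stems carrying only a
root-collar diameter contribute that diameter to basal area — how
sub-breast-height stems enter dominance is a genuine convention gap, and
excluding them would silently drop most young regeneration. For elliptical
windows the quadrats are the 3 m cells of the bounding box that intersect
the ellipse. Ties in the IV ordering break alphabetically.

Shannon H uses natural logarithms; zero abundances are excluded. Because
whether shrubs belong in richness/diversity alongside trees is often left
implicit, every community metric takes an `include` switch
(trees/shrubs/all) and the pipeline reports tree-only and all-stems values
side by side.

Height comparisons across gap-age classes use classical one-way ANOVA and
Tukey HSD (Tukey–Kramer for the unbalanced groups that real treatments
produce), α = 0.05 by default. The compact letter display uses the
insert-and-absorb algorithm: start from one letter containing all groups,
split on each significant pair, absorb subset letters; letters are ordered
by descending group mean with label tie-breaks, so the display is
deterministic. The degenerate case of zero within-group variance with
unequal means reports F = +inf, p = 0, and is flagged.

## Second-order point-pattern analysis

K follows the ordered-pair definition
`K(r) = s/(n(n−1)) Σ_{m≠n} I(d_mn ≤ r) e_mn` (each unordered pair counted
twice, matching the n(n−1) normalisation). g(r) is estimated directly from
annulus counts with a box kernel — `ĝ(r) = s/(n(n−1)) · Σ_{d∈(r−h,r+h]} e /
(2πr·2h)` — rather than by differentiating K̂, which matches the
"annuli as distance categories" definition and avoids differentiation
noise. The default grid is r = 0.5, 1.0, …, 10 m with half-width
h = 0.25 m (contiguous annuli); analyses of gap regeneration concentrate
on 0–6 m, so 10 m covers the range with margin. The grid is clipped to
half the window's shorter extent.

Edge corrections (the `e` weight, usually left unnamed in field papers):

* **translation** (default for rectangles): `e = |W| / |W ∩ W_v|` for pair
  displacement v; exact and unbiased for rectangular windows.
* **border** (default for ellipses): minus-sampling — only points whose
  full annulus lies inside the window serve as reference points, with the
  remaining n−1 (or n2) points as targets. Valid for any convex window.
  Bins whose reference count falls below 10 are flagged `unstable` in the
  result, not dropped. Distance-to-boundary for ellipses uses a dense
  (1024-vertex) boundary polyline; the chord error is ~10⁻⁴ m, far below
  the 0.25 m bin half-width.

Both estimators are checked against CSR closed forms (E K = πr², E g = 1)
and against a naive O(n²) Python-loop enumeration, pair for pair.

**Envelopes.** Monte Carlo envelopes use 199 simulations and the
2nd-smallest / 2nd-largest simulated value at each r, a pointwise two-sided
level of 2·2/200 = 0.02 (98% envelope). Simulations condition on the
observed count n (conditional CSR) — standard conditional Monte Carlo.
Classification per distance: above the upper envelope = clustered
(univariate) / attraction (bivariate); below the lower = regular /
repulsion; inside = random / independent. The calibration experiment
(`scripts/acceptance.py`) verifies the empirical rejection rate under CSR.
Envelopes are pointwise, not simultaneous: across ~20 bins at level 0.02,
occasional single-bin exceedances are expected under the null.

**Bivariate null.** The default holds pattern 1 fixed and toroidally
shifts pattern 2, preserving its internal clustering — the independence
null proper. Toroidal wrapping is undefined on an ellipse, so for
elliptical gap windows the pipeline falls back to CSR re-randomisation of
pattern 2 (`csr2`), which tests the stronger "complete randomness of
pattern 2" null; both nulls are selectable.

## Kernel density estimation

Each stem contributes a quartic (biweight) bump `K(u) = (3/π)(1−u²)²`,
u = distance/radius ≤ 1, with compact support equal to the search radius
(1 m, the study convention; no bandwidth selection is attempted). The
kernel is normalised in two dimensions so each point integrates to one
stem and cell values are stems m⁻². The 1/(p·r) normaliser that sometimes
accompanies the printed one-dimensional form of this estimator is
dimensionally inconsistent with a density-per-area surface; it is exposed
as `mode="literal"` for comparison, and `mode="probability"` divides by
the point count. Default cell size 0.25 m (guard: ≤ radius/2); extents
snap outward onto a lattice anchored at the origin so rasters from
replicate gaps align exactly. Averaging over replicate gaps is cellwise
over the rasters that cover each cell, with per-cell coverage counts
reported — a small gap's raster does not dilute the mean outside its own
footprint. Rasters export as ESRI ASCII grids and long-format tables.

Midpoint-rule discretisation keeps the raster integral within 2% of the
point count at the default resolution (asserted by test).

## Synthetic generator

The generator exists because fully mapped gap censuses are essentially
never deposited; it reproduces the statistical structure the analysis is
designed to detect, not any particular forest.

* **Processes**: homogeneous Poisson (CSR); Thomas cluster process with
  Poisson parents simulated on the window dilated by 4σ (avoids cluster
  truncation at the boundary), Poisson broods, isotropic Gaussian(σ)
  dispersal, offspring clipped to the window; hard-core patterns by dart
  throwing with rejection (feasibility guard λ·π·d² < 0.5). Bivariate
  structure: independent draws, shared cluster parents (attraction), or
  distance-d thinning of type 2 around type 1 (repulsion).
* **Treatment presets** PYG/POG/PCK/SYG/SOG/SCK echo the printed gap-area
  and gap-age summaries (e.g. PYG 440.7 ± 153.7 m² at 6.3 ± 1.7 yr; 30 m
  controls), drawn from a normal truncated below at 100 m². Demographics
  encode the qualitative regeneration story: clustered lower layers
  densest for light-demanding species in young gaps and shifting toward
  intermediate/shade-tolerant species with gap age; medium layers
  clustered at small scales in primary stands but random in older
  secondary stands; sparse random upper layers; shrubs sharing cluster
  parents with lower-layer trees in young gaps. Lower-layer plot
  intensities of ~0.5–2.6 stems m⁻² per cohort are realistic for temperate
  gap regeneration and give local KDE maxima of order 10 stems m⁻² in
  young gaps; they are stated once in `presets.py` and not fitted to any
  census.
* Heights draw from Beta(2, 2) rescaled to each cohort's layer bounds
  (smooth, bounded, no stronger claim intended); diameters follow
  d = a·h^b cm with lognormal noise (defaults a = 1.0, b = 1.1,
  σ = 0.15 — placeholders, configurable per cohort).
* One root seed spawns independent substreams per plot and per cohort
  (`numpy` SeedSequence), so outputs are reproducible and stable under
  re-ordering.

**What passing tests show.** The suite demonstrates that the estimators
are unbiased under their nulls, calibrated at the stated significance, and
able to recover known generating structure (clustering scale, hard cores,
cross-type attraction/repulsion) at realistic point counts. It does not
validate any ecological claim about real gaps: the generator has no
spatial environmental heterogeneity, no inter-annual dynamics, no
species-specific dispersal kernels, and its allometries are placeholders.

## Problem sizes

The shipped experiments use desk-scale sizes chosen to give the tests
statistical power: envelope calibration at 500 replicates × 199
simulations (n = 100); CSR closed forms over 200 patterns of n = 500;
structure-recovery runs at 100 replicates per scenario. The hard-core
recovery scenario uses a 60 m × 60 m window at 0.03 stems m⁻²: at the
dart-throwing feasibility limit a 30 m window admits too few points
(≈ 35) for the rank-2 lower envelope to lift off zero below 2 m, so the
test would be powerless there; the larger window keeps the generator
within its feasibility guard while giving the envelope test power.

## Known limitations

* Inhomogeneous summary functions, mark correlations, nearest-neighbour
  functions and global (simultaneous) envelope tests are out of scope.
* The border correction discards information near the boundary; for very
  small gaps the flagged unstable tail bins should not be interpreted.
* The dart-throwing hard-core generator is a rejection sampler, not an
  equilibrium Gibbs process; its pair correlation near the core distance
  has the usual slight RSA contact enhancement.
* ESRI ASCII is the only raster format; coordinates are local metres with
  no projection handling.
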