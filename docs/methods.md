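# Methods

This note documents the models, numerical choices and limitations behind
`patchscape`. It is the package's own account; every number quoted here is
computed by the test suite or `scripts/acceptance.py`, not asserted.

## Landscape metrics

**Isolation.** For a focal patch *j*, `I_j = −log_b Σ_k (A_k / d_jk²)` over
all habitat units *k* within a 500 m edge-to-edge radius, with `A_k` the
unit's area (m²) and `d_jk` the minimum boundary-to-boundary distance (m).
Larger values mean fewer, smaller, or more distant neighbours. The log base
is configurable (default 10); every downstream statistic is invariant to
the choice up to an affine rescaling of `I`, because PCA standardises the
variable anyway. Two degenerate cases need policies: touching units
(`d = 0`) have their distance replaced by ε = 1 m (configurable, logged by
the caller), and an empty neighbourhood (Σ = 0, log undefined) returns a
NaN sentinel by default — keeping such patches identifiable rather than
silently extreme — with an optional ceiling value. Historical isolation
uses the same formula against the era's filtered potential-habitat units,
excluding a unit that is the focal patch itself.

**Historical area.** `A_era` is the fraction of the present-day footprint
covered by the union of the era's habitat units. It is evaluated on a
regular grid (default 1 m cells) rather than by exact polygon clipping:
grid sampling is robust to invalid polygons, treats discs — the synthetic
first-class geometry — exactly as polygons, and its convergence is
testable (the unit tests verify the estimate approaches the exact shapely
intersection as the cell size shrinks). Exact shortcuts handle the common
cases of no intersecting unit (0) and full coverage by a single unit (1).

**Abiotic filtering of potential habitat.** Era habitat units are retained
only if every abiotic variable lies within `[min − SE, max + SE]` of the
envelope computed from the old patches; units missing a value are removed
and tallied. The filter is a subset operation and idempotent.

**Patch age.** A patch first visible on map year `m`, with preceding map
`m′`, is dated to `(m′ + m)/2`; a patch on no map appeared midway between
the newest map and the survey; one on the oldest map is anchored at a
configurable pre-map year (default 1788, which at survey year 2009 yields
a maximum age of 221 years). With maps 1843/1954/1980 and survey 2009 the
midpoint rule gives ages 14.5 / 42 / 110.5 / 221. The youngest printed
age in comparable field studies (13) differs from the midpoint arithmetic
(14.5); both are reachable through the survey-year/anchor configuration,
and the midpoint rule is the default because it is the only fully stated
rule.

**TWI.** `ln(As / tan b)` with `As` the specific catchment area and `b`
the slope in degrees; defined for `As > 0`, `0 < b < 90`.

## Diversity metrics

**Gower distance.** Per trait block, the pair dissimilarity is the mean of
per-trait terms: continuous `|x_i − x_j| / range`, binary 0/1 mismatch
(both 0/0 and 1/1 count as agreement — presence-coded life-history traits
are informative in both states), ordinal via Podani's (1999) tie-corrected
rank formula. Missing traits are pairwise-deleted with equal re-weighting
of the rest; a pair sharing no observed trait is masked, not zeroed. A
zero-range trait contributes 0 with a warning. Entries lie in [0, 1].

**Combining blocks.** The overall functional distance is the unweighted
mean of the three block matrices (each block weight 1/3), skipping masked
blocks per pair. The alternative — re-running Gower on the stacked traits —
coincides only when blocks have equal trait counts; mean-of-blocks was
chosen as the reading that gives each trait *group* equal weight regardless
of its size.

**MPD.** The mean of `d(i, j)` over unordered pairs of species present
(presence/absence weighting, diagonal excluded); NaN with a warning below
two species. MPD is insensitive to richness per se, which is why no
null-model standardisation is applied.

**Cophenetic distances.** Path-length sums between tips (via dendropy),
normalised by the matrix maximum by default so PD shares the [0, 1] scale
of FD; raw branch-length mode is available since the scale of any given
published phylogeny is not asserted.

**Community means.** Unweighted trait means over present species, skipping
missing values (no abundance weighting is available for presence/absence
data).

## Inference

**Collinearity screen.** Variables are walked in a caller-supplied priority
order; one is kept only if its |Pearson r| with every already-kept variable
is ≤ the threshold (default 0.5). The pipeline never lets a block fall
below two variables (a two-axis PCA needs them); constant variables (e.g.
age within the new class, where all patches share one appearance window)
are dropped automatically beforehand.

**PCA.** Correlation-matrix eigendecomposition of the transformed (log10
for area, identity otherwise; config-driven) and standardised block
variables; first two axes; each axis is oriented so its largest-|loading|
variable loads positively, making signs deterministic. Rows with missing
values are dropped and reported.

**GLMs.** Poisson log-link for richness counts, Gaussian identity for FD
and PD, fitted by IRLS (statsmodels; convergence tolerance 1e-8, ≤ 100
iterations). Wald `z = β̂/SE` and two-sided normal p-values are reported
for both families. Singular designs and non-integer Poisson responses are
rejected with validation errors.

**Explained variation and partitioning.** `D² = (D₀ − D)/D₀` from the null
and residual deviances (identical to R² in the Gaussian case), adjusted as
`1 − [(n−1)/(n−p−1)](1−D²)` with `p` the number of predictors. The
three-block partition fits the seven models {A, P, H, AP, AH, PH, APH} on
the PCA score matrices (two axes per block), converts each to adjusted
explained variation, and solves the inclusion–exclusion system: e.g.
`unique(A) = adj(APH) − adj(PH)` and
`shared(all) = Σ singles − Σ pairs + adj(APH)`. The seven fractions sum to
`TVE = adj(APH)` identically (the algebra is exact; the container enforces
1e-9). Negative adjusted fractions are reported as computed; only the
optional bar chart floors them at zero. When blocks overlap exactly,
linearly dependent columns are removed before fitting so the combined
models stay identifiable. Patches with undefined FD/PD (fewer than two
species) are excluded listwise from the FD/PD models only.

**Group comparisons.** All old-vs-new contrasts use the Welch two-sample
t-test with Satterthwaite degrees of freedom — the classes are unequal in
size, so the pooled-variance and paired variants are not applicable — and
Benjamini–Hochberg FDR across the variable family, reporting both raw and
adjusted p. Constant variables are flagged and excluded from the family.

## The synthetic generator

The generator emulates the structure of a dry-grassland survey: 272 patches
over an 8 × 8 km extent, about 216 of them "old" (present on the newest
historical map), 99 species, 12 functional traits in three blocks plus
three ordinal ecological indicators with the survey's published scales and
ranges, survey year 2009 and maps 1843/1954/1980. Defaults fixed once:

* patch centres uniform; areas log-normal with log₁₀ mean 3.32 / sd 0.63
  (the old-patch moments of the reference survey); disc geometry;
* abiotic variables (TWI 8.3 ± 1.0, slope 12 ± 5°, elevation 70 ± 34 m,
  June irradiation 5540 ± 200) drawn from Gaussian fields with exponential
  spatial covariance (range 800 m, nugget 0.1) — spatial autocorrelation
  lets the abiotic and landscape blocks be made collinear on demand, which
  is what exercises the shared fractions;
* era presence simulated backward with persistence probabilities
  (P(1954 | 1980) = 0.7, P(1843 | 1954) = 0.6), plus 150 background
  potential-habitat units per map; ages and historical metrics are then
  *computed* by the landscape module, not re-simulated;
* a Yule (pure-birth) phylogeny; traits evolve by Brownian motion on the
  tree and are mapped onto their scales by quantile thresholding, so
  functional and phylogenetic distances are positively coupled;
* occupancy `P(s, j) = logistic(b₀ + b_env·match + b_abi·suit + b_area·logA
  + b_iso·I + b_age·age + b_tx·trait×env)` on standardised predictors.
  `match` is a Gaussian niche kernel between a species' latent
  environmental optimum (evolved on the tree) and the patch TWI; `suit` is
  a direct abiotic-suitability term (slope) acting on all species — the
  niche kernel alone yields a hump-shaped richness response that a linear
  model cannot attribute, whereas real grassland richness also responds
  monotonically to terrain, so both pathways exist. Defaults
  (b₀ = −1.1, b_env = 0.9, b_abi = 0.3, b_area = 0.5, b_iso = −0.35,
  b_age = 0.35, b_tx = 0.2) give mean richness ≈ 30 of 99 with moderate,
  mixed drivers. Patches below three species are flagged (kept by default;
  a redraw switch exists but would bias the model).

What the generator does **not** emulate: mechanistic colonisation–
extinction dynamics through time, seed banks, abundance structure,
observation error in the survey, or realistic terrain (abiotic fields are
stationary Gaussian). Passing recovery tests therefore shows the
*inferential chain* is sound — that known dominant drivers produce the
largest unique fractions — not that any particular field system behaves
this way.

## Problem sizes and numerical choices

The verification suite checks each statistic against an independent
brute-force oracle on 1000 random small instances, and runs driver
recovery on 100 survey-scale studies (272 patches, 99 species) cycling
three single-driver regimes, 30 null studies for partition calibration and
1000 replicated null group-comparisons — sizes chosen to make the binomial
uncertainty of the pass criteria small while keeping the whole suite under
a minute of simulation time. The overlap grid in the generator adapts its
cell size to the largest patch radius (≈ radius/40) so the A_era columns
cost seconds, while the standalone function defaults to 1 m cells.

## Known limitations

* Isolation assumes planar metric coordinates; no geodesic handling (the
  intended extents are a few km).
* The Gower combination rule (mean of blocks) and the cophenetic
  normalisation are documented choices, not the only defensible ones; both
  have switches.
* Adjusted D² for Poisson responses uses the Ezekiel-style correction on
  the deviance scale; other penalised pseudo-R² definitions exist.
* Variance partitioning inherits the usual caveat that shared fractions
  are not variance "explained jointly" in a causal sense; they can be
  negative and are reported as computed.
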