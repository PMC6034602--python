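# Methods

`cytospat` analyses the microspatial structure of mixed-ploidy plant
populations: plots of a few thousand m² in which a diploid taxon (2x),
its derived tetraploid (4x), and their sterile triploid hybrids (3x)
co-occur, every individual mapped with projected planar coordinates.
This note records the statistical models implemented, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Geometry and units

All coordinates are treated as planar Cartesian metres. Survey plots
are georeferenced in a projected (UTM) system and span well under a
kilometre, so projection distortion is orders of magnitude below GPS
error and no geodetic computation is performed. Plot areas use the
shoelace formula; a user-supplied (published) area that differs from
the shoelace value of the supplied corners by more than 0.5 % triggers
a warning, and the supplied value is then used for reporting so that
published summary tables can be reproduced digit for digit. One of the
three reference plots shows exactly this situation (printed 12,826 m²
versus 12,722.5 m² from its printed corners, ≈0.8 %); the package
surfaces the disagreement rather than silently picking a side.

Boundary points count as inside a window: field plots are delimited
with ropes, and individuals recorded on the rope must not be dropped.
Points outside the window are a loud error by default
(`outside_policy="fail"`), with an explicit `"drop"` override that
warns with the number of points removed.

Densities are reported as individuals per hectare, 10,000·n/area.
Report rounding follows the published convention: densities to one
decimal place, cytotype ratios to two, half-up.

## Ripley's K and Monte Carlo envelopes

The within-taxon second-order structure is summarised by the K
function,

    K̂(r) = |A| / (n(n−1)) · Σ_{i≠j} e_ij · 1{d_ij ≤ r},

with πr² as the benchmark under complete spatial randomness (CSR).
Edge correction is the translation correction,
e_ij = |A| / |A ∩ A_shift(i,j)|, which is exact on arbitrary simple
polygons and has no tuning constants; axis-aligned rectangles use the
closed form (w−|Δx|)(h−|Δy|) for speed, general polygons fall back to
polygon–polygon intersection. `edge_correction="none"` is retained
because it admits an exact brute-force oracle. With translation
correction the admissible radius range is capped at half the shorter
bounding-box side (beyond it the weights diverge); the default grid is
512 steps from 0 to a quarter of that side, a common variance-limiting
choice.

The null for classification is CSR **conditioned on the observed
count**: the abundance of the taxon in the plot is treated as fixed and
only locations are randomised (a binomial process). An envelope is
built from `n_sim = 300` independent CSR replicates; the lower/upper
bounds are the pointwise rank-th smallest/largest simulated K̂ values
(default rank 1, i.e. pointwise min/max, the usual default for
simulation envelopes; configurable). Classification is pointwise per
radius — clumped above the envelope, regular below, random inside.
This mirrors the per-distance reading of such envelopes in field
studies; it is *not* a single global test, and the pointwise coverage
(≈ 1 − 2·rank/(n_sim+1) per radius) should not be quoted as a global
type-I error. The envelope seed must be supplied, or it is drawn once
and logged.

## Equal-area density association

The cross-taxon question — does taxon B track the density of taxon A?
— is answered at quadrat scale. Taxon A's intensity is estimated on a
regular lattice of square cells clipped to the window (default cell
size 1 m, the quadrat scale of the field design). Two estimators are
offered: an isotropic Gaussian kernel (default; bandwidth by a pooled
Scott-type rule, always logged) and raw per-cell quadrat counts. The
surface is renormalised to total mass n_A; only the *ordering* of cell
values matters downstream, which is robust to moderate bandwidth
changes — re-running with both estimators is the intended sensitivity
check.

Cells are sorted by (intensity, cell index) — the index tie-break makes
the partition deterministic — and cut into three consecutive groups
whose cell counts differ by at most one: the low/mid/high equal-area
tertiles (all cells share one area by construction). Each B individual
is assigned to its containing cell's region (a B point whose containing
cell was clipped from the lattice falls back to the nearest remaining
cell, logged). Under the null that B is uniform over area and
independent of A, each region expects n_B/3 individuals; the Pearson
statistic Σ(O−E)²/E has 2 degrees of freedom. n_B < 15 triggers an
expected-count warning. Null simulations (500 independent CSR pairs)
put the empirical rejection rate at the nominal 5 %.

## Nearest-parental distance profiles

For each triploid, the Euclidean distance to the nearest diploid and
the nearest tetraploid is computed (k-d tree; verified against a
double-loop oracle). Summary statistics are the arithmetic mean and
the standard error using the n−1 sample standard deviation.

The distance profile reports triploid density (individuals/m²) against
nearest-parental distance. The denominator is the area of the window
at each distance band — the region whose distance-to-nearest-reference
falls in [a, a+Δ) — computed by a discrete distance transform on a
lattice of resolution `grid_res` (default 0.25 m; bands default to
0.5 m, resolving the ~1 m scale of interest). Count conservation
(Σ density·band area = n) holds on every input; a band holding
individuals but no lattice area raises an error instructing a finer
grid. Both the normalised density and the raw per-band counts are
reported, because they answer different questions: for offspring
displaced by an isotropic Gaussian of scale σ_d, the nearest-distance
law is approximately Rayleigh(σ_d), whose *histogram* peaks at the
displacement scale σ_d, while the band-area-normalised density
(≈ f(d)/annulus area ∝ exp(−d²/2σ_d²)) is monotone decreasing from
zero. A "highest density at distance x" reading therefore refers to
the raw histogram; the tests assert the histogram mode accordingly.
Peak detection operates on the binned values directly (strict local
maxima; plateaus take their left edge; peaks closer than
`min_separation` to a taller peak are dropped) — no smoothing, to avoid
introducing a second bandwidth choice.

## Quadrat ecology

Continuous covariates are compared between quadrats with and without a
cytotype by the two-sample Wilcoxon rank-sum (Mann–Whitney) test: the
groups are independent and of unequal size, for which a signed-rank
(paired) test is undefined. Mid-ranks handle ties; the exact null is
enumerated when both groups have ≤ 10 observations and no ties,
otherwise the normal approximation with tie and continuity corrections
applies (verified against full enumeration for all group sizes ≤ 7).

Species presence/absence against cytotype presence/absence uses the
2×2 chi-square **with Yates continuity correction**. This choice is
evidence-based: back-calculating the published adjusted p-values from
the published 2×2 counts reproduces them only with the correction on.
Both families are Bonferroni-adjusted, min(1, p·m); default family
sizes are the number of covariates (10) and the number of species
tested (31 in the reference survey), both overridable — e.g. to m = 30
if one prefers to correct the covariate family across all three taxa.

Bray–Curtis dissimilarities (Σ|u−v| / Σ(u+v)) between quadrat species
profiles are exposed as the input to ordination; the ordination itself
(NMDS stress minimisation, environmental vector fitting) is deliberately
out of scope — any standard implementation consumes the matrix. A pair
of all-zero rows has an undefined dissimilarity and is reported as 0
with a warning.

Soil samples carry seven grain-size fractions (>2 mm, five sieve bands
from 2 to 0.05 mm, and the <0.05 mm pan) constrained to close to
100 ± 0.5 %, pH ∈ [0, 14], electrical conductivity, organic matter,
Munsell hue/value/chroma, and the redness index RI = R²/(B·G³) from
calibrated mean RGB values (a free-iron proxy in dune sands). RGB
calibration and Munsell chart reading are manual/laboratory steps, out
of scope.

## Synthetic data generator

The generator exists so every downstream stage is testable without the
field coordinates, which are distributed only as a supplementary
archive. It emulates the three structural features the analyses rely
on:

- **Within-taxon clumping** — a Thomas cluster process: Poisson(κ·|A|)
  parents (simulated in a 4σ-buffered window to avoid edge bias in
  offspring intensity), Poisson(μ) offspring per parent, isotropic
  Gaussian displacement σ, clipped to the window. Default test
  conditions κ = 0.005 parents/m², μ = 6, σ = 2 m on a 100 × 100 m
  window give ≈300 individuals — the mid-range of the observed plot
  abundances (137–501) at densities of the observed order — with
  clusters at the few-metre scale of the observed aggregation.
- **Triploids near diploids** — each triploid picks a uniformly random
  diploid mother and is Gaussian-displaced by σ_d (rejection-sampled
  into the window, capped at 1,000 attempts so impossible geometry
  errors out instead of hanging). σ_d = 1 m echoes the ~1.3 m observed
  nearest-diploid means; the short-range seed shadow of a plant whose
  fruits mostly fall near the mother.
- **CSR nulls** — exactly n i.i.d. uniform points (count-conditioned),
  matching the envelope null.
- **Quadrat/soil tables** — ~108 quadrats with the diploid present in
  ~45 %, Gaussian covariates clipped to admissible ranges with additive
  presence effects (hemicryptophyte cover +16 points, path distance
  +35 m, richness +2 species where the diploid is present — the
  reported group contrasts), Bernoulli species occurrences conditional
  on diploid presence, Dirichlet grain fractions rescaled to exactly
  100 %, and dune-sand colour with RI computed from it.

Fixed seed ⇒ bit-identical output (NumPy PCG64). What the generator
does **not** emulate: anisotropy along the shore-to-inland gradient,
the pathway network and its disturbance halo, spatial autocorrelation
of the quadrat covariates, interactions beyond the mother–offspring
link, and temporal dynamics. Passing tests therefore demonstrate that
the *statistics* behave as designed under the assumed structure, not
that the field system satisfies those assumptions.

## Numerical conventions and problem sizes

- K̂ accumulates pairwise distances into the radius grid by binning
  (no per-radius loops); equivalence with the O(n²) double loop is
  asserted to 1e-12 relative tolerance.
- Intensity ties in the equal-area partition break by stable cell
  index; partitions are bit-reproducible.
- Chi-square p-values are floored at the smallest positive float to
  keep p ∈ (0, 1].
- Undefined ratios (zero-count denominator taxon) report as NA, never
  as infinity; undefined 2×2 tests (zero marginal) report p = 1 with a
  warning by default, or raise on request.
- Monte Carlo studies in the test-suite and acceptance script use
  100 pattern replicates × 300-simulation envelopes (n ≈ 300 points),
  500 null pairs for the association calibration, and 50–100
  replicates for the proximity statistics; these sizes put the Monte
  Carlo standard error of every asserted rate well inside its
  acceptance margin while keeping a full run in a few minutes.

## Known limitations

- The pointwise envelope classification inflates the family-wise error
  across radii; global rank envelopes are not implemented.
- Translation correction on non-rectangular windows costs one polygon
  intersection per point pair; large patterns in irregular plots are
  slow (rectangles are closed-form).
- The kernel intensity estimator does not correct for mass leaking
  across the window boundary beyond renormalisation; with bandwidths
  much larger than the window this flattens the surface.
- Cross-type second-order statistics (cross-K, pair correlation) are
  intentionally absent; the density-tertile association is the
  implemented reading of the cross-taxon question.
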