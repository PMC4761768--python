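# Methods

This note documents the statistical model behind `distdecay`, the choices
made where the methodology was genuinely open, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Pairwise similarity

Assemblages are binary species lists. For a site pair, `a` is the shared
species count and `b`, `c` the counts unique to each site. Jaccard
similarity `a/(a+b+c)` is the primary index; Simpson similarity
`a/(a+min(b,c))` is provided as the richness-independent alternative
(equal to 1 whenever one assemblage nests inside the other, so it responds
to true turnover only). Both are undefined when their denominator is zero;
since the containers reject sites with no recorded species, this cannot
occur in practice. Abundance data are deliberately rejected: the indices
here are incidence-based, and silently thresholding abundances would hide
an upstream decision the user should make explicitly.

The canonical unrolling of any symmetric pairwise matrix is the upper
triangle in row-major order ((i, j) with i < j), matching SciPy's condensed
form. Nothing depends on which triangle is chosen — only that every
regression and permutation test in the package consumes the same ordering.

## Distance matrices

**Geographic.** Geodesic distance on the WGS84 ellipsoid between site
centroids, computed by a vectorized Vincenty inverse iteration
(sub-millimetre agreement with Karney-style reference implementations on
test pairs; validated against `geosphere::distGeo` values frozen into the
test suite). Nearly antipodal pairs, where Vincenty's iteration can fail to
converge, fall back to the spherical haversine distance — irrelevant for
regional surveys but it keeps the function total. Treating polygonal survey
units as centroid points is a deliberate simplification; polygon-aware
distances are out of scope. The mean-radius sphere deviates from the
ellipsoid by at most ≈0.56% (meridional arcs); within a mid-latitude
regional window the deviation is below 0.5%, which is the bound the test
suite asserts there.

**Environmental.** The environmental block is standardized per variable
(zero mean, unit variance) and decomposed by PCA — equivalent to PCA on the
correlation matrix, which stops large-unit variables from dominating.
Constant variables carry no correlation information and are dropped with a
warning. Retention keeps the smallest k axes whose cumulative explained
variance reaches `variance_target` (default 0.95); a fixed `n_components`
override exists because published analyses often pin the axis count.
Environmental distance is then the unweighted Euclidean distance between
retained score vectors. Weighting axes by eigenvalue was considered and
rejected: the reduced scores are treated as a single multivariate
environment variable, and the unweighted form is the standard reading of
"distance in the space of the retained components". Distances are invariant
to the sign indeterminacy of PCA axes (tested).

**Isolation and heterogeneity proxies.** Absolute pairwise differences of
mean elevation and of elevation range, plus area difference for incremental
checks. These are plain |x_i − x_j| matrices.

## Decay regression and halving distance

Each of the three decay forms is fitted by OLS on its own linearizing
transform: y on x (linear), y on ln x (logarithmic, zero-distance pairs
excluded with a logged count), ln y on x (exponential, zero-similarity
pairs excluded likewise, multiplier recovered as exp(intercept)).
Log-transform OLS for the exponential form is the standard distance-decay
practice; a nonlinear least-squares fit of the untransformed exponential
would weight large similarities more heavily and is not what regional
turnover studies conventionally report. R² is reported on the transformed
scale of each fit — the scale on which the OLS ran — so the three forms'
R² values are each meaningful for their own fit but are not a
model-selection statistic (no AIC machinery is provided, by design).

Initial similarity S0 defaults to the maximum observed pairwise similarity
of the region (1 wherever an identical site pair exists); a fixed value can
be supplied instead, since "initial similarity" is also sometimes read as
the similarity at minimal distance. The halving distance solves
`model(x) = S0/2` in closed form:

* linear: `(b − S0/2)/(−a)`, requires `b > S0/2`;
* logarithmic: `exp((S0/2 − b)/a)`, always solvable for a < 0;
* exponential: `ln(2b/S0)/(−a)`, requires `2b/S0 > 1`.

A non-negative slope raises "no decay"; unreachable half-similarity raises
rather than returning an extrapolated negative distance. Values are kept at
full precision; display rounding to integer km happens only at output.

Significance: because pairs sharing a site are not independent, parametric
p-values would inflate degrees of freedom. The package permutes the site
labels of the similarity matrix — rows and columns simultaneously, which
preserves the symmetric pair structure (permuting rows alone destroys
symmetry, a mistake the suite tests for explicitly) — refits, and reports
the one-sided add-one-corrected `p = (1 + #{R²_perm ≥ R²_obs})/(n_perm+1)`,
minimum `1/(n_perm+1)`. When n! ≤ n_perm the full permutation group is
enumerated instead and p is exact (identity included, so p ≥ 1/n!).

## Mantel tests, MRM, variation partitioning

Simple Mantel r is the Pearson correlation of two pair vectors; its null
distribution comes from the same row/column-coherent relabeling. Two-sided
p is the default because turnover correlations are signed; one-sided tails
are available. Partial Mantel uses the residual method: both pair vectors
are residualized by OLS (with intercept) on the control matrices' pair
vectors, r is the correlation of residuals, and the permutation scheme
permutes the residuals of the first matrix folded back into symmetric form
— the approach of the `ecodist` lineage. Raw-matrix permutation is a known
alternative; residual permutation was chosen and is documented here because
the two can differ under strong confounding. Multiple controls are handled
by multivariate OLS residuals.

MRM is OLS of the response pair vector on several predictor pair vectors,
with collinear designs rejected by a rank check, and permutation of the
response matrix for significance. Variation partitioning fits the seven
predictor subsets of {G, E, A} and solves the Venn fractions by
inclusion–exclusion; the seven fractions sum to R²(GEA) to 1e−10 by
construction (asserted on random instances). Joint fractions may be
negative (suppression); they are reported as computed, never clipped. Raw
R² is used throughout, not adjusted R²: the partition is of the fitted
variance of a specific model family, and mixing in per-model df corrections
would break the Venn algebra. Incremental ΔR² for an extra matrix is the
nested-model difference, non-negative by construction.

## Zonation

Bands along latitude, longitude or mean elevation use half-open intervals
[low, high) with the top interval closed above — a convention chosen once
because verbal band definitions ("<2000 m", "2000–3000 m") leave boundaries
ambiguous. Sites outside all intervals are excluded with a warning (band
edges are configuration, not inference; excluding a data-deficient band is
an explicit config act). Each zone is re-analysed self-contained: species
absent from the zone are dropped, the geographic and similarity matrices
are zone-local, and S0 is the zone's own maximum observed similarity, which
is why zone-level S0 can be < 1.

## Synthetic generator

The generator emulates the structure of a mountainous county-level survey:

* **Landscape.** Sites on a jittered grid in a lon/lat box; elevation from
  a small number of Gaussian-profile ridges whose crest lines share one
  orientation (default south–north, so elevation varies east–west);
  elevation range as local surface relief; environmental variables as
  standardized mixtures `corr·smooth + (1−corr)·noise`, where the smooth
  part combines linear trends in position and elevation with low-frequency
  sinusoids. `env_spatial_corr` is therefore the single dial between a
  geography-confounded and a spatially unstructured environment.
* **Species.** Each species draws a range centre (uniform in the box), a
  radius (exponential around `range_scale_km`, floored at 10% of it), and —
  when niche filtering is on — an optimum (a random site's standardized
  environment plus N(0, 0.3) jitter) and a breadth (±25% around
  `niche_breadth`, in RMS standardized-environment units). Presence
  requires effective distance < radius AND RMS environmental mismatch <
  breadth, whichever mechanisms are enabled.
* **Isolation.** Effective distance = geodesic × (1 + barrier_penalty ×
  ridge crossings) × (1 + barrier_elev_scale × normalized elevation of the
  endpoints). Crossings are counted on the straight path in the
  ridge-normal coordinate. This is deliberately crude — no least-cost
  paths — but suffices to make turnover anisotropic and elevation-
  dependent with a one-line ground truth.
* **Richness calibration.** When a target band is set, a global radius
  multiplier is bisected in log scale (≤40 steps) until mean richness hits
  the band midpoint; each site's membership is then clamped into the band
  by ranking species on their marginality score max(distance/radius,
  mismatch/breadth) — under-rich sites gain their least-marginal absent
  species, over-rich sites keep their least-marginal members. The clamp
  preserves the distance-driven ranking and makes the band a hard
  guarantee. Species left with zero occurrences get their single
  least-marginal site. All randomness flows from one integer seed through
  named substreams (ridges / landscape / occurrence), so identical seed +
  config reproduce outputs exactly; ridge geometry is re-derivable from the
  seed alone, keeping landscape and occurrence stages consistent.

The default configuration generates 164 sites × 191 species over
21–35°N × 92–106°E with richness calibrated into [17, 87] — the shape of
the survey the analysis chain is designed around (`demo_dataset`). Three
factory configs define mechanism-isolation experiments: `dispersal_only_config`
and `niche_only_config` (each with the other mechanism off and
`env_spatial_corr=0`, so the competing predictor cannot proxy the active
one) and `isolation_gradient_config` (elevation-scaled barriers). These are
the conditions under which the acceptance suite asserts mechanism recovery:
the pure geographic fraction dominates the partition under dispersal-only
generation and the pure environmental fraction under niche-only generation
in ≥8 of 10 seeds; zone-wise halving distance decreases with elevation
(negative Spearman rank correlation over quartile zones, logarithmic form)
in ≥8 of 10 seeds. The logarithmic form is used for the gradient because
its halving distance exists for every decaying fit, whereas the linear and
exponential forms can leave S0/2 unreachable in high-turnover zones.

What the generator does **not** emulate: real occupancy noise (detection
error, survey effort), phylogenetic structure, historical range dynamics,
abundance, and polygonal survey units. Passing mechanism-recovery tests
therefore shows the *estimators* attribute variance correctly under clean
generating mechanisms — not that any field dataset satisfies those
mechanisms.

## Numerical choices and problem sizes

* OLS via explicit centred sums (simple regression) and `numpy.lstsq`
  (multiple regression); collinearity rejected via matrix rank, except in
  incremental ΔR² where a rank-deficient augmented design is legitimate
  (the minimum-norm solution leaves the fitted subspace unchanged, making
  ΔR² = 0 for a duplicated predictor).
* Permutation comparisons use an 1e−12 slack so ties count as extreme,
  keeping p conservative; add-one correction everywhere Monte Carlo
  sampling is used; exhaustive enumeration below n! ≤ n_perm.
* Symmetric matrices are symmetrized to (M + Mᵀ)/2 on construction after a
  1e−8 asymmetry check; similarity diagonals forced to 1, distance
  diagonals to 0.
* Default test-suite problem sizes: calibration 500 null datasets of 20
  sites at 199 permutations; mechanism recovery 10 seeds of 45 sites × 120
  species; isolation gradient 10 seeds of 64 sites × 140 species — sizes at
  which every statistical property asserted is already stable, keeping the
  whole suite under a minute.

## Known limitations

* Vincenty (not Karney) geodesics: no convergence guarantee for
  near-antipodal pairs (handled by spherical fallback) — irrelevant at
  regional scale, inelegant globally.
* The exponential form's R² is computed on the log scale; comparing it
  numerically against the other forms' R² conflates scales (documented
  rather than "fixed", since the per-form fits are each reported on their
  own OLS scale).
* Partial Mantel's residual-permutation p is known to be anticonservative
  under strong spatial autocorrelation of the control; the test suite
  checks calibration only under exchangeable nulls.
* The barrier model counts straight-line crest crossings; corridors,
  passes and river barriers are not represented.
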