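# Methods

This note records the models, the defaults and the reasoning behind the
design choices; the numbers quoted as defaults are what the code ships
with, and nothing here asserts an empirical result the tests or
`scripts/acceptance.py` do not themselves compute.

## Data model and stopover detection

An Argos fix is (bird, UTC timestamp, lon, lat, location class). Classes
A/B/Z carry no usable accuracy estimate and are excluded before any
analysis; classes 3/2/1/0 bound the positional error at <250 m, 250–500 m,
500–1500 m and >1500 m. Duplicate (bird, timestamp) rows keep the better
class, ties keep the first — Argos feeds occasionally deliver duplicates
and a deterministic rule is required for reproducibility.

Sites are built by *sequential chaining*: a fix joins the current site iff
its distance to the previous fix is < 0.4°, otherwise a new site starts.
Distance is Euclidean in degree space because the threshold itself is
quoted in degrees; a great-circle variant is available behind a flag but
is deliberately not the default — converting silently would change which
fixes chain at these latitudes, where 0.4° of longitude is ~30 km but 0.4°
of separation mixes both axes. The site position is the per-coordinate
median of its member fixes (robust to one bad class-0 fix). Sites are
single-position (1 fix), stopovers (occupancy ≥ 2 days, configurable) or
short stops otherwise. The first and last site of each bird are its
wintering origin and final position: they anchor the route and are never
treated as migration stopovers, whatever their occupancy.

Duty-cycle arithmetic: with an off:on cycle of 48:10 h, a window that
yields no fix extends the silence to at least off+on+off = 106 h. This
bounds duration censoring: with passes in every window a stopover's fix
span can understate its true duration by at most one full period (58 h) on
each side, which the recovery tests assert.

## Availability sampling

The route is the polyline origin → stopovers (temporal order) → terminus
with linear lon/lat interpolation inside segments and great-circle
(haversine, R = 6371.0088 km) segment lengths. Availability points are
uniform in along-route arc length within ±184 km of the stopover's route
position (two-sided by default; the transect length is one travel day at
184 km/day), clipped to the route ends, with rejection sampling enforcing
≥ 0.4° centre-to-centre separation from the stopover and between points of
one replicate so that availability buffers do not overlap the use buffer.
Two points × four replicates per stopover; four is exactly
floor(184 / (2 × 0.2° × 111.32 km/°)), the number of disjoint 0.2° plots a
transect can hold. Infeasible geometry (e.g. a 10 km transect with 0.4°
separation) raises after 10 000 attempts rather than silently relaxing the
constraint. Points before the first or after the last stopover are
permitted; they are ordinary route positions.

## Composition extraction and PCA

A raster cell belongs to a buffer iff its centre lies within the radius —
the standard zonal-statistics convention, deterministic under regridding.
Degree radii use a circle in degree space (matching the 0.2° "home-range"
buffer definition); metre radii (the 1500–21000 m sweep) use great-circle
distance. The unit travels with every composition row and is never
converted implicitly. Nodata cells are excluded from the denominator;
water is an ordinary class. Rows sum to 100 by construction.

The PCA is an eigendecomposition of the *covariance* matrix of
compositions expressed as fractions, not of the correlation matrix:
compositional classes differ in variance by orders of magnitude and the
rare-class axes a correlation PCA would inflate are exactly the ones a
selection model should not be handed. (On fraction scale the eigenvalues
of a mosaic landscape come out at ~10⁻²–10⁻¹, and the retained five
components typically carry ~85–93% of the variance.) Zero-variance columns
are dropped with a logged notice before the decomposition — they would
make the spectrum degenerate. Eigenvector signs are fixed by making the
largest-magnitude loading of each component positive, so runs are
comparable; `cropland_axis` reports which retained component is most
aligned with the summed cropland + cropland-mosaic indicator and with what
orientation, which is how the recovery experiments identify "the cropland
PC" without hand inspection. One PCA is fitted on the pooled table (use
rows once, availability rows of all four replicates) and its scores are
used by every replicate's model.

## The mixed logistic model

logit P(use) = β₀ + Σⱼ βⱼ PCⱼ + bᵢ, bᵢ ~ N(0, σ²) per bird, fitted by
maximum marginal likelihood. The per-group integral is evaluated by
adaptive Gauss–Hermite quadrature: a Newton search finds each bird's
posterior mode, the nodes are centred and scaled there, and 15 nodes
(9 in the Monte-Carlo suites) integrate the conditional likelihood. The
gradient is the posterior expectation of the complete-data score,
evaluated with the same nodes, which keeps objective and gradient
consistent and was verified against finite differences at 1e-9. σ is
optimised on [0, 20]; a boundary fit σ = 0 is legal and reduces exactly to
plain logistic regression (asserted against an independent GLM fit). The
implementation agrees with `lme4::glmer` (nAGQ = 25) to ~1e-4 on
coefficients, σ and log-likelihood on a fixture; lme4 is a test oracle
only, never the implementation. Wald SEs come from the observed
information of the β block at (β̂, σ̂); quasi-separation is flagged when
any |β̂ⱼ|·SD(xⱼ) exceeds 12 — a huge coefficient on a tiny-variance score
is a legitimate fit, a huge standardised effect is not — and flagged fits
are excluded from averaging.

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with k = fixed effects (incl.
intercept) + 1 for σ². All 2⁵ additive subsets (including intercept-only)
are enumerated; the ΔAICc < 2 subset is averaged with renormalised Akaike
weights, *full* (zero-substitution) averaging, and unconditional standard
errors SEⱼ = Σᵢ wᵢ √(SEᵢⱼ² + (βᵢⱼ − β̄ⱼ)²); P-values are two-sided normal.
Full averaging is chosen over conditional averaging because the scientific
question is "does this axis matter at all", for which shrinkage of terms
absent from good models toward zero is the honest answer.

## Spatial autocorrelation control

Moran's I on the model's conditional response residuals (y − P̂ with the
bird modes plugged in), inverse great-circle-distance weights with zero
diagonal, significance by permutation (999 permutations by default, 199 in
the Monte-Carlo suites) against the null expectation −1/(n−1), two-sided.
Duplicate coordinates are jittered by 1e-6° with a notice. If P ≤ 0.05 the
table is thinned by 10% of rows, stratified by bird so no bird empties,
and the fit/test loop repeats (the trace is returned and written to JSON);
it aborts with a diagnosis if fewer than 3 birds or 9 rows would remain or
after 50 rounds. The 10% schedule is a compromise between convergence
speed and not overshooting the smallest decorrelated table.

Replicates are decorrelated and dredge-averaged independently; the global
model is the unweighted per-term mean of the four averaged β, with
SE = √(mean(SE²) + var(β across replicates)) — the between-replicate
variance term acknowledges that the four averages are four draws of the
same availability design, and ignoring it would understate uncertainty.

## Buffer sweep and duration correlations

The sweep refits the full five-PC model on the replicate-1 points at each
of the 14 metre radii, with a fresh extraction and a fresh PCA per radius,
reporting AICc, ΔAICc and deviance sorted ascending; a radius whose fit
fails is reported with the error rather than aborting the sweep.

The ten Spearman tests (duration × PC1–5, longitude × PC1–5 at the 0.2°
buffer) use average-rank ties — durations quantised by duty cycles tie
often — and a two-sided P from the t approximation for n ≥ 10 or exact
enumeration of all n! rank orderings below that. Significance flags use
the Bonferroni threshold 0.05/10 = 0.005. All detected stopovers enter
these tests, not the decorrelated subsample: the correlations are
descriptive of the stopovers themselves, and the subsampling is a device
for the use–availability contrast only.

## The synthetic world

The generator is the package's ground-truth instrument; its defaults are
the study conditions and are not tuned per experiment.

**Raster.** Geographic grid, 0.0027° cells (~300 m at mid-latitudes) by
default, GlobCover 2009 integer codes, nodata 255, written as ESRI ASCII
grid + JSON legend. Structure at three scales: (i) a baseline class
mixture resembling the flyway's reported stopover landscape (~20%
cropland, ~30% cropland-bearing mosaic, ~25% closed forest, the remainder
grass/shrub/sparse/flooded/urban/bare/water); (ii) a regional
agricultural-intensity factor, piecewise constant on 0.75° (~75 km)
blocks, g ~ N(0, 0.8), multiplying cropland-bearing class weights by e^g
and forest weights by e^−g — agricultural basins interleaved with
forested uplands, the dominant compositional axis of European mosaic
landscapes, at a scale well below the ±184 km availability transect so
that the use–availability contrast has something to measure; (iii)
categorical mosaic patches of 0.1° (~11 km) within regions. On top, the
expected rainfed-cropland weight declines west→east at 0.0015 per degree
(≈29% at the Atlantic end to ≈11% in Siberia, with the other classes
renormalised), reproducing the continental cropland→forest gradient.

**Birds.** 9 birds; origins uniform in a north-Iberian box, destinations
in a central-Siberian box, giving ~6500 km routes travelled in daily
184 km steps along the lon/lat straight line (the truth record keeps the
along-path sum of daily displacements, which exceeds the single great
circle by a few percent at these latitudes). Stopover count per bird is
max(1, Poisson(2.8)); landing candidates are the end-of-day positions,
scored by the cropland+mosaic fraction in a 0.2° buffer, standardised per
bird across candidates. Stopovers are drawn by softmax with logits
β_sel × score — β_sel = 0 is *exactly* the uniform null, and because the
scores are standardised β_sel is a log-odds per SD (β = ln 3 ⇒ odds ratio
3 per SD of cropland score). Durations are
max(2, round(exp(log 5 + β_dur × score + N(0, 0.5)))) days: median ~5 days
with a several-day to two-week range, long enough that the 48:10 duty
cycle detects most stays, as spring staging of this kind of migrant
requires. Four stationary days pad the wintering and arrival ends.

**Telemetry.** Emission only inside on-windows of the 48:10 cycle (random
phase per bird), three evenly spaced satellite passes per window, each
succeeding with probability 0.8; location classes drawn as
3/2/1/0 = 15/25/35/25% with A/B/Z injected at 15%; isotropic positional
noise of 0.12/0.35/0.9/2.5 km SD for classes 3/2/1/0 (5/10/30 km for
A/B/Z, which the filter removes anyway) plus 0.03° of within-site
movement. Timestamps are UTC; nocturnality is not modelled beyond the
duty cycle, and travel-day discretisation of landing is a modelling
assumption, not an inference about the species.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: wind and weather, energetics, real
GlobCover spatial textures (roads, rivers, city halos), Argos error
ellipses (noise is isotropic), irregular satellite pass schedules, tag
failure, and non-random stopover revisitation. The neutral-world
calibration shows the *pipeline* adds no false selection signal; it cannot
show that real woodcock data meet the model's assumptions.

## Problem sizes and numerical choices

Demonstration runs and the determinism checks use 0.0125° raster cells —
1/20 of the default cell count while still guaranteeing that the smallest
1500 m sweep buffer contains at least one cell centre (cell half-diagonal
≈ 980 m < 1500 m). The 100-seed Monte-Carlo experiments use 0.025° cells,
199 Moran permutations and 9 quadrature nodes; at those sizes one world
takes ~1–2 s and the full neutral + selective suites run in minutes. The
fitter's tolerances are L-BFGS-B ftol 1e-13 / gtol 1e-7; quadrature was
checked at 25 nodes against lme4. One master seed derives per-stage
sub-seeds through `numpy.random.SeedSequence`, so every table the pipeline
writes is bit-reproducible from the manifest.

## Known limitations

Wald inference with 9 birds undercovers slightly when the random-intercept
variance is material (a few-clusters effect inherent to the design, not to
the implementation); the duration estimates are duty-cycle-censored spans,
biased low by up to ~2.4 days for short stays; sequential chaining can
split one biological stopover into two sites if a single bad fix exceeds
the 0.4° step; and the longitude×PC correlations test a genuinely non-null
quantity whenever the landscape has a real longitudinal gradient, so their
Bonferroni flags are true positives of landscape structure rather than
evidence about bird behaviour.
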