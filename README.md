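# stopover-rsf

Meso-scale use–availability habitat-selection analysis of migratory
stopovers from Argos satellite telemetry.

Many landbird migrants cross mosaic agro-forest landscapes in which, at the
scale of a landing decision (~20 km), suitable habitat may be effectively
everywhere. Testing whether such a migrant *selects* habitat when it stops
over requires contrasting the land cover at the sites a bird actually used
against the cover at sites it could have used along its own route. This
package implements that entire analysis chain for duty-cycled Argos
tracking data, together with a synthetic-world generator with known
selection strength so every stage can be validated against ground truth.
It is aimed at movement ecologists working with satellite-tagged migrants
(the motivating system is the Eurasian woodcock *Scolopax rusticola* on its
~6500 km spring migration from Iberia to Siberia) and at methodologists who
want a fully testable reference implementation of the workflow.

## The analysis

1. **Stopover detection.** Argos fixes are filtered to location classes
   0–3; a bird's consecutive fixes closer than 0.4° chain into a *site*
   whose position is the per-coordinate median; sites occupied ≥ 2 days are
   stopovers. Duty-cycle arithmetic (e.g. a 48 h : 10 h charge/emit cycle
   goes silent ≥ 106 h when one window yields no fix) bounds the temporal
   censoring of durations.
2. **Route-constrained availability.** The migration route is the polyline
   through the wintering origin, the stopover medians and the final
   position. For each stopover, 2 random points are drawn uniformly in
   along-route arc length within a ±184 km transect (one travel day at the
   estimated migration speed), at least 0.4° from the stopover and from
   each other, in 4 independent replicates — 4 being the number of
   non-overlapping 0.2°-radius plots a 184 km transect can hold.
3. **Habitat composition.** Per-class percentage cover of a
   GlobCover-style categorical raster is extracted in a 0.2° buffer
   (cell-centre inclusion), and summarised by a covariance-matrix PCA of
   the compositions as fractions; the first five components are the
   habitat axes.
4. **Selection inference.** Use (1) versus availability (0) is modelled as
   logit P(use) = β₀ + Σⱼ βⱼ PCⱼ + bᵢ, with a per-bird random intercept
   bᵢ ~ N(0, σ²), fitted by maximum likelihood with an adaptive
   Gauss–Hermite approximation. All 2⁵ additive fixed-effect subsets are
   ranked by AICc and the ΔAICc < 2 subset is model-averaged (full
   averaging, Akaike weights, unconditional SEs). Before averaging, each
   replicate is randomly thinned until Moran's I on the model residuals
   (inverse-distance weights, permutation test) is non-significant; the
   four replicate averages are then pooled into a global model.
5. **Scale sensitivity and duration.** The full model is refit at 14
   buffer radii (1500–21000 m in 1500 m steps) and ranked by AICc; and ten
   Spearman correlations (stopover duration × PC1–5, longitude × PC1–5)
   are tested at the Bonferroni-corrected level 0.05/10 = 0.005.

## Worked example

One command simulates a world (9 birds, neutral habitat use), runs the full
pipeline and writes every table:

```sh
stopover-rsf run-all --simulate --seed 7 --out demo/
```

prints

```
stopovers: 25
global averaged model:
     term      beta       se        p
Intercept -0.559098 0.286349 0.050878
      PC1 -0.012348 0.466992 0.978905
      PC2 -0.214604 0.723386 0.766721
      PC3 -1.069151 2.385775 0.654055
      PC4 -0.080609 0.425221 0.849647
      PC5 -0.273979 0.979914 0.779789
outputs in demo/
```

Reading the output: 25 stopovers were detected and contrasted with
2 × 4 × 25 availability points. The intercept is near ln(1/2) ≈ −0.69, the
base rate implied by 1 use : 2 available rows per replicate; every PC
coefficient is small relative to its (unconditional) standard error, i.e.
no habitat axis separates used from available sites — correct, because this
world was simulated with selection strength zero. `demo/` then contains
`sites.csv`, `availability.csv`, `compositions.csv`, `pca_loadings.csv`
(PC1 is the cropland↔forest axis, 45.7% of variance in this run), the four
per-replicate averaged models, `buffer_sweep.csv` (14 rows whose AICc
spread is small when, as here, composition is scale-stable) and
`duration_correlations.csv` (all ten non-significant at 0.005). Simulating
instead with `beta_sel = beta_dur = ln 3` (odds ratio 3 per SD of cropland
score) makes the cropland-loaded PC significantly positive and makes
duration × cropland-PC the strongest of the ten correlations — see
`stopover_rsf.calibration`.

The library is importable piecewise (`detect`, `sample`, `extract`, `fit`,
`sweep`, `duration` subcommands mirror the module functions) and every
stage is deterministic under a seed.

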