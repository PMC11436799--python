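# Methods

## The problem

Field surveys of rice production record, for thousands of fields, what the
farmer did (fertilizer rates, irrigation events, sowing date, variety class),
the seasonal weather, and the yield achieved. `paddygap` turns such a table
into an intervention-targeting analysis: how large is the gap to the yields
the best local farmers already obtain, which management practices account for
it, *where* do they bind, and what would closing them deliver in production,
input use and profit — comparing uniform ("blanket") recommendations against
recommendations targeted at the fields predicted to respond.

## Pipeline

1. **Attainable yield.** For a region, the attainable yield `Y_att` is the
   mean observed yield of the top decile of fields (yield ≥ the empirical
   90th-percentile cutoff, linear-interpolation quantile, ties included). The
   attainable yield gap of every other field is `Y_att − y_i`, strictly
   positive because the cutoff never exceeds the top-decile mean.

2. **Yield model.** A random forest regresses observed yield (t ha⁻¹,
   untransformed) on the encoded predictors. Overfitting survey noise is
   controlled by a floor on terminal-node size (default 50 observations per
   leaf); `mtry` defaults to ⌈p/3⌉. The out-of-bag R² is reported next to the
   training R² (and optionally a small cross-validated grid over node size
   and mtry), because "variance explained" is ambiguous between the three and
   they can differ by tens of points.

3. **Sequential ICE decomposition.** Management variables are ranked by
   permutation importance (mean increase in squared error; name-order tie
   break for reproducibility). For each field, the prediction is swept over a
   grid of levels of the top variable — observed data range, never
   extrapolated; 10 kg ha⁻¹ steps for N, 1 event for irrigation, 5/10/2
   kg ha⁻¹ for P/K/Zn, 5 days for sowing date — holding everything else at
   the field's reported values. `Yg1` is the gain from moving to the curve's
   optimum; the optimum is substituted and the sweep repeated for the
   second-ranked variable to give `Yg2`. Optimal-level ties resolve to the
   reported value when it attains the maximum (no change recommended when
   indifferent), otherwise to the smallest level attaining it
   (resource-minimizing). Both gains are ≥ 0 because each grid effectively
   contains the field's current operating point.

4. **Shapley attribution.** The Shapley value φ_j of predictor j for a field
   is its contribution, in t ha⁻¹, to that field's prediction relative to the
   mean prediction over a background population. We use the *interventional*
   expectation — coalition value v(S) replaces out-of-coalition features with
   background records — so additivity `base + Σφ = prediction` is exact. The
   implementation enumerates, per (field, background) pair, the tree leaves
   reachable by any hybrid of the two records; a leaf reached with `a`
   features committed to the field and `b` to the background contributes its
   value times the closed-form weight `1/(a·C(a+b,b))` to each field-committed
   feature (negated analogue for background-committed ones). This is exact,
   not sampled; an exhaustive subset-enumeration oracle (≤ 12 features)
   cross-checks it in the tests. The background is the explained table itself,
   subsampled deterministically to 128 rows when larger so the pairwise
   traversal stays tractable at 5,000 fields on one CPU; the base value is the
   mean prediction over that background.

5. **Co-limitation clusters.** Fields are classed by the sign of φ for the
   number of irrigations (I) and the N rate (N): I⁻N⁻ is co-limited, I⁺N⁺
   limited by neither; φ = 0 counts as non-limiting since a zero marginal
   contribution promises no gain from change. Shares are reported overall and
   per district.

6. **Hotspots.** Local spatial clustering of φ is scored with the
   self-inclusive Getis-Ord Gi* z-statistic under binary weights within a
   fixed great-circle band (default 10 km; haversine on a 6371.0088 km
   sphere). Fields with z beyond the two-sided normal critical value are hot
   (consistently high φ) or cold (consistently low φ — an opportunity zone);
   no multiplicity correction is applied to the map classes by default,
   matching standard practice for these maps, with alpha configurable. If
   every pair falls inside the band the z denominator is identically zero and
   all z are reported as 0. Isolated fields keep their (self-inclusive) score
   and are flagged via the neighbour count.

7. **Scenarios.** Four counterfactuals: (1) blanket 125 kg N ha⁻¹ (state
   recommendation); (2) blanket 180 kg N ha⁻¹ (analytics-derived
   population-level non-limiting rate); (3) 180 kg N ha⁻¹ only for fields
   with φ_N < 0; (4) 180 kg N ha⁻¹ *and* 5 irrigations only for I⁻N⁻ fields.
   Blanket scenarios impose the rate downward as well as upward; targeted
   scenarios only raise inputs. District deltas scale the mean per-field
   delta (non-adopters contributing zero) by the district rice area; one
   surveyed field is treated as representative of one hectare when scaling
   irrigation event counts. Partial net returns per adopting hectare are
   `Δyield × paddy price − ΔN × N cost − Δirrigations × irrigation cost`
   (defaults $0.14 kg⁻¹ N and $20 per irrigation; the paddy price has no
   default and must be supplied — the acceptance script passes 250 USD t⁻¹,
   the 2018 minimum support price at ≈ ₹70/USD). Marginal N-use efficiency is
   Σ extra grain (kg) / Σ extra N (kg) over fields receiving extra N, and is
   undefined (NaN) when none does. A `derive_blanket_rate` helper reads the
   population-level rate off the partial-dependence curve (smallest rate
   attaining its maximum); a plateau criterion would give a lower rate, and
   this choice is flagged as an interpretation.

## Synthetic landscapes

The generator emulates the *structure* of a landscape crop-assessment survey,
not any real joint distribution. Expected yield is additive:
Mitscherlich-type saturating responses for N (asymptotic gain 2.0 t ha⁻¹,
e-folding scale 60 kg ha⁻¹, hard plateau at 180 kg ha⁻¹) and irrigation
(1.8 t ha⁻¹, scale 2.2 events, plateau at 5 events), linear terms for
seasonal radiation and maximum temperature, a late-sowing penalty, small P
and Zn slopes, a deliberately null K effect (a no-signal control feature),
a three-level ordinal variety effect, and i.i.d. Gaussian noise (default SD
0.4 t ha⁻¹). The saturating-with-hard-plateau form gives diminishing returns
like real N-response curves while remaining analytically differentiable and
exactly flat beyond the plateau, which the tests exploit as closed-form
oracles.

Each field draws a latent limitation class with shares 35% neither-limited,
35% irrigation-limited, 20% co-limited, 10% N-limited; deficient classes draw
inputs well below the response scale (N 20–80 kg ha⁻¹, 1–2 irrigations) and
adequate classes near or beyond the plateau (N 130–200, 5–7 irrigations).
Districts tile a 2° × 2° extent as a grid; fields are uniform within their
district, giving ~35 neighbours within a 10 km band at 5,000 fields — enough
for the Gi* statistic to be meaningful at desk scale. Planted circular
"hotspots" override the class spatially (by default one N-depleted circle of
15 km radius and one irrigation-depleted circle of 18 km) so the hotspot
stage has a known target. Ground truth records each field's exact expected
yield and whether raising N (or irrigation) to its plateau would raise true
yield by more than noise_sd/2 — the operational definition of "truly
limited". A field's limitation labels, the true attainable yield (top-decile
mean of expected yields), and the latent class are all written alongside the
survey.

What the generator does **not** emulate: measurement error distinct from
process noise (a single noise term covers both), correlation between
management and weather, soil covariates, multi-year dynamics, or the heavy
tails and reporting heaping of real surveys. Passing recovery tests therefore
demonstrates that the machinery identifies constraints *when the generating
assumptions hold*, not that any particular real landscape satisfies them.

## Numerical choices

- Min-max scaling (display only; models see raw values) maps a constant
  column to 0.
- Rows with missing or invalid values are rejected with per-row diagnostics,
  never imputed — the per-field substitution logic requires complete records.
  Duplicate (field_id, year) keys are a table-level error.
- Predictions follow sklearn's float32 casting; the Shapley kernel routes
  inputs through the same cast so threshold comparisons agree bit-for-bit,
  which is what makes the additivity identity hold to ~1e-13 rather than a
  loose tolerance.
- A single pipeline seed fans out to per-stage seeds by fixed offsets, so any
  stage rerun in isolation reproduces its output bitwise; the run manifest
  carries the seed and a configuration hash and no timestamps.

## Problem sizes

Reference runs and the test suite use 5,000-field landscapes with a
200-tree forest and a 128-row attribution background; unit tests use 400–600
fields and smaller forests. At these sizes the full pipeline (generation
through scenarios) completes in well under two minutes on a single core. The
forest default outside the pipeline remains 500 trees; results are
insensitive to the difference well within the across-seed variability.

## Known limitations

- Sequential two-variable decomposition ignores interactions beyond the
  substitution order; on additive surfaces the order changes the combined
  closure by well under 10% (tested), but strongly interacting real systems
  could disagree more.
- ICE grids never extrapolate beyond the observed data range, so a constraint
  whose remedy lies outside the surveyed range cannot be detected.
- Interventional Shapley values with a finite background measure deviation
  from that background's mean prediction; a different background shifts the
  base value and, slightly, the signs of near-zero attributions (hence
  cluster shares carry sampling noise of a point or two).
- The Gi* map classes are raw per-field tests; treat them as descriptive
  zoning, not inference corrected for multiplicity.
- Scenario profits are partial net returns (extra revenue minus extra N and
  irrigation costs only); labour, seed, and risk are out of scope, as are
  water-balance and greenhouse-gas accounting.
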