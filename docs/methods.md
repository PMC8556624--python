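# Methods

This note documents the models, algorithms, defaults and design choices in
`acprev`, and what its synthetic world does and does not establish.

## Estimation model

The estimand is the prevalence of a binary indicator at small electoral
units (ACs). The model is an intercept-only random-effects logistic
regression over the survey's sampling hierarchy — child (1) ⊂ cluster (2) ⊂
district (3) ⊂ state (4):

    logit P(y = 1) = β0 + u_state + v_district + w_cluster,
    u ~ N(0, σ²_u), v ~ N(0, σ²_v), w ~ N(0, σ²_w).

No covariates are used; each indicator is modelled separately. The
cluster-level *precision-weighted* estimate shrinks noisy observed cluster
proportions toward district/state means in proportion to their precision:
clusters with few children borrow more strength. The AC estimate is then the
unweighted arithmetic mean of its member clusters' posterior prevalences
(a child-weighted mean is available but off by default: "mean of
cluster-specific estimates" is taken literally).

### Sampler

The posterior is sampled by Polya-Gamma data augmentation: with
ω_i ~ PG(1, ψ_i) every conditional is Gaussian (effects) or inverse-gamma
(variances), giving an exact Gibbs sampler with no tuning. PG(1, z) variates
are generated with Devroye's alternating-series method (series/exponential
switch at t = 0.64, truncated inverse-Gaussian proposals), jit-compiled with
numba (~150 ns per draw). The kernel additionally performs a *translation
sweep* after each level's update: the likelihood is invariant under
β0 → β0 + c, eff → eff − c, so c has a Gaussian conditional determined by
the priors alone; sampling it removes the strong β0–random-effect-mean
autocorrelation (intercept effective sample size improved ~30× in testing).
This is an ancillarity-sufficiency interweaving move and leaves the target
posterior unchanged.

Unit indices follow first appearance in the data, which makes the sampler
exactly equivariant under relabelling of units (permuting ids permutes
outputs identically).

### Priors and defaults

* β0 ~ N(0, 10⁶) — effectively flat.
* σ² ~ InvGamma(0.001, 0.001) on each variance component — the conventional
  "noninformative" default of multilevel software; configurable. Note the
  known pathology: with few groups (e.g. 8 states) this prior concentrates
  variance posteriors toward 0, which can under-cover the state variance and
  slightly narrow the intercept interval. The parameter-recovery test
  tolerates this (coverage ≥ 8/10 replicates), and users fitting few groups
  should consider a flatter variance prior via `MCMCConfig`.
* Chains: single chain, burn-in 5000, 50 000 monitored iterations, thin 1 —
  the production defaults. All tests and bundled drivers run reduced chains
  (stated per test); diagnostics (split-R̂ on chain halves, ESS via arviz)
  are attached to every fit.
* Cluster prevalence: *transform-then-average* — p̂ = mean over iterations of
  expit(ψ_t) — avoiding the Jensen bias of plugging in the posterior-mean
  linear predictor. A `plugin` mode implements the latter because the exact
  estimator used by the original multilevel software is not documented; at
  the chain lengths used here the two differ by well under a percentage
  point in the synthetic world.

### Five-level sensitivity variant

ACs do not nest in districts, so before adding an AC random intercept each
AC is resolved to exactly one district: the district containing strictly
more than 60 % of the AC's linked clusters, else the district whose polygon
shares the largest overlap area with the AC. The comparison statistic is the
mean (SD) over ACs of |p₄ − p₅| in percentage points, per indicator.

## Geolink

All geometry is planar, in metres. Inputs in geographic coordinates must be
projected first; a closed-form spherical Lambert azimuthal equal-area helper
is provided (adequate at survey extents; no geodesic library is required).

* **Direct ("nonadjustment")**: a point is assigned to the polygon whose
  interior contains it. Boundary points contained by several polygons take
  the lexicographically smallest id (logged); a point in the *interior* of
  two polygons means the layer overlaps and is an error. Invalid polygons
  get the standard zero-width-buffer repair first.
* **Reassignment**: a circular buffer of the displacement radius (2 km
  urban / 5 km rural, U(0, r) distance by default — "up to r") is
  intersected with every polygon; assignment is argmax of
  intersection-area / buffer-area, ties to smallest id with a warning.
  Buffers are discretised with 128 segments per quarter circle; against the
  closed-form circle/half-plane segment area the resulting ratios are
  accurate to ~10⁻⁵, well inside the 10⁻³ verification tolerance. An
  optional constraining polygon (for displacement confined to an admin
  unit) is off by default.
* Drop rules: missing coordinates; point/buffer outside the layer; polygons
  with null or duplicated unit names.

A property worth knowing: on a layer with *straight* borders, the polygon
containing a displaced point almost always also holds the majority of its
buffer, so direct and reassignment linkages agree on nearly every surviving
cluster; reassignment's gain is recovering clusters whose displaced point
fell outside the layer. Discrepancy rates like the few percent seen with
real, irregular constituency borders should not be expected from the
rectangular synthetic world.

## Indicators

Thresholds are strict (`<`): z < −2.0 for the three anthropometric
indicators, hemoglobin < 11.0 g/dL for anemia, which is evaluated only at
ages 6–59 months (not-applicable otherwise). Missing inputs propagate: the
anthropometry sample requires non-missing age, height and weight; the anemia
sample non-missing hemoglobin and age in range; the two samples are built
independently and an exclusion log counts children per first-failing reason.
WHO-style biological-plausibility filtering (|HAZ| > 6 etc.) exists but
defaults **off**, since the emulated analysis does not describe it; the same
holds for hemoglobin altitude/smoking adjustment (not implemented).
Precomputed z-score columns are accepted in place of measures + reference
table.

## Synthetic world

The generator emulates the *structure* the analysis assumes, not any real
geography:

* **Geometry**: states are rectangles tiled by a near-square grid of AC
  cells (default edge 10 km, last row widened to tile exactly); districts
  are vertical strips whose interior boundaries are offset by 0.4 cells so
  ACs generically span two districts — the non-nesting that motivates the
  pipeline. States are separated by a one-cell gap (no cross-state
  adjacency). Clusters are uniform within their AC; the urban flag is
  Bernoulli (default 0.3).
* **Displacement**: distance U(0, r), angle U(0, 2π); r = 2000 m urban,
  5000 m rural. The DHS practice of sending 1 % of rural clusters up to
  10 km is available (`far_fraction`) but off by default, matching the
  displacement rule as described. True coordinates are retained for
  diagnostics.
* **Outcomes**: stunting, underweight and anemia are independent Bernoulli
  draws from per-indicator 4-level specs. Default intercepts are the logits
  of the reported national AC-level medians (35.56 %, 32.82 %, 19.91 %,
  55.74 %); default variances 0.3 / 0.2 / 0.4 (state/district/cluster) are
  the reference simulation values. Measures are back-generated so indicator
  derivation reproduces the simulated flags exactly: z-scores drawn from the
  correct side of −2 (truncated standard normal, |z| ≤ 5.5), inverted
  through the synthetic LMS table; hemoglobin from a truncated
  N(11.6, 1.4²) on the correct side of 11.0.
* **Wasting is derived, not independent**: a single weight value cannot
  carry independent weight-for-age *and* weight-for-height flags, so weight
  is generated from the WAZ tail and the wasting flag is defined by the
  implied WHZ. Its marginal prevalence is therefore emergent (≈ 19 % at the
  defaults). Model-recovery tests use stunting.
* **Missingness** defaults (age 1 %, height 7 %, weight 7 %, hemoglobin
  16 %, independent) reproduce the emulated survey's attrition: ≈ 85.6 % of
  children survive the height/weight screen and ≈ 83 % the hemoglobin
  screen.
* **Within-cluster sample size** is fixed (default 10 ≈ the survey's mean
  children per cluster) because the real distribution is undocumented; it is
  configurable.
* The synthetic LMS table (smooth, plausible L/M/S curves; labelled
  synthetic) is generated deterministically by
  `synthetic.synthetic_lms_table()` and written as CSV by the pipeline;
  official growth-reference tables can be supplied in the same format but
  are never bundled.

A green test on this world establishes that the *algorithms* are correct
(linkage geometry, sampler targeting, aggregation arithmetic, spatial
statistics), not that real-survey estimates are reproduced: the world has no
realistic geography, no survey weights, no spatially structured covariates,
and far fewer units than the real application.

## Spatial summaries

* **Queen contiguity**: w_ij = 1 iff polygons share ≥ 1 boundary point;
  binary symmetric by default (row-standardised available and labelled in
  output, since spatial software defaults differ). Islands are excluded
  from Moran's I with a logged count. Weights export as GAL and edge-list
  CSV.
* **Moran's I** = (n/S0)·Σ w_ij (x_i−x̄)(x_j−x̄) / Σ (x_i−x̄)², E[I] =
  −1/(n−1). Two-tailed p from the analytic randomization (moment) variance
  by default — matching a generic "2-tailed P value" report — with
  normality and ≥ 999-draw permutation nulls available; degenerate graphs
  whose null variance is zero (e.g. fully connected) return p = NaN rather
  than a spurious significance. Which null the emulated analysis used is
  unknown; outputs label the choice.
* **Dispersion**: per-state and pooled median, 25th/75th percentiles, IQR,
  SD (ddof 1; single-AC states report SD as missing). Quantiles use linear
  interpolation, stated in output headers.
* **Deciles**: equal-count classes 1–10 by stable rank; all-equal input
  collapses to class 1 with a warning.

## Numerical and engineering choices

* Determinism: every stochastic component takes an explicit seed; the
  pipeline derives stage seeds from the config seed (stable arithmetic, no
  Python `hash`). CSV floats use `%.10g`; rerunning a config byte-identically
  reproduces all outputs, and each file carries `# seed=` / `# config_hash=`
  header comments.
* Hierarchy validation: each cluster must map to one district, each district
  to one state (and each AC to one district in the 5-level fit); violations
  raise before sampling. All-0/all-1 outcome vectors warn (intercept weakly
  identified) but run.
* Tie-breaks (boundary containment, equal area ratios) go to the smallest
  unit id and are logged — the emulated procedure is silent on ties.
* Polygon interchange is GeoJSON (Shapefile support would require a reader
  not available in the target environment and is out of scope).
* Test-scale chains: acceptance-style checks run 200–4000 monitored
  iterations rather than 50 000; the shrinkage check (criterion-style
  n ∈ {10, 500} comparison) uses 400 + 1600 iterations to stay inside the
  suite's runtime budget. Assertions are unchanged by the scaling.

## Known limitations

* No survey design weights, no covariates, no spatially structured (CAR)
  effects — faithful to the emulated analysis, but a limitation for reuse.
* AC-level uncertainty is not propagated beyond the envelope of member
  clusters' credible intervals; the AC estimate is a point prevalence.
* The InvGamma(ε, ε) variance prior under-covers with very few groups (see
  above).
* The spherical equal-area projection helper is a convenience, not a
  replacement for a projection library, and should not be used across
  continental extents.
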