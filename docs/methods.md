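# Methods

`springhab` implements an ecohydraulic habitat-modelling pipeline for
small spring-fed channels: from co-registered hydraulic and substrate
rasters to logistic habitat-suitability models, habitat maps, and
habitat–discharge response curves. This note records the models and
procedures, the parameters that matter, the numerical choices, and the
limitations — particularly what the synthetic springbrook does and does
not emulate.

## The habitat model

Fish occurrence at a sampled location is modelled as a Bernoulli response
with logit link:

    logit P(presence) = β0 + Σ_k β_k x_k

where the covariates x_k are water depth `DEP` (m), depth-averaged
velocity `VEL` (m/s), Froude number `FRD = V / sqrt(g d)` (dimensionless,
g = 9.81 m/s², not configurable), substrate class `SUB3` (1 fines,
2 gravels, 3 cobble/boulder), and water temperature `TMP` (°C).
Curvilinear selection is captured with squared (and optionally cubed or
log) terms; substrate enters as two dummies coded against the
cobble/boulder reference, so positive dummy coefficients mean "more
likely than on cobble/boulder". A concave quadratic response in a
covariate implies an interior preference optimum at `−β_linear /
(2 β_squared)`; for the packaged reference dace coefficients these optima
are 0.64–0.71 m of depth, 0.14 m/s of velocity and a Froude number of
0.1 — a deep, gently moving pool.

Fitting is by iteratively reweighted least squares with step-halving on
any likelihood decrease, at most 100 iterations, convergence when the
largest score component falls below 1e−8 or the relative log-likelihood
change falls below 1e−10. Standard errors come from the inverse observed
information at the optimum. A zero deviance (perfectly predicted data)
or a coefficient norm above 1e3 is reported as separation — there is no
finite MLE to report. Rank-deficient designs raise an error naming the
dependent columns; near-collinear column pairs from *different*
covariates (|r| > 0.95, e.g. velocity vs Froude) are flagged with a
warning, since within-variable pairs such as `DEP`/`DEP_2` are expected
to be correlated.

Candidate models are compared with AIC (= −2L + 2·NPar, NPar counting
every estimated coefficient including the intercept and each dummy),
Akaike weights, Nagelkerke pseudo-R², the Hosmer–Lemeshow statistic Ĉ
over ten fitted-probability groups (near-equal counts, ties kept in the
lower group, zero-expected groups merged with a warning, p-value from
χ² with g − 2 df), a binary classification table at the 0.3 cutpoint
(presence predicted when p > cutpoint, strictly), and the rank
(Mann–Whitney) AUC with ties contributing ½. Backward elimination drops
one term per step — the deletion with the best AIC — and stops when no
deletion improves AIC; a likelihood-ratio test against the parent model
is logged for every candidate, but AIC decides. Every candidate fitted
along the way is recorded in the comparison table, with Akaike weights
normalised over all recorded models.

## Sampling design

Observed fish locations carry roughly 0.5–1 m of positional error and
cluster into patches. The design therefore operates at the patch level:

* **Patches** are unions of 0.5 m buffers around observation points
  (points within twice the buffer radius merge). The buffer radius of
  the original field polygons is not knowable, so it is an explicit
  configuration parameter. A patch's mean count is the mean of its
  per-survey totals over the surveys in which it was occupied; averaging
  over all surveys could push means below one fish for intermittently
  occupied patches, which would contradict a patch existing at all.
* **Presences**: per patch, the half-up-rounded mean count of uniform
  random points inside the polygon (restricted to wet cells when a scene
  is supplied — buffers overhang the dry margin).
* **Pseudo-absences**: points on wet cells outside every patch, default
  309 against 141 presences, characterising the unused background with
  more absences than presences.
* **Spacing**: all points (presences and absences jointly) keep a
  minimum spacing of 0.12 m — one grid cell — so no cell is sampled
  twice and edge-adjacent duplicates are excluded. Spacing is enforced
  by seeded dart-throwing with rejection, capped at 10,000 consecutive
  rejections before a capacity error that reports the achievable count.
  Simple and reproducible, and entirely adequate at n ≈ 450.

Each point is attributed with the value of its containing cell
(half-open cell intervals; row 0 is northernmost), for `DEP`, `VEL`,
`FRD`, `SUB3` and `TMP`.

## Raster conventions

Grids are planar, cell-centred, 0.12 m resolution by default (cell area
0.0144 m²). Nodata is IEEE NaN in memory and −9999 in ESRI ASCII grids
on disk; I/O is restricted to the ESRI ASCII dialect, which round-trips
values to written precision and grid metadata exactly. The CRS is an
opaque label and is never reprojected. A cell is wet when its depth
exceeds 0.001 m; wetted extent has no standard numeric definition, so
the threshold is explicit and configurable. Channel units are classified
from Froude number as pool (Fr < 0.18), riffle (Fr > 0.41) and glide in
between; the strict inequalities leave the two boundary values
unassigned, and both are given to glide. Froude on effectively dry cells
is nodata, not zero. Unit composition is reported over wet cells.

## The synthetic springbrook

The generator stands in for field bathymetry, a calibrated 2-D
hydrodynamic model, substrate surveys and snorkel observations. Its
defaults describe a ~130 m spring-fed channel at 0.071 cms baseflow and
31 °C with patchy substrate and pool-riffle-glide structure:

| parameter | default | meaning |
|---|---|---|
| `length` | 130 m | channel length |
| `cell_size` | 0.12 m | grid resolution |
| `baseflow_q` | 0.071 cms | reference discharge |
| `width_min`, `width_max` | 1.5, 3.2 m | riffle/pool channel widths |
| `unit_wavelength` | 14 m | pool-riffle spacing |
| `pool_bias` | 1.6 | skew of the width profile (>1 → more narrow stations) |
| `slope_pool`, `slope_riffle` | 5e−6, 1.2e−2 | energy-slope range (log-interpolated on width) |
| `manning_n` | 0.035 | roughness |
| `bank_relief` | 0.35 m | parabolic section height |
| `substrate_mix` | 0.2/0.4/0.4 | fines/gravels/cobble-boulder shares |
| `mean_patch_area` | 1 m² | substrate patch scale |
| `spring_temperature` | 31 °C | near-isothermal spring water |

Hydraulics are solved per cross-section: bisection on the water-surface
stage until the Manning conveyance discharge matches the target Q within
1% (≤100 iterations), then lateral allocation of the discharge in
proportion to cell conveyance d^(5/3), which makes the per-section audit
Σ v·d·Δx = Q exact by construction. Pools in a real channel are
backwaters controlled by the downstream riffle crest rather than
normal-depth reaches; the generator mimics that with a near-flat pool
energy slope (5e−6), which is what produces realistic 0.6–0.7 m pool
depths at 0.071 cms. With these defaults the channel classifies to
roughly 70% pool, 12% glide and 18% riffle — pool-dominated, with all
three units well represented.

Substrate patches are grown by seeded competitive region growing: patch
seeds are allocated to the three classes by largest remainder on the
target mix, and growth always extends the class furthest below its
target share, so empirical shares track the mix to within a few points
while patches stay contiguous. The 7-class codes aggregate as
{1}→fines, {2,3,4}→gravels, {5,6,7}→cobble/boulder; the 3-class layer is
always that aggregation of the 7-class layer. Temperature is constant at
the spring temperature with an optional linear downstream cooling rate
(default 0 — spring-fed brooks near their source are near-isothermal,
which is also why temperature plays a weak role in the models).

Fish are simulated from a known ("true") habitat model — the packaged
reference dace coefficients by default. Patch centres are drawn from wet
cells with probability proportional to the model's per-cell occurrence
probability; each survey allocates the target abundance (141 by
default, at least one fish per patch) and places each fish on a
probability-weighted wet cell within 1 m of its patch centre, jittered
inside the cell. This yields patchy, habitat-selective observations
whose generating model is known exactly, enabling parameter-recovery
tests: refitting on 2000 simulated locations recovers every coefficient
within 3 reported standard errors.

**What the generator does not emulate:** 2-D momentum effects
(recirculation, transverse flow, super-elevation), unsteady flow,
sediment dynamics, thermal physics, observer detection error, and fish
movement between surveys beyond independent re-draws. Tests passing on
synthetic scenes therefore demonstrate that the pipeline's statistics
and bookkeeping are correct and that known generating models are
recoverable — not that any particular field system matches the packaged
reference coefficients.

## Habitat mapping and verification

The fitted model is applied to the covariate layers cell by cell
(identically to how it is applied to sample tables — both paths share
one design-construction routine). Probability maps are thresholded at
the 0.3 cutpoint, strictly: p > 0.3 is habitat, p ≤ 0.3 is not.
Verification counts a fish location as correct when any habitat cell
lies within a Chebyshev distance of 2 cells (~24 cm) of its containing
cell — a square raster buffer consistent with GIS cell-buffer semantics
and with positional error in field locations; measuring to the nearest
predicted-habitat cell (rather than to an occupied-patch polygon) is the
implemented reading of that rule. The density diagnostic bins wet cells
into 20-percentage-point probability classes (half-open intervals, the
first including 0), merges top classes downward while they hold fewer
than 5 cells or less than one expected fish, and fits an ordinary
least-squares line through (class index, fish per cell); a well-fitting
model shows a positive slope. The numeric coefficients of that line are
scene-specific and are always computed, never assumed.

## Flow response

Habitat–discharge curves re-solve the hydraulics at multipliers of
baseflow (default 0.7–1.3 in 0.1 steps), holding geometry, substrate and
temperature fixed, then recompute Froude, probability and the binary map
at the model cutpoint. Standardizations: habitat per linear metre
(area / channel length) and percent change relative to the baseflow row,
which is exactly zero by construction. Both standardizations commute.
On the default template the depth optimum of the reference model
(0.64 m) exceeds the channel's modal depth, so habitat increases with
flow — about −16% at a 30% drawdown and +9% at a 30% ramp-up in the
packaged configuration, numbers the acceptance script recomputes at run
time.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the CLI derives
per-stage seeds from one top-level seed by hashing, and identical
configuration plus seed reproduces byte-identical outputs. The default
problem sizes — a 130 m channel (~17,500 wet cells), 450 sample points,
2000 parameter-recovery locations, 200 calibration-null replicates —
were chosen so the statistical checks have real power while the whole
suite runs in well under a minute of compute per stage.

## Known limitations

* The hydraulic stand-in is 1-D per cross-section; velocities are
  conveyance-shared, not momentum-solved, so eddies and lateral
  recirculation are absent and velocity fields are smoother than a 2-D
  solver would produce.
* Hosmer–Lemeshow grouping conventions differ between statistical
  packages near ties; results can differ in the second decimal from
  other software on tied data.
* The published model-selection table's parameter counts cannot be
  reconciled with its printed per-model term lists (higher-order terms
  are suppressed in the listing); parameter counts here are therefore
  always computed from the explicit term list, and the published table
  is treated as given input where its values are used.
* Detection probability is deliberately out of scope: absences are
  background pseudo-absences, and fitted probabilities are relative
  habitat suitabilities, not occupancy estimates.
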