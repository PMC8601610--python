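# Methods

This note documents the model, the numerical scheme, the parameter
defaults and the design choices behind `hedgescape`, in the spirit of a
package methods appendix. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Landscape model

The spatial support is a T-tessellation of a square extent (default
5.55 km): every interior vertex is a T-junction. The built-in generator
splits rectangles recursively — the rectangle to split is drawn with
probability proportional to its area, the cut is perpendicular to the
longer side at a uniform fraction in [0.3, 0.7] — which yields exactly the
requested polygon count and a mosaic of axis-aligned fields. It is a
synthetic stand-in for a digitised field mosaic; arbitrary polygonal
landscapes load from GeoJSON, and nothing downstream assumes axis
alignment (the mesh builder samples segments geometrically).

Land cover comes from two zero-mean, unit-variance Gaussian random fields
with exponential correlation exp(−d/φ), drawn jointly on the pooled set of
polygon centroids and edge midpoints so that the cross-correlation ϱ
between the hedge field and the crop field is spatially coherent. φ = 0 is
treated as the independence limit; covariance matrices receive a 10⁻¹⁰
diagonal jitter before Cholesky factorisation. Allocation is by count
quantile: the ⌊P·n + ½⌋ elements with the highest field values get the
label, so realised proportions match their targets exactly; ties break by
element index for determinism. (Whether proportions should be interpreted
by count or by area is genuinely open; count is the literal reading and
the default here.)

Descriptors per polygon: area, perimeter, number of adjacent crop fields,
number of boundary hedges. Landscape level: realised proportions,
crop–hedge interface length, and a crop aggregation index (the fraction of
crop–crop pairs among adjacent pairs involving at least one crop polygon).

## Population dynamics

State variables: pest density u (pests·km⁻²) and predator density v on 2D
cells, predator density on 1D hedge nodes (per km). Hedges carry logistic
predator growth (r_v, K_h) and 1D diffusion D1v, continuous across
junctions; fields carry predator mortality m_v plus a numerical response
β·u·v, and pest logistic growth (r_u, C_it) on crop or mortality m_u on
non-crop, with predation loss β·u·v everywhere. Pest crosses every border
freely; the predator crosses hedge-free borders freely but a hedge
interrupts its direct field-to-field diffusion — transfer through a hedge
happens via the migration exchange (per-capita rates ρ₂₁ field→hedge,
ρ₁₂ hedge→field, with ρ₁₂ ≤ ρ₂₁ enforced: the predator is reluctant to
leave its habitat). Landscape boundaries reflect. Carrying capacities are
saturation levels, not literal head counts.

The spray rule is evaluated once per reporting day per crop field: if the
area-weighted mean pest density strictly exceeds the threshold
(0.2 pests·km⁻²) and no application is active there, the field's capacity
C_it drops to K/reduction_factor for the efficacy period, then reverts.
The optimal profile divides by 200 (99.5 % efficacy); a realistic preset
divides by 10/3 (70 %), and low/high threshold presets halve/double the
trigger. The efficacy period is nowhere quantified in the source material;
the default is 10 days and it is configurable. The pesticide is selective:
predators are unaffected.

Pest arrivals: the number of events per season is Poisson with mean
25 × (crop area fraction); each event occurs at a uniform day, in a crop
field drawn proportionally to area, at a uniform point inside it.

### Inoculum calibration

The size and footprint of one arrival are not specified by the source
material and had to be set. Each event deposits a Gaussian patch (peak
`amount`, scale σ = `spatial_spread`), discretized mass-conservatively so
the inoculum per event (amount·2πσ²) is independent of mesh resolution.
The defaults — peak 1.5 pests·km⁻², σ = 0.1 km, i.e. ≈ 0.094 pests per
event — seed a typical 0.5 km² field at ≈ 0.19 pests·km⁻², the order of
the spray threshold. This calibration is deliberate: with a much smaller
inoculum no field can ever reach the threshold within a 100-day season
(growth is bounded by e^{r_u·100} ≤ ×7.4), so the application process
would be degenerate; with a much larger one every inoculated field
triggers instantly and the growth, diffusion and predation signals are
erased. At the default, threshold crossing is decided by the season's
dynamics, which is the regime the model is meant to study.

## Numerical scheme

Cell-centred finite volumes on a uniform grid over the extent; hedges are
discretized into 1D control volumes at matching spacing, with junctions
handled by eliminating the junction value under flux balance (a star of
pairwise conductances — exact for two-way continuations, reflecting at
dead ends). Each polygon's exact intersection area with every cell is
precomputed: field means are area-weighted, and cells straddling a border
blend the crop and non-crop reaction maps by their crop area fraction,
which removes the O(h) land-cover misclassification error.

Time stepping is operator-split within each reporting day (default
internal step 0.1 d):

1. implicit (backward-Euler) diffusion solves for u, v and the hedge
   network, via prefactorised sparse LU — unconditionally stable and
   mass-conservative to solver precision;
2. the hedge–field exchange, explicit and exactly conservative: per hedge
   node of control length ℓ, the hedge gains ρ₂₁·v_trace per unit length
   from each bordering side and loses ρ₁₂·v split over sides, with the
   matching individual counts moved between compartments. v_trace is the
   field density linearly extrapolated to the hedge line from the two
   nearest cells, which removes the leading O(h) strip bias;
3. reactions as exact one-step maps (exponential decay/growth factors and
   the closed-form logistic map), so pure-reaction trajectories are exact
   at any step size and densities stay nonnegative by construction.
   Negative values from solver round-off are clipped and the clipped mass
   is accumulated for inspection.

Daily events: scheduled inoculations deposit at the start of their day;
efficacy timers tick and the spray rule runs at the end of each day.

Convergence: season summaries converge under joint (h, Δt) refinement; the
acceptance suite verifies < 2 % change in the season means between
resolutions 0.1 and 0.05 km (with Δt 0.1 → 0.05 d) on a reference scenario
without spray events. The spray rule is a hard threshold, so scenarios
poised exactly at the trigger can flip an application between resolutions;
production experiments therefore fix one resolution across a design
(coarse-mesh experiments use 0.37 km cells, Δt 0.25 d).

## Parameters

Defaults are the fixed published values, or midpoints of the published
ranges for varied parameters.

| parameter | meaning | default | range |
|---|---|---|---|
| φ | allocation aggregation (km) | 2.8 | 0.0555–5.55 |
| P_c, P_h | crop / hedge proportions | 0.5 | 0–1 |
| ϱ | hedge–crop GRF correlation | 0.5 | fixed |
| D2v | predator 2D diffusion (km²/d) | 0.0063125 | 0.000625–0.012 |
| D1v | predator 1D diffusion (km²/d) | 0.012 | fixed |
| 1/m_v | predator lifespan (d) | 43 | 20–66 |
| β | predating rate (pest⁻¹ d⁻¹) | 0.01 | 0.01–0.10 |
| r_v | predator growth on hedges (d⁻¹) | 0.015 | 0.010–0.020 |
| K_h | hedge carrying capacity | 1 | fixed |
| ρ₂₁ | field→hedge migration (d⁻¹) | 0.05 | fixed |
| ρ₁₂ | hedge→field migration (d⁻¹) | 0.025 | 0–0.05 |
| D2u | pest 2D diffusion (km²/d) | 0.0063125 | 0.000625–0.012 |
| r_u | pest growth on crop (d⁻¹) | 0.015 | 0.010–0.020 |
| K_field | crop capacity for pest | 20 | fixed |
| 1/m_u | pest lifespan on non-crop (d) | 43 | 20–66 |

Notes. The published parameter table prints the β row with two equal
values to its precision; since the analysis layer reports an estimated β
effect, β is treated as varied over [0.01, 0.10]. ρ₂₁ is printed with
inconsistent units (km⁻¹·d⁻¹ vs d⁻¹ for ρ₁₂); both migration rates are
implemented as daily per-capita transfer rates. K_h is a single scalar for
all hedges. Lifespans are sampled on the lifespan scale and inverted to
mortalities.

## Experimental design

Factors are sampled with a scrambled Sobol sequence arranged in Saltelli
radial blocks A, B, AB_i (base sample N, k factors → N(k+2) distinct
configurations). The full published design size, 11,500 configurations,
forces N(k+2) = 11,500 with integer N; the only plausible factor count is
k = 8 (N = 1,150), and the default factor set is φ, P_c, P_h, D2v, ρ₁₂,
D2u, β, r_u — the eight whose effects the analysis reports. With 15
landscape replicates per configuration the full design holds 172,500
simulations. Replicate seeds are shared across configurations (common
random numbers), which reduces the noise of sensitivity contrasts.
Checkpoint/resume stores one JSON per finished run keyed by a parameter
hash.

## Statistical analysis

First-order indices use the Saltelli estimator
S_i = E[y_B(y_{AB_i} − y_A)]/V(y), total indices the Jansen estimator
S_{Ti} = E[(y_A − y_{AB_i})²]/(2V(y)); 95 % confidence intervals come from
a percentile bootstrap (default 1,000 resamples) over the base-sample rows
jointly across blocks. A zero-variance response is an error, and small
negative index estimates are reported as such rather than clipped.

Global GLMs: Gamma with log link for positive channels (zero responses
excluded), binomial for presence/absence; covariates standardized so
coefficient magnitudes are comparable (can be disabled); candidate terms
are main effects plus all pairwise interactions; bidirectional stepwise
BIC selection starts from the main-effects model and respects marginality
(an interaction is eligible only with both parents present, a main effect
removable only when none of its interactions is active). BIC is
−2·logL + k·log n; the Gamma dispersion parameter is common to all
candidate models and cancels in comparisons. Suspected perfect separation
in binomial fits is detected (exploding coefficients or non-finite
standard errors) and flagged on the result.

Local (patch-scale) models use the per-field table with a random intercept
per landscape simulation. Presence/absence: a variational-Bayes binomial
mixed GLM (statsmodels); that fitter has no offset argument, so a supplied
global-model offset enters as an additional fixed covariate. Application
counts: positive counts are fit as a linear mixed model on log counts —
the log-normal approximation to a Gamma log-link, chosen because no Gamma
mixed model is available in the Python stack — with the offset subtracted
from the log response. A singular random-effect fit is reported and is
equivalent to the fixed-effects model. The sign table maps each
coefficient to +, − or NS by whether its 95 % normal CI excludes zero.

## Scaled-down verification experiments

The full 172,500-run design is out of desk-scale reach, so the system
level checks in `tests/test_acceptance.py` run a reduced design chosen as
a package default for verification: 6 factors (P_c, P_h, φ, ρ₁₂, D2u,
r_u), base sample N = 48 → 384 configurations × 2 landscape replicates =
768 simulations on a 60-field landscape at 0.37 km resolution. At this
scale the dominance structure of the sensitivity analysis (crop proportion
for pest density and application counts; predator migration then hedge
proportion for predator density) and the direction of the regression
effects are stable; the index magnitudes carry wide bootstrap intervals,
which is why the checks assert dominance and sign rather than exact
values.

## What the synthetic landscapes do and do not capture

The generator reproduces the T-tessellation character, controllable
composition (P_c, P_h), aggregation (φ) and hedge–crop association (ϱ) of
an agricultural mosaic. It does not reproduce a specific real geometry:
fields are axis-aligned rectangles with near-degenerate area/perimeter
variation compared to digitised landscapes (log area and log perimeter are
almost collinear, which inflates the variance of their separate local
effects), there are exactly two land-cover classes, and hedge placement is
restricted to existing field borders. Passing the sign and dominance
checks therefore says the mechanisms behave correctly on landscapes of
this class, not that effect magnitudes transfer to any particular real
landscape.

## Known limitations

- The hedge–field exchange and the hedge barrier are first-order accurate
  in h at the interface despite the trace extrapolation; predator season
  means move by ≈ 1 % between 0.1 and 0.05 km resolutions.
- The spray threshold makes outputs discontinuous in parameters and
  resolution near the trigger point.
- Only a selective pesticide is modelled; broad-spectrum effects on the
  predator, predator aggregation toward pests, alternative prey, and
  multi-season carry-over are out of scope.
- The binomial mixed model is variational (posterior SDs are
  approximate), and Gamma mixed models are approximated on the log scale.
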