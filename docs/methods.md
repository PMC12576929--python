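# Methods

`movekba` implements a behaviour-aware workflow for identifying key at-sea
areas from central-place-forager GPS tracks, together with a synthetic
track generator that stands in for restricted seabird tracking data.  This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not
demonstrate about real data.

## The movement model

Observed quantities per trip are step lengths `s_t` (planar km between
consecutive fixes at the nominal 100-s duty cycle) and turning angles
`φ_t ∈ (−π, π]` (signed heading change at each interior fix).  A 3-state
hidden Markov model links them to latent behaviours — resting, foraging,
transiting — with

* `s_t | state k ~ Gamma(mean m_k, sd σ_k)` (internally shape
  `(m_k/σ_k)²`, rate `m_k/σ_k²`),
* `φ_t | state k ~ von Mises(μ_k, κ_k)`,
* latent states following a first-order Markov chain with transition
  matrix `Γ` and initial law `δ`.

States are always reported in ascending step-mean order, which makes
"resting < foraging < transiting" an identifiable labelling rather than a
convention of the optimiser.

### Default emission parameters

The generator's defaults are the colony-weighted grand means estimated for
breeding black-legged kittiwakes (*Rissa tridactyla*):

| state      | step mean (km) | step sd (km) | μ (rad) | κ     |
|------------|----------------|--------------|---------|-------|
| resting    | 0.07           | 0.04         | 0.00    | 10.77 |
| foraging   | 0.23           | 0.26         | 0.03    | 0.34  |
| transiting | 0.98           | 0.32         | 0.00    | 9.84  |

The foraging μ of 0.03 rad is retained although it is practically zero.
No transition matrix is published for this system, so the default `Γ` is a
constructed stand-in: `Γ_ij = c·π_j` for `i ≠ j`, `Γ_ii = 1 − c(1 − π_i)`,
with target occupancy `π = (0.23, 0.48, 0.29)` (resting, foraging,
transiting).  This family has `π` as its exact stationary distribution for
any switching rate `c`; the default `c = 0.1` gives mean dwell times of
10–13 fixes (≈ 17–22 min at 100 s), a biologically plausible bout length.
`δ = π`.

### Fitting and decoding

Fitting is direct numerical maximum likelihood (L-BFGS on a working scale:
log for positive parameters, multinomial logit for `Γ` rows and `δ`),
not EM — this simplifies constraint handling and makes multi-start cheap.
Five seeded restarts (first start = user init, others perturbed by
N(0, 0.2²) on the working scale) guard against local optima.  The forward
algorithm is scaled per step and batched across equal-length series.
Viterbi decoding runs in log space; backtracking ties break toward the
lowest state index for reproducibility.  Zero step lengths are
incompatible with a gamma density; a per-state zero-inflation mass is
estimated, but only when zeros actually occur in the data.  Sampling gaps
are not modelled: steps are treated as per-interval observations
regardless of the true gap (an optional linear interpolation utility
exists for sensitivity checks, mirroring the finding that regularising to
100 s changes little).

## Synthetic central-place trips

Free-running mode emits the pure HMM kinematics (used for all
parameter-recovery experiments, because it is exactly the model the
estimator assumes).  Central-place mode wraps the HMM into colony round
trips: a departure fix at the colony, an outbound leg of transiting steps
with headings von-Mises-biased (strength `homing_kappa = 15`) toward a
random away direction, a free-running mid-trip segment, and a homing leg
biased toward the colony that terminates at the colony.  Forced legs are
labelled transiting — consistent with their kinematics — so ground truth
remains meaningful, but because the forced legs are not Markov-generated,
HMM-recovery experiments use free-running mode.  Between trips, 20 min of
at-colony fixes are emitted so the trip-segmentation rules apply.

What the generator does **not** emulate: GPS position error, tag failure
and duty-cycle gaps, environmental covariates (wind, prey fields),
individual heterogeneity in emission parameters, and memory-based site
fidelity.  Passing recovery tests therefore demonstrates correctness of
the estimators under the model's own assumptions, not robustness to
real-data violations of them.

## Trip segmentation

Fixes within the 500-m inner buffer of the colony are stationary colony
fixes and are excluded; a trip closes when the bird stays inside the 1-km
return buffer at least 14 min.  Conventions the source rules leave open,
fixed here: "within a buffer" is the closed condition (distance ≤ radius);
return-duration is the elapsed time between the first and last consecutive
fixes inside the return buffer, a single fix counting as one sampling
interval; colony-buffer fixes count toward return-buffer residence even
though they never enter trip fix lists.  Trips need ≥ 5 at-sea fixes to be
emitted (configurable; guards against jitter excursions).  Data gaps do
not break trips; gaps > 1 h are logged.  Colonies are retained only with
≥ 8 individuals holding complete trips and ≥ 3 tagged individuals in every
represented year.

## Utilisation distributions and isopleths

The UD is an isotropic bivariate Gaussian kernel density with standard
deviation `h` km per axis, evaluated on a regular grid and renormalised to
unit mass.  `h` follows the central-place "mag" convention: the natural
log of the median per-trip maximum distance from the colony, floored at
0.5 km (the log is non-positive for ranges ≤ 1 km), shared across a
colony's individuals.  Numerical choices:

* cell size `h/10`, enlarged if a grid would exceed 2000×2000 cells;
* margin `max(20% of the point span, 4h)` per side — at 3h the ~0.5% of
  kernel mass lost off-grid biases the 95% isopleth area by ≈ 3%, at 4h
  the bias is < 0.1%;
* the p-level isopleth is the smallest *thresholded* cell set holding
  ≥ p of the UD mass: cells are taken in descending density order and all
  cells tied with the threshold density are included (deterministic and
  level-conservative);
* isopleth area is the selected-cell count × cell area (not a smoothed
  contour), so areas add exactly through the population stage.

Per individual, five UDs share one bandwidth and one grid: all fixes, the
three behaviour subsets, and a "sample" control — a uniform random
subsample of all fixes sized to the rarest behaviour, which separates
"behaviour occupies different space" from "behaviour has fewer fixes".
Subsets under 10 fixes are skipped with a log entry.

## Capture proportions and the boundary transform

The capture proportion is `x = area(behaviour ∩ all)/area(behaviour)` at a
common isopleth level, computed as an exact cell-set intersection.  Area
overlap (not UD-mass overlap) is the default because the downstream
regression operates on per-individual core-area polygons; mass overlap is
available via a flag.  Before beta regression, proportions are pulled off
the boundary with `ẋ = (x(N−1) + 0.5)/N`, `N` being the number of records
entering the regression (dataset-level, configurable).

## Representativeness and key areas

For each colony and subset, representativeness is estimated by an
inclusion bootstrap: for `k = 1..N−1`, repeatedly (default 50 iterations,
seeded) sample `k` individuals, pool their locations, build the
level-isopleth, and measure the fraction of held-out individuals'
locations inside it; a Michaelis–Menten curve `a·k/(b+k)` fitted to mean
inclusion vs `k` gives representativeness `100·N/(b+N)` percent, i.e. the
fitted inclusion at the full sample size relative to the asymptote.
Colonies need ≥ 3 individuals to be assessed and ≥ 70% representativeness
to enter population-level estimates; representativeness is computed per
behaviour subset, since dispersed behaviours saturate more slowly.

Key areas aggregate individual isopleths on a common grid (cell size =
median individual cell size; coverage by cell-centre-in-polygon test):
cell value = (fraction of individuals covering the cell) ×
(representativeness/100) × 100%, an estimate of the percentage of the
source population using the cell.  Cells ≥ the 10% population threshold
are dissolved into the key-area polygon.  An empty estimate (area 0) is a
valid outcome, not an error.

## Comparison models

**Capture model.**  Mixed-effects beta regression: `ẋ ~ Beta(μφ, (1−μ)φ)`
with `logit μ = β_subset + u_colony`, `u ~ N(0, σ²)`.  The marginal
likelihood integrates `u` by adaptive Gauss–Hermite quadrature (15 nodes
by default; estimates change < 1e-3 between 9 and 31 nodes), with the
integrand mode found per colony by warm-started damped Newton.  Cell-means
coding is used so each subset's response-scale mean `logit⁻¹(β_s)` is read
directly off the fit; φ is common across subsets.  Reported means are
conditional (random effect at zero).

**Area model.**  Gaussian LMM on `log10(area_km2)` with behaviour fixed
effects (treatment coding, all-behaviour baseline) and a colony random
intercept, fitted by ML profiled over the variance ratio
`λ = σ²_colony/σ²_resid` (Woodbury identities per colony make each profile
evaluation closed-form).  R² follows Nakagawa: marginal
`var_f/(var_f+σ²_c+σ²_e)`, conditional `(var_f+σ²_c)/(same)`.

Both models report Wald 95% intervals from the observed information (no
profile likelihood, no multiple-testing correction — raw intervals are
reported, matching common practice for these models).

## Problem sizes used in the shipped experiments

Parameter recovery uses 50 free-running series of 500 fixes (~25,000
steps); behavioural-proportion recovery uses 100,000 fixes; mixed-model
recovery uses 14 colonies × 40 records; the qualitative corridor
experiment uses 10 individuals with 200 fixes each; pipeline runs use 2
colonies × 8–12 individuals × 2–4 trips.  These sizes give Monte-Carlo
error comfortably inside the stated tolerances while keeping a full run on
one core in minutes.

## Known limitations

* The transition matrix is a constructed stand-in; dwell-time structure in
  real kittiwake data is unknown to this package.
* Projection is spherical Lambert azimuthal equal-area (R = 6371.0088 km);
  ellipsoidal effects (< 0.3% at study ranges) are ignored.
* The representativeness bootstrap is re-derived from its description, not
  ported: the inclusion curve family and iteration counts are explicit
  choices of this package.
* No position-error model, no covariates on transitions, no >3-state or
  continuous-time HMMs.
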