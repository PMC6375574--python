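# Methods

`stmort` estimates and projects cause-specific adult mortality for the four
major non-communicable disease (NCD) groups — cardiovascular diseases,
cancers, diabetes, and asthma & COPD — at a subnational (province) level
from death-registration data, and projects age-standardized rates to a
horizon year (default 2030). Because real registry microdata of this kind
is confidential, the package ships a synthetic death-registration generator
with a complete truth ledger; every stage of the pipeline is validated
against that known truth.

## The estimation pipeline

### Registry preparation

Raw data is a record-level registry `(record_id, year, province, sex,
single-year age, ICD-10 code)`. Preparation runs four steps:

1. **Deduplication.** Re-submitted certificates carry the same record id;
   rows identical in all fields are collapsed. Rows with malformed ages or
   unknown provinces are rejected and logged; a rejection rate above 10 %
   aborts the run. Ages below 25 are outside the study population and are
   dropped with a logged count. Survivors are aggregated into the 13
   five-year bands 25–29 … 80–84, 85+.
2. **Cause grouping.** ICD-10 codes map to the four NCD groups by interval
   (I00–I99, C00–C97, E10–E14, J30–J98); a fixed set of ill-defined
   "garbage" codes (R99, R54, I46, J96, Y34) takes precedence over the
   intervals — cardiac arrest (I46) and respiratory failure (J96) sit
   inside the letter ranges but are not usable underlying causes.
3. **Completeness.** Registration completeness c per province is estimated
   with the Generalized Growth Balance (GGB) method: for open age
   intervals x+ (x = 30 … 70), the balance `entry rate − growth rate =
   k + d/c` is fit by orthogonal (total least squares) regression of
   `b(x+) − r(x+)` on the registered death rate `d(x+)`; completeness is
   1/slope, clipped to (0, 1.25]. The density of persons at exact age x is
   estimated from the three surrounding 5-year bands with a log-quadratic
   correction (geometric mean of the flanking bands times a curvature and
   slope factor); the naive band-below/5 rate overstates the density
   increasingly with age and badly biases the slope. Counts are then
   inflated by 1/c. Completeness is applied uniformly across age within a
   province; no age profile of completeness is modelled.
4. **Garbage redistribution.** Within each (year, province, sex, age band)
   stratum, garbage-coded deaths are allocated to the four causes
   proportionally to the observed cause counts; strata with no cause
   information fall back to the pooled national (year, sex, age)
   distribution, then to an equal split. Stratum totals are conserved
   exactly and the operation is idempotent. Counts are real-valued from
   here on and are treated as precision weights downstream.

Provinces created by administrative splits are reconstructed backwards in
time by dividing the parent's pre-split counts among the children by fixed
shares; census populations are interpolated between census years with the
exponential growth model `P(t) = P(t0) (P(t1)/P(t0))^((t−t0)/(t1−t0))` and
extrapolated beyond the last census with the last intercensal growth rate.

### Covariate trends

Three socioeconomic covariates drive the mortality level: household wealth
index (unitless), mean years of schooling (years), and urbanization
(proportion). Each (province, sex, covariate) series is fit with a natural
cubic spline through the observed years. Beyond the observed span the
series continues linearly, anchored at the spline's boundary value; the
extrapolation slope is the least-squares trend of the five years nearest
the boundary. This is a deliberate departure from using the interpolant's
endpoint derivative, which amplifies end-point observation noise roughly
15-fold over a 15-year horizon and visibly degrades projection coverage.
Projected urbanization is clamped to [0, 1] and schooling floored at 0;
observed values are never modified, and no covariate uncertainty is
propagated (point projections only).

### The three-stage spatio-temporal estimator

Observations are log rates per stratum: `rate = deaths / person-years`,
with a +0.5 continuity correction when deaths < 1, delta-method variance
`1/max(deaths, 0.5)`. Zero-count strata therefore stay finite with
honestly inflated uncertainty.

**Stage 1 — mixed model.** Per (cause, sex):

    log rate ~ age-band intercepts (13) + β·(wealth, schooling, urbanization)
               + province random intercept,  precision-weighted by 1/variance

with priors N(0, 10²) on coefficients and Inverse-Gamma(1, 1) on the
residual scale and the random-effect variance. All full conditionals are
conjugate; the Gibbs sampler runs on precomputed sufficient statistics
(cost per sweep is O(p² + G), independent of n) with defaults 10,000
iterations, 5,000 burn-in, thinning 5. After each sweep the mean of the
random effects is swept into the age intercepts, enforcing the sum-to-zero
parameterization draw by draw. Effective sample sizes below 100 for any
coefficient emit a warning with the full ESS vector. There is no separate
secular time slope: temporal signal enters through the covariate trends,
the residual smoothing, and the GP; a free time slope would double-count
the covariate-driven decline.

**Stage 2 — age-space-time residual smoothing.** Stage-1 residuals are
averaged with separable weights and added back:

    w = w_time · w_age · w_space
    w_time  = (1 − (|Δt| / (max|Δt| + 1))^λ)³        λ = 2.0 (tricube-style)
    w_age   = exp(−ω |Δa|), Δa in band steps           ω = 1.0
    w_space = ζ^g, g = graph distance, 0 beyond g_max  ζ = 0.9, g_max = 2

`max|Δt|` is taken per target year over the observed years, so the weights
are defined for future target years as well: the same machinery carries
the residual surface into the projection period, where recent years
dominate. Empty neighbourhoods yield a zero smoothed residual (logged).

**Stage 3 — Gaussian-process smoothing.** One GP per (province, sex, age
band, cause) time series: prior mean is the stage-2 surface, covariance
`amplitude² · Matern-5/2(length scale 10 years)` (RBF optional), and
heteroskedastic observation noise equal to each point's sampling variance
plus jitter. The amplitude defaults to 1.4826 × MAD of the stage-2
residuals per series (floor 0.01). The posterior over observed *and*
future years is exact (Cholesky); 95 % intervals come from posterior draw
percentiles (default 1,000 draws), and the posterior standard deviation
widens towards the horizon as the data's influence decays.

**Projection uncertainty.** Stage-1 parameter uncertainty is pushed into
the projections: for each posterior draw, the stage-1 coefficient draw
shifts the GP prior mean, and the induced posterior-mean shift is
`δ_all − B δ_obs` where `B` is the GP's linear response operator. At
observed years the shift is annihilated by the data; at 2030 it passes
through almost fully, so projected intervals reflect coefficient
uncertainty in addition to GP variance.

Disabling stages 2–3 reduces the estimator exactly to the mixed-model
prediction (regression-tested).

### Summaries

Age-standardized rates (ASR) use the direct method with the national
both-sex age distribution of the standard year (default 2015) as weights,
applied per posterior draw so intervals are coherent. National and
both-sex aggregates are population-weighted means of rates per draw
(equivalently expected deaths over person-years). Percent change
2015→2030 is computed from unrounded point ASRs and reported to one
decimal, half away from zero. Proportional mortality is each cause's
percent share of expected deaths; shares sum to 100 by construction.

## The synthetic registry

The generator emulates a middle-income country's death-registration
system at desk scale. Defaults are fixed once and are the conditions under
which all validation statements hold:

- 31 provinces on a random connected graph (spanning tree plus extra
  edges), Dirichlet population shares;
- years 2001–2015, two sexes, 13 age bands, 4 cause groups;
- true log rates: `age intercept + cause offset + β·covariates + province
  effect + trend·(year − 2001)` with β = (−0.5, −0.1, 0.3), i.i.d. N(0,
  0.3²) province effects, trend 0 (decline is purely covariate-driven),
  age intercepts rising log-linearly from ln 3·10⁻⁴ to ln 0.12, cause
  offsets 0 / −1.35 / −2.3 / −3.4 (CVD largest, mirroring the observed
  dominance of CVD mortality);
- covariates rise roughly linearly (wealth ≈ +0.08/yr, schooling ≈
  +0.18/yr, urbanization ≈ +0.01/yr) with small i.i.d. noise (sd 0.02 /
  0.05 / 0.005) — survey-derived covariate series are themselves smoothed,
  so small noise is the realistic choice;
- population: cohorts projected forward on single-year ages 25–119 under
  the truth model's own total mortality, with entry cohorts growing at
  1.2 %/yr, scaled so per-stratum person-years fall in roughly the
  10³–10⁵ range. Because the accounting is closed, the emitted censuses
  (1 Jan of the first year and of the year after the last) are
  demographically consistent with the registered deaths — this is what
  makes GGB completeness estimation meaningful end to end. A simpler
  smooth-profile population generator is also provided for tests that do
  not need consistency;
- counts: independent Poisson per stratum with mean person-years × rate;
- corruption: 13.2 % of records garbage-coded (uniform over R99, R54,
  I46, J96, Y34), per-province completeness drawn U(0.75, 0.98) (the
  registry literature gives no duplicate or completeness figures for the
  emulated system; these are free parameters), 2 % duplicates re-submitted
  under the same record id. Corruption never alters a record's year,
  province, sex or age, and the garbage map permits exact reconstruction
  of the clean cause distribution.

What the generator does *not* emulate: realistic population pyramids
(mortality below 25 and non-NCD mortality are absent), cause-specific
covariate effects, migration, age-dependent completeness, near-duplicate
records (only exact re-submissions), and ICD coding error beyond garbage
assignment. Passing tests therefore demonstrate that the machinery
recovers truth under the model's own assumptions plus registry-style
corruption — not that the model is correctly specified for any real
country's registry.

A separate deterministic stable-population construction (Gompertz
mortality, exponential growth, closed-form intercensal deaths on a fine
age grid) serves as the oracle for completeness estimation: thinning its
deaths by a known factor must be recovered by GGB.

## Numerical choices

- GP posterior covariance is factorized with escalating jitter (×10 up to
  8 times) before sampling; failure names the offending series.
- The Gibbs sampler seeds from `random_state`; separate (cause, sex) fits
  offset the seed so chains are independent but reproducible. The full
  pipeline is bit-reproducible given config and seed.
- Redistribution allocates garbage proportionally with exact conservation;
  fractional counts are kept (no stochastic integerization).
- GGB requires ≥ 3 open-age points, positive censuses, and non-degenerate
  death rates; the slope must be positive.
- Problem sizes in the validation suite are scaled to the question: the
  stage-1 recovery check runs the reference scenario in full (31 provinces
  × 15 years × 13 bands, 10,000 MCMC iterations, 10 replicates); the
  projection-coverage check runs 10 replicates of a single cause with a
  shorter chain (2,500 iterations) and 250 posterior draws; pipeline
  round-trip checks use 4–6 provinces. The acceptance script runs the
  default 31-province scenario with the full 10,000-iteration sampler and
  200 posterior draws.

## Known limitations

- Proportional within-stratum redistribution ignores cause-specific
  garbage patterns (e.g. I46 arising predominantly from CVD); with
  cause-dependent garbage coding the redistributed mix would be biased.
- GGB completeness is weakly identified in provinces whose mortality is
  very low (small spread of death rates across open ages); single-province
  errors up to ~0.15 occur at the default scenario while the cross-province
  mean error stays near zero.
- The GP treats series independently; no cross-cause or cross-age
  correlation is modelled, so aggregated intervals are mildly narrow.
- Covariate projections are point trajectories; scenario uncertainty in
  the covariates is not part of the projection intervals.
- Both-sex and national results are aggregates of the per-(cause, sex)
  fits, not a joint model.
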