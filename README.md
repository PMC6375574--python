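# stmort

Subnational estimation and projection of non-communicable-disease (NCD)
mortality from death-registration data.

Health planners need cause-specific mortality trends — and credible
projections — at the province level, but death-registration systems
deliver messy inputs: duplicate certificates, ill-defined ("garbage")
causes of death, under-registration that varies by province, and
administrative boundaries that change mid-series. `stmort` implements the
full chain from raw registry records to age-standardized projections with
uncertainty, for the four major NCD groups (cardiovascular diseases,
cancers, diabetes, asthma & COPD), together with a synthetic
death-registration generator with a complete truth ledger so every stage
can be validated without confidential data.

## The model

Cleaned log mortality rates `y_past` (per year *t*, province *p*, sex,
5-year age band *a* 25–29 … 85+, cause) are fit in three stages, per cause
and sex:

1. **Mixed model (Gibbs-sampled):**
   `y ~ α_a + β·(wealth, schooling, urbanization)_{pt} + u_p + ε`,
   precision-weighted by delta-method variances, `u_p ~ N(0, τ²)` i.i.d.
   province intercepts; conjugate Normal/Inverse-Gamma priors, 10,000 MCMC
   iterations by default.
2. **Age-space-time residual smoothing:** residuals averaged with
   separable weights — tricube in time, `exp(−ω|Δa|)` in age,
   `ζ^(graph distance)` in space — and added back to the stage-1 surface.
3. **Gaussian-process regression:** per (province, sex, age, cause) time
   series, prior mean = stage-2 surface, Matern-5/2 covariance,
   heteroskedastic observation noise; the exact posterior over observed
   *and* future years yields means, draws and 95% uncertainty intervals
   that widen toward the horizon.

Covariates are extended to the horizon (default 2030) with natural cubic
splines and stabilized linear tails; projected rates follow the
covariate-driven mean with stage-1 coefficient uncertainty propagated into
the draws. Direct age standardization (standard population = national
both-sex 2015 age structure) turns the posterior cube into ASR series,
percent changes 2015→2030, and proportional-mortality shares.

Registry preparation implements deduplication, ICD-10 cause grouping
(I00–I99, C00–C97, E10–E14, J30–J98, with classic garbage codes carved
out), proportional garbage redistribution, Generalized Growth Balance
(GGB) completeness estimation and correction, split-province realignment,
and growth-model census interpolation. See `docs/methods.md` for the full
specification of every stage.

## Worked example

Run the whole pipeline on a small synthetic scenario (6 provinces,
2001–2015, registry corrupted with 13.2% garbage coding, drawn
per-province completeness and 2% duplicates), projecting to 2030:

```python
from stmort import RunConfig, run_pipeline

cfg = RunConfig(seed=5)
cfg.scenario.n_provinces = 6
cfg.mcmc.iterations, cfg.mcmc.burnin, cfg.mcmc.thin = 1500, 500, 2
cfg.gpr.n_draws = 150
run = run_pipeline(cfg, "out")
nat = run.state["summary_table"].set_index("province_id").loc["national"]
print(nat[["cvd_asr_2001", "cvd_asr_2015", "cvd_asr_2030",
           "cvd_pct_change"]])
```

which prints (CVD, both sexes, national):

```
cvd_asr_2001      1080.6
cvd_asr_2015       463.0
cvd_asr_2030       185.9
cvd_pct_change     -59.8
```

Reading: the age-standardized CVD mortality rate per 100,000 falls from
≈1081 in 2001 to ≈463 in 2015 (observed, model-smoothed) and is projected
to reach ≈186 by 2030 — a 59.8% decline from 2015 — because the wealth,
schooling and urbanization trends that drive rates in this synthetic world
keep improving. `out/` also contains `asr.csv` (per-province and national
ASR series with 95% intervals, by sex and both sexes),
`proportional_mortality.csv` (cause shares per year), the cleaned death
table, completeness estimates, and a run manifest; rerunning with the same
seed reproduces every file byte for byte.

The same stages are scriptable from the shell:

```bash
stmort run-all --seed 5 --out out/        # or: simulate/prep/covariates/
stmort project --config my.yaml --out out # fit/project/summarize
```

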