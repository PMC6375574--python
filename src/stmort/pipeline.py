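"""Stage orchestration: simulate -> prep -> covariates -> fit/project -> summarize.

Each stage writes its artifacts as CSV into the output directory and
records row counts in a manifest (seed, config hash, per-stage counts).
Stages run in order; a stage whose inputs are neither in memory (from an
earlier stage of the same run) nor on disk raises a dependency error
naming the missing artifact.  The same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import covariates as covmod
from . import io as tio
from . import prep as prepmod
from . import summaries as summod
from .config import RunConfig
from .stgpr import STGPREstimator
from .synthetic import TruthParams, simulate_scenario

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "covariates", "fit", "project", "summarize")
#: run-all order; the standalone fit stage (observed-year estimates only) is
#: subsumed by project, so it is skipped unless requested explicitly
DEFAULT_STAGES = ("simulate", "prep", "covariates", "project", "summarize")


class DependencyError(FileNotFoundError):
    """A required input artifact for a stage is missing."""


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class PipelineRun:
    """Holds config, output directory and in-memory artifacts for one run."""

    def __init__(self, cfg: RunConfig, outdir: str | Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.state: dict[str, object] = {}
        self.manifest: dict = {"seed": cfg.seed, "config_hash": config_hash(cfg),
                               "stages": {}}

    # -- artifact helpers ---------------------------------------------------
    def _need(self, name: str, schema: str) -> pd.DataFrame:
        if name in self.state:
            return self.state[name]  # type: ignore[return-value]
        path = self.outdir / f"{name}.csv"
        if not path.exists():
            raise DependencyError(f"missing required artifact {path.name}; "
                                  f"run the producing stage first")
        df = tio.read_table(path, schema)
        self.state[name] = df
        return df

    def _emit(self, name: str, df: pd.DataFrame, schema: str) -> None:
        self.state[name] = df
        tio.write_table(df, self.outdir / f"{name}.csv", schema)

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> None:
        sc = self.cfg.scenario
        params = TruthParams(garbage_fraction=sc.garbage_fraction,
                             duplicate_fraction=sc.duplicate_fraction,
                             spatial_sd=sc.spatial_sd)
        scen = simulate_scenario(n_provinces=sc.n_provinces,
                                 years=range(sc.first_year, sc.last_year + 1),
                                 params=params, seed=self.cfg.seed)
        self._emit("records", scen.records, "records")
        self._emit("population", scen.population, "population")
        self._emit("censuses", scen.censuses, "censuses")
        self._emit("covariates", scen.covariates, "covariates")
        deaths = scen.deaths.copy()
        deaths["deaths"] = deaths["deaths"].astype(float)
        self._emit("deaths_true", deaths, "deaths")
        self._emit("truth", scen.truth.log_rates, "truth")
        tio.write_table(tio.graph_to_frame(scen.graph),
                        self.outdir / "adjacency.csv", "adjacency")
        self.state["adjacency"] = tio.graph_to_frame(scen.graph)
        self.state["scenario"] = scen

    def stage_prep(self) -> None:
        records = self._need("records", "records")
        try:
            censuses = self._need("censuses", "censuses")
        except DependencyError:
            censuses = None
        splits_path = self.outdir / "splits.csv"
        splits = tio.read_table(splits_path, "splits") if splits_path.exists() else None
        clean, completeness = prepmod.prep_registry(records, censuses, splits)
        self._emit("deaths_clean", clean, "deaths")
        comp = pd.DataFrame(sorted(completeness.items()),
                            columns=["province_id", "completeness"])
        self._emit("completeness", comp, "completeness")

    def stage_covariates(self) -> None:
        cov = self._need("covariates", "covariates")
        out = covmod.project_covariates(cov, horizon_year=self.cfg.horizon_year)
        self._emit("covariates_projected", out, "covariates")

    def _run_engine(self, horizon: int) -> STGPREstimator:
        deaths = self._need("deaths_clean", "deaths")
        population = self._need("population", "population")
        cov = self._need("covariates_projected", "covariates")
        adj = self._need("adjacency", "adjacency")
        graph = tio.frame_to_graph(adj, nodes=sorted(deaths["province_id"].unique()))
        est = STGPREstimator(
            iterations=self.cfg.mcmc.iterations, burnin=self.cfg.mcmc.burnin,
            thin=self.cfg.mcmc.thin,
            lambda_time=self.cfg.smoothing.lambda_time,
            omega_age=self.cfg.smoothing.omega_age,
            zeta_space=self.cfg.smoothing.zeta_space,
            max_graph_distance=self.cfg.smoothing.max_graph_distance,
            kernel=self.cfg.gpr.kernel, length_scale=self.cfg.gpr.length_scale,
            amplitude_rule=self.cfg.gpr.amplitude_rule,
            amplitude=self.cfg.gpr.amplitude, n_draws=self.cfg.gpr.n_draws,
            jitter=self.cfg.gpr.jitter, horizon_year=horizon,
            random_state=self.cfg.seed)
        est.fit(deaths, population, cov, graph)
        return est

    def stage_fit(self) -> None:
        deaths = self._need("deaths_clean", "deaths")
        est = self._run_engine(int(deaths["year"].max()))
        self._emit("estimates_observed", est.cube_.to_frame(), "estimates")

    def stage_project(self) -> None:
        est = self._run_engine(self.cfg.horizon_year)
        self.state["cube"] = est.cube_
        self._emit("estimates", est.cube_.to_frame(), "estimates")
        if self.cfg.io.write_draws:
            cube = est.cube_
            idx = pd.MultiIndex.from_product(
                [cube.years, cube.provinces, cube.sexes, cube.ages, cube.causes],
                names=["year", "province_id", "sex", "age_group", "cause"])
            wide = pd.DataFrame(
                cube.draws.reshape(cube.draws.shape[0], -1).T,
                index=idx,
                columns=[f"draw_{i}" for i in range(cube.draws.shape[0])])
            wide.reset_index().to_parquet(self.outdir / "draws.parquet")

    def stage_summarize(self) -> None:
        if "cube" not in self.state:
            raise DependencyError(
                "missing in-memory estimate draws (draws are produced by the "
                "project stage; run project and summarize in the same invocation)")
        cube = self.state["cube"]
        censuses = self._need("censuses", "censuses")
        years_all = cube.years
        pop_full = prepmod.interpolate_population(censuses, years_all)
        std = summod.standard_population(pop_full, self.cfg.standard_year)
        tio.write_table(std.rename("weight").reset_index(),
                        self.outdir / "standard_population.csv",
                        "standard_population")

        both = summod.aggregate_strata(cube, pop_full, "province", "both")
        nat = summod.aggregate_strata(cube, pop_full, "national", "both")
        asr_prov = summod.age_standardize(both, std)
        asr_nat = summod.age_standardize(nat, std)
        asr_bysex = summod.age_standardize(cube, std)
        asr_nat_bysex = summod.age_standardize(
            summod.aggregate_strata(cube, pop_full, "national", "by-sex"), std)
        asr = pd.concat([asr_prov, asr_nat, asr_bysex, asr_nat_bysex],
                        ignore_index=True)
        asr["sex"] = asr["sex"].astype(str)
        self._emit("asr", asr, "asr")

        table_years = (years_all[0],
                       min(self.cfg.scenario.last_year, years_all[-1]),
                       years_all[-1])
        both_sex = asr[asr["sex"] == "both"]
        summary = summod.make_summary_table(both_sex, table_years)
        summary.to_csv(self.outdir / "summary_table.csv", index=False)
        self.state["summary_table"] = summary

        pm = summod.proportional_mortality_from_cube(
            nat, pop_full, years=[table_years[0], table_years[1], table_years[2]])
        self._emit("proportional_mortality", pm, "proportional_mortality")

    # -----------------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        todo = list(stages) if stages else list(DEFAULT_STAGES)
        unknown = [s for s in todo if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage {unknown[0]}")
        for stage in STAGES:
            if stage not in todo:
                continue
            t0 = time.time()
            getattr(self, f"stage_{stage}")()
            dt = time.time() - t0
            counts = {k: len(v) for k, v in self.state.items()
                      if isinstance(v, pd.DataFrame)}
            self.manifest["stages"][stage] = {"seconds": round(dt, 2),
                                              "rows": counts}
            logger.info("stage %s finished in %.1fs", stage, dt)
        (self.outdir / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 stages: list[str] | None = None) -> PipelineRun:
    """Execute the requested stages (default: run-all) and return the run."""
    run = PipelineRun(cfg, outdir)
    run.run(stages)
    return run
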