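"""Synthetic multi-province death-registration system with known truth.

Emulates the structure of a national vital-registration analysis at desk
scale: provinces on a connected adjacency graph, smooth socioeconomic
covariates, log-linear covariate-driven cause-specific mortality with
province random effects, Poisson death counts, and a corruption step that
garbage-codes, under-registers and duplicates records.  Every stochastic
quantity is recorded in a :class:`TruthLedger` so downstream cleaning and
modelling stages can be validated against known truth.

The default scenario is fixed once: 31 provinces, years 2001-2015, two
sexes, four NCD cause groups, per-stratum populations in the 10^3-10^5
range, 13.2 % garbage coding, province completeness drawn uniformly from
[0.75, 0.98] and a 2 % duplicate rate.  Temporal decline in rates enters
purely through the covariate trends (no separate secular slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .ages import AGE_GROUPS, AGE_STARTS, N_AGE_GROUPS, SEXES
from .causes import CAUSES, GARBAGE_CODES

COVARIATES: tuple[str, ...] = ("wealth_index", "years_schooling", "urbanization")

#: Plausible underlying-cause codes per category, used when exploding counts
#: to records.  All lie inside their category's ICD-10 interval and none is a
#: garbage code.
CAUSE_CODE_POOL: dict[str, tuple[str, ...]] = {
    "cvd": ("I21", "I25", "I50", "I61", "I63"),
    "cancers": ("C16", "C22", "C34", "C50", "C61"),
    "diabetes": ("E10", "E11", "E14"),
    "asthma_copd": ("J43", "J44", "J45", "J47"),
}


class MissingStratumError(KeyError):
    """A required (year, province, sex, ...) stratum is absent from an input."""


@dataclass(frozen=True)
class ProvinceSet:
    """Provinces with national population shares.

    ids are unique short keys; shares are positive and sum to one.
    """

    ids: tuple[str, ...]
    names: tuple[str, ...]
    shares: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("province ids must be unique")
        shares = np.asarray(self.shares, dtype=float)
        if np.any(shares <= 0):
            raise ValueError("population shares must be positive")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("population shares must sum to 1")
        object.__setattr__(self, "shares", shares)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TruthParams:
    """Parameters of the data-generating truth model.

    log rate = age_intercept + cause_offset + beta . covariates
               + province_effect + trend * (year - first_year)

    beta is ordered (wealth_index, years_schooling, urbanization).
    completeness may be a scalar, a per-province mapping, or None to draw
    per-province values uniformly from [0.75, 0.98] during corruption.
    """

    beta: tuple[float, float, float] = (-0.5, -0.1, 0.3)
    age_intercepts: np.ndarray = field(
        default_factory=lambda: np.linspace(np.log(3e-4), np.log(0.12), N_AGE_GROUPS)
    )
    cause_offsets: dict[str, float] = field(default_factory=lambda: {
        "cvd": 0.0, "cancers": -1.35, "asthma_copd": -2.3, "diabetes": -3.4,
    })
    spatial_sd: float = 0.3
    trend: float = 0.0
    garbage_fraction: float = 0.132
    completeness: float | dict[str, float] | None = None
    duplicate_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.age_intercepts = np.asarray(self.age_intercepts, dtype=float)
        if self.age_intercepts.shape != (N_AGE_GROUPS,):
            raise ValueError(f"age_intercepts must have {N_AGE_GROUPS} entries")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be >= 0")
        for name in ("garbage_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if isinstance(self.completeness, (int, float)):
            if not 0 < self.completeness <= 1:
                raise ValueError("completeness must be in (0, 1]")
        elif isinstance(self.completeness, dict):
            for p, c in self.completeness.items():
                if not 0 < c <= 1:
                    raise ValueError(f"completeness[{p}] must be in (0, 1]")


@dataclass
class TruthLedger:
    """Everything the generator knows that the pipeline must recover.

    log_rates has one row per (year, province_id, sex, age_group, cause) with
    the true log mortality rate; completeness maps province -> registration
    probability; garbage_map records each garbage-coded record's true cause.
    """

    log_rates: pd.DataFrame
    province_effects: dict[str, float]
    completeness: dict[str, float] = field(default_factory=dict)
    garbage_map: pd.DataFrame | None = None

    def true_rate_lookup(self) -> pd.Series:
        return self.log_rates.set_index(
            ["year", "province_id", "sex", "age_group", "cause"]
        )["log_rate"]


def make_geography(n_provinces: int, seed: int) -> tuple[ProvinceSet, nx.Graph]:
    """Random connected province geography: spanning tree plus extra edges.

    Deterministic for a fixed seed.  Population shares are Dirichlet-drawn
    so provinces differ in size without any being negligible.
    """
    if n_provinces < 1:
        raise ValueError("n_provinces must be >= 1")
    rng = np.random.default_rng(seed)
    ids = tuple(f"P{i + 1:02d}" for i in range(n_provinces))
    names = tuple(f"Province {i + 1}" for i in range(n_provinces))
    shares = rng.dirichlet(np.full(n_provinces, 12.0))
    shares = shares / shares.sum()
    provinces = ProvinceSet(ids=ids, names=names, shares=shares)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    # random spanning tree: attach each node to a random earlier node
    order = rng.permutation(n_provinces)
    for k in range(1, n_provinces):
        j = order[k]
        i = order[rng.integers(0, k)]
        graph.add_edge(ids[i], ids[j])
    # extra edges for cycles (~n/2 attempts)
    for _ in range(n_provinces // 2):
        i, j = rng.integers(0, n_provinces, size=2)
        if i != j:
            graph.add_edge(ids[i], ids[j])
    return provinces, graph


def simulate_covariates(
    provinces: ProvinceSet,
    years: range | list[int],
    seed: int,
    noise_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Smooth province-sex covariate series: monotone trend plus small noise.

    Wealth index (unitless, rising), years of schooling (years, rising, lower
    for women at baseline), urbanization (proportion in [0,1], rising).
    Setting all noise sds to zero yields exactly linear series.
    """
    years = list(years)
    if not years:
        raise ValueError("year range must be non-empty")
    if noise_sd is None:
        noise_sd = {"wealth_index": 0.02, "years_schooling": 0.05, "urbanization": 0.005}
    rng = np.random.default_rng(seed)
    t = np.array(years, dtype=float) - years[0]
    rows = []
    for p, pid in enumerate(provinces.ids):
        start = {
            "wealth_index": rng.normal(0.0, 0.25),
            "years_schooling": max(rng.normal(6.5, 0.8), 0.5),
            "urbanization": float(np.clip(rng.normal(0.55, 0.08), 0.05, 0.95)),
        }
        slope = {
            "wealth_index": rng.normal(0.08, 0.02),
            "years_schooling": rng.normal(0.18, 0.04),
            "urbanization": rng.normal(0.010, 0.003),
        }
        for sex in SEXES:
            sex_off = {"wealth_index": 0.0,
                       "years_schooling": -0.4 if sex == "female" else 0.0,
                       "urbanization": 0.0}
            vals = {}
            for cov in COVARIATES:
                series = start[cov] + sex_off[cov] + slope[cov] * t
                if noise_sd[cov] > 0:
                    series = series + rng.normal(0.0, noise_sd[cov], size=len(t))
                vals[cov] = series
            vals["years_schooling"] = np.maximum(vals["years_schooling"], 0.0)
            vals["urbanization"] = np.clip(vals["urbanization"], 0.0, 1.0)
            for k, year in enumerate(years):
                rows.append({
                    "year": year, "province_id": pid, "sex": sex,
                    **{cov: vals[cov][k] for cov in COVARIATES},
                })
    return pd.DataFrame(rows)


def simulate_true_rates(
    params: TruthParams,
    covariates: pd.DataFrame,
    provinces: ProvinceSet,
    years: range | list[int],
    seed: int,
) -> TruthLedger:
    """True log rates per stratum from the covariate-driven mixed model."""
    years = list(years)
    rng = np.random.default_rng(seed)
    effects = rng.normal(0.0, params.spatial_sd, size=len(provinces))
    province_effects = dict(zip(provinces.ids, effects.tolist()))

    cov = covariates.set_index(["year", "province_id", "sex"]).sort_index()
    grid = pd.MultiIndex.from_product(
        [years, provinces.ids, SEXES], names=["year", "province_id", "sex"]
    )
    missing = grid.difference(cov.index)
    if len(missing) > 0:
        raise MissingStratumError(
            f"covariates missing for stratum {tuple(missing[0])}"
        )
    base = cov.loc[grid, list(COVARIATES)].reset_index()
    beta = np.asarray(params.beta, dtype=float)
    base["lin"] = base[list(COVARIATES)].to_numpy() @ beta
    base["lin"] += base["province_id"].map(province_effects)
    base["lin"] += params.trend * (base["year"] - years[0])

    frames = []
    for a, age in enumerate(AGE_GROUPS):
        for cause in CAUSES:
            f = base[["year", "province_id", "sex"]].copy()
            f["age_group"] = age
            f["cause"] = cause
            f["log_rate"] = (
                base["lin"].to_numpy()
                + params.age_intercepts[a]
                + params.cause_offsets[cause]
            )
            frames.append(f)
    log_rates = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(log_rates["log_rate"])):
        raise ValueError("non-finite true log rates")
    return TruthLedger(log_rates=log_rates, province_effects=province_effects)


def simulate_population(
    provinces: ProvinceSet,
    years: range | list[int],
    seed: int,
    growth: float = 0.012,
) -> pd.DataFrame:
    """Mid-year person-years per (year, province, sex, age band).

    National age profile declines geometrically from 9e5 (25-29) to 9e4
    (85+); provinces scale by their population share with a small fixed
    age-structure jitter; steady exponential growth over time.
    """
    years = list(years)
    rng = np.random.default_rng(seed)
    profile = 9e5 * (0.1 ** (np.arange(N_AGE_GROUPS) / (N_AGE_GROUPS - 1)))
    rows = []
    for p, pid in enumerate(provinces.ids):
        jitter = np.exp(rng.normal(0.0, 0.05, size=(2, N_AGE_GROUPS)))
        for s, sex in enumerate(SEXES):
            sex_factor = 1.0 if sex == "male" else 0.98
            base = profile * provinces.shares[p] * sex_factor * jitter[s]
            for year in years:
                g = (1.0 + growth) ** (year - years[0])
                for a, age in enumerate(AGE_GROUPS):
                    rows.append({
                        "year": year, "province_id": pid, "sex": sex,
                        "age_group": age, "population": base[a] * g,
                    })
    return pd.DataFrame(rows)


def simulate_cohort_population(
    truth: TruthLedger,
    provinces: ProvinceSet,
    years: range | list[int],
    entry_base: float = 1.0e5,
    entry_growth: float = 0.012,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demographically consistent population: cohorts thinned by true mortality.

    Each province-sex population is projected on single-year ages 25-119 with
    annual entry cohorts growing at ``entry_growth``; attrition is exactly the
    truth model's total (all-cause = four-cause) mortality.  Returns
    (mid-year person-years by band per year, census populations by band at
    1 January of the first year and of the year after the last).  Because
    the accounting is closed, death-distribution completeness methods hold on
    this population by construction.
    """
    years = list(years)
    ages = np.arange(25, 120)
    band_idx = np.searchsorted(np.array(AGE_STARTS), np.minimum(ages, 85), side="right") - 1

    # total (all-cause) hazard per band, as [year][band] arrays per province-sex
    tot = (
        truth.log_rates.assign(rate=lambda d: np.exp(d["log_rate"]))
        .groupby(["province_id", "sex", "year", "age_group"])["rate"].sum()
    )
    hazard: dict[tuple[str, str], np.ndarray] = {}
    for (pid, sex), sub in tot.groupby(level=["province_id", "sex"]):
        mat = sub.droplevel(["province_id", "sex"]).unstack("age_group")
        hazard[(pid, sex)] = mat.loc[years, list(AGE_GROUPS)].to_numpy()

    pop_rows: list[dict] = []
    cen_rows: list[dict] = []
    for p, pid in enumerate(provinces.ids):
        for sex in SEXES:
            entry = entry_base * provinces.shares[p] * (1.0 if sex == "male" else 0.98)
            haz = hazard[(pid, sex)]
            mu0 = haz[0][band_idx]
            cum = np.concatenate([[0.0], np.cumsum(mu0[:-1])])
            n = entry * np.exp(-entry_growth * (ages - 25)) * np.exp(-cum)
            states = {years[0]: n}
            for k, t in enumerate(years):
                mu = haz[k][band_idx]
                nxt = np.zeros_like(n)
                nxt[1:] = n[:-1] * np.exp(-mu[:-1])
                nxt[0] = entry * np.exp(entry_growth * (t + 1 - years[0]))
                states[t + 1] = nxt
                n = nxt
            for cy in (years[0], years[-1] + 1):
                agg = np.bincount(band_idx, weights=states[cy], minlength=N_AGE_GROUPS)
                for a, age in enumerate(AGE_GROUPS):
                    cen_rows.append({"census_year": cy, "province_id": pid, "sex": sex,
                                     "age_group": age, "population": agg[a]})
            for t in years:
                py = 0.5 * (states[t] + states[t + 1])
                agg = np.bincount(band_idx, weights=py, minlength=N_AGE_GROUPS)
                for a, age in enumerate(AGE_GROUPS):
                    pop_rows.append({"year": t, "province_id": pid, "sex": sex,
                                     "age_group": age, "population": agg[a]})
    return pd.DataFrame(pop_rows), pd.DataFrame(cen_rows)


def simulate_deaths(
    truth: TruthLedger, population: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Poisson death counts per stratum: counts ~ Poisson(population * rate)."""
    pop = population.set_index(["year", "province_id", "sex", "age_group"])["population"]
    if np.any(pop.to_numpy() <= 0):
        raise ValueError("population must be strictly positive")
    df = truth.log_rates.copy()
    key = pd.MultiIndex.from_frame(df[["year", "province_id", "sex", "age_group"]])
    missing = key.difference(pop.index)
    if len(missing) > 0:
        raise MissingStratumError(f"population missing for stratum {tuple(missing[0])}")
    py = pop.loc[key].to_numpy()
    lam = py * np.exp(df["log_rate"].to_numpy())
    rng = np.random.default_rng(seed)
    df["deaths"] = rng.poisson(lam)
    return df[["year", "province_id", "sex", "age_group", "cause", "deaths"]]


def corrupt_registry(
    deaths: pd.DataFrame,
    params: TruthParams,
    seed: int,
    truth: TruthLedger | None = None,
) -> tuple[pd.DataFrame, TruthLedger | None]:
    """Explode counts to records and corrupt them.

    Steps, in order: assign a single-year age within the band and a plausible
    ICD-10 code; garbage-code a ``garbage_fraction`` of records (true cause
    recorded in the garbage map); drop each record with probability
    1 - completeness of its province; duplicate a ``duplicate_fraction`` of
    survivors (the duplicate is a re-submission carrying the same record_id).
    Corruption never alters a record's year, province, sex or age.
    """
    rng = np.random.default_rng(seed)
    d = deaths[deaths["deaths"] > 0]
    counts = d["deaths"].to_numpy().astype(int)
    idx = np.repeat(d.index.to_numpy(), counts)
    rec = d.loc[idx, ["year", "province_id", "sex", "age_group", "cause"]].reset_index(drop=True)
    n = len(rec)
    rec.insert(0, "record_id", [f"R{i:08d}" for i in range(n)])

    starts = rec["age_group"].map({g: s for g, s in zip(AGE_GROUPS, AGE_STARTS)}).to_numpy()
    widths = np.where(rec["age_group"].to_numpy() == "85+", 15, 5)
    rec["age"] = starts + rng.integers(0, widths)

    # plausible true-cause codes
    icd = np.empty(n, dtype=object)
    for cause, pool in CAUSE_CODE_POOL.items():
        mask = (rec["cause"] == cause).to_numpy()
        icd[mask] = rng.choice(pool, size=int(mask.sum()))
    # garbage coding
    is_garbage = rng.random(n) < params.garbage_fraction
    icd[is_garbage] = rng.choice(GARBAGE_CODES, size=int(is_garbage.sum()))
    rec["icd10"] = icd
    garbage_map = rec.loc[is_garbage, ["record_id", "year", "province_id", "sex",
                                       "age_group", "cause"]].rename(
        columns={"cause": "true_cause"}).reset_index(drop=True)

    # per-province completeness
    provinces = sorted(deaths["province_id"].unique())
    if params.completeness is None:
        completeness = {p: float(rng.uniform(0.75, 0.98)) for p in provinces}
    elif isinstance(params.completeness, dict):
        completeness = {p: float(params.completeness[p]) for p in provinces}
    else:
        completeness = {p: float(params.completeness) for p in provinces}
    keep_prob = rec["province_id"].map(completeness).to_numpy()
    kept = rng.random(n) < keep_prob
    rec = rec[kept].reset_index(drop=True)

    # duplicates: re-submitted certificates, same record_id
    dup = rng.random(len(rec)) < params.duplicate_fraction
    rec = pd.concat([rec, rec[dup]], ignore_index=True)
    rec = rec[["record_id", "year", "province_id", "sex", "age", "icd10"]]

    if truth is not None:
        truth = replace(truth, completeness=completeness, garbage_map=garbage_map)
    return rec, truth


@dataclass
class Scenario:
    """A complete simulated study: geography, inputs, truth, corrupted registry."""

    provinces: ProvinceSet
    graph: nx.Graph
    params: TruthParams
    years: list[int]
    covariates: pd.DataFrame
    population: pd.DataFrame
    censuses: pd.DataFrame
    truth: TruthLedger
    deaths: pd.DataFrame
    records: pd.DataFrame


def simulate_scenario(
    n_provinces: int = 31,
    years: range | list[int] = range(2001, 2016),
    params: TruthParams | None = None,
    seed: int = 0,
    corrupt: bool = True,
) -> Scenario:
    """Run the full generator with sub-seeds split from ``seed``.

    The population is the demographically consistent cohort projection, so
    the emitted censuses support completeness estimation downstream.
    """
    years = list(years)
    if params is None:
        params = TruthParams()
    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    provinces, graph = make_geography(n_provinces, sub[0])
    covariates = simulate_covariates(provinces, years, sub[1])
    truth = simulate_true_rates(params, covariates, provinces, years, sub[2])
    population, censuses = simulate_cohort_population(truth, provinces, years)
    deaths = simulate_deaths(truth, population, sub[3])
    if corrupt:
        records, truth = corrupt_registry(deaths, params, sub[4], truth)
    else:
        records = pd.DataFrame(
            columns=["record_id", "year", "province_id", "sex", "age", "icd10"])
        truth.completeness = {p: 1.0 for p in provinces.ids}
    return Scenario(provinces, graph, params, years, covariates, population,
                    censuses, truth, deaths, records)


def make_stable_population(
    completeness: float = 1.0,
    growth: float = 0.02,
    span: float = 10.0,
    da: float = 0.1,
) -> tuple[pd.Series, pd.Series, pd.Series, float, float]:
    """Deterministic stable-population construction for completeness methods.

    A population with Gompertz mortality growing exponentially at ``growth``
    per year is evaluated on a fine age grid; intercensal deaths are computed
    in closed form (density N(a) mu(a) (e^{rT}-1)/r) and then thinned by
    ``completeness``.  Returns (census1, census2, registered_deaths, t1, t2),
    each Series indexed by 5-year band start ages 0,5,...,85 with 85 open.
    """
    ages = np.arange(0.0, 110.0, da)
    mu = 3e-4 * np.exp(0.085 * ages) + 5e-4
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (mu[1:] + mu[:-1]) * da)])
    survival = np.exp(-cum)
    n1 = 1e5 * np.exp(-growth * ages) * survival
    n2 = n1 * np.exp(growth * span)
    if growth != 0:
        deaths_density = n1 * mu * (np.exp(growth * span) - 1.0) / growth
    else:
        deaths_density = n1 * mu * span

    band_starts = list(range(0, 90, 5))
    def aggregate(density: np.ndarray) -> pd.Series:
        out = {}
        for s in band_starts:
            lo = s
            hi = s + 5 if s < 85 else 110
            mask = (ages >= lo) & (ages < hi)
            out[s] = float(np.trapezoid(density[mask], dx=da))
        return pd.Series(out)

    census1 = aggregate(n1)
    census2 = aggregate(n2)
    deaths = aggregate(deaths_density) * completeness
    return census1, census2, deaths, 0.0, span
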