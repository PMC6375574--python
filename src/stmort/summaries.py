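"""Reported quantities: age-standardized rates, percent change, shares.

Age standardization is direct: ASR = sum_a w_a r_a with the standard
population's age weights, applied draw by draw so the 95% intervals are
coherent with the point estimates.  Aggregation to national or both-sex
levels is a population-weighted mean of rates per draw (equivalently,
expected deaths over person-years).  Percent change is reported to one
decimal, half away from zero, matching conventional table display.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS
from .stgpr import EstimateCube


def standard_population(population: pd.DataFrame, year: int = 2015) -> pd.Series:
    """National both-sex age distribution of ``year`` as standard weights."""
    sub = population[population["year"] == year]
    if sub.empty:
        raise ValueError(f"no population rows for standard year {year}")
    w = sub.groupby("age_group")["population"].sum()
    w = w.reindex(list(AGE_GROUPS))
    if w.isna().any():
        raise ValueError(f"standard population missing band {w.index[w.isna()][0]}")
    return w / w.sum()


def check_standard_weights(weights: pd.Series) -> np.ndarray:
    w = weights.reindex(list(AGE_GROUPS))
    if w.isna().any():
        raise ValueError(f"missing age band {w.index[w.isna()][0]} in standard weights")
    arr = w.to_numpy(dtype=float)
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("standard weights must be >= 0 and sum to 1")
    return arr


def asr_from_rates(rates: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Direct standardization along the trailing age axis."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.shape[-1] != weights.size:
        raise ValueError("rates and weights disagree on the number of age bands")
    return rates @ weights


def _population_array(population: pd.DataFrame, cube: EstimateCube) -> np.ndarray:
    """Person-years on the cube's (year, province, sex, age) axes.

    Aggregated cubes use the labels "national" / "both"; the corresponding
    person-years are summed over provinces / sexes.
    """
    pop = population.copy()
    if cube.provinces == ["national"]:
        pop["province_id"] = "national"
    if cube.sexes == ["both"]:
        pop["sex"] = "both"
    agg = pop.groupby(["year", "province_id", "sex", "age_group"])["population"].sum()
    idx = pd.MultiIndex.from_product(
        [cube.years, cube.provinces, cube.sexes, cube.ages])
    missing = idx.difference(agg.index)
    if len(missing) > 0:
        raise KeyError(f"population missing for stratum {tuple(missing[0])}")
    return agg.loc[idx].to_numpy().reshape(
        len(cube.years), len(cube.provinces), len(cube.sexes), len(cube.ages))


def aggregate_strata(cube: EstimateCube, population: pd.DataFrame,
                     level: str = "national", sex_mode: str = "by-sex"
                     ) -> EstimateCube:
    """Population-weighted aggregation of the cube's rate draws.

    ``level``: "province" (unchanged) or "national"; ``sex_mode``: "by-sex"
    or "both".  Rates are averaged with person-year weights per draw, which
    equals summing expected deaths and dividing by summed person-years.
    """
    if level not in ("province", "national"):
        raise ValueError(f"unknown level {level!r}")
    if sex_mode not in ("by-sex", "both"):
        raise ValueError(f"unknown sex_mode {sex_mode!r}")
    if level == "province" and sex_mode == "by-sex":
        return cube
    w = _population_array(population, cube)  # (Y,P,S,A)
    axes = []
    if level == "national":
        axes.append(2)   # province axis of (D,Y,P,S,A,C)
    if sex_mode == "both":
        axes.append(3)
    axes_t = tuple(axes)
    wf = w[None, ..., None]  # (1,Y,P,S,A,1)
    den = w[..., None].sum(axis=tuple(a - 1 for a in axes_t), keepdims=True)

    num_mean = (np.exp(cube.log_mean) * w[..., None]).sum(
        axis=tuple(a - 1 for a in axes_t), keepdims=True)
    log_mean = np.log(num_mean / den)

    D = cube.draws.shape[0]
    out_shape = list(cube.draws.shape)
    for a in axes_t:
        out_shape[a] = 1
    draws = np.empty(out_shape, dtype=np.float32)
    step = max(1, 50_000_000 // max(cube.draws[0].size, 1))
    for s in range(0, D, step):
        r = np.exp(cube.draws[s:s + step].astype(np.float64))
        draws[s:s + step] = np.log(
            (r * wf).sum(axis=axes_t, keepdims=True) / den)

    provinces = ["national"] if level == "national" else cube.provinces
    sexes = ["both"] if sex_mode == "both" else cube.sexes
    return dc_replace(cube, provinces=provinces, sexes=sexes,
                      log_mean=log_mean.reshape([len(cube.years), len(provinces),
                                                 len(sexes), len(cube.ages),
                                                 len(cube.causes)]),
                      draws=draws.reshape([D, len(cube.years), len(provinces),
                                           len(sexes), len(cube.ages),
                                           len(cube.causes)]))


def age_standardize(cube: EstimateCube, standard: pd.Series,
                    per: float = 1e5) -> pd.DataFrame:
    """ASR per ``per`` person-years with draw-percentile intervals.

    One row per (year, province, sex, cause); asr is the posterior mean of
    the per-draw ASRs, so lo <= asr <= hi by construction of the draws.
    """
    w = check_standard_weights(standard)
    # (D,Y,P,S,C): standardize over the age axis per draw
    draws_asr = np.einsum("dypsac,a->dypsc",
                          np.exp(cube.draws.astype(np.float64)), w) * per
    asr = draws_asr.mean(axis=0)
    lo, hi = np.percentile(draws_asr, [2.5, 97.5], axis=0)
    idx = pd.MultiIndex.from_product(
        [cube.years, cube.provinces, cube.sexes, cube.causes],
        names=["year", "province_id", "sex", "cause"])
    return pd.DataFrame({"asr": asr.ravel(), "lo": lo.ravel(), "hi": hi.ravel()},
                        index=idx).reset_index()


def percent_change(asr_start: float, asr_end: float) -> float:
    """Percent change, one decimal, rounded half away from zero."""
    if asr_start <= 0:
        raise ValueError("starting rate must be positive")
    x = 100.0 * (asr_end - asr_start) / asr_start
    return float(np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5) / 10.0)


def proportional_mortality(deaths_by_cause: pd.Series | dict[str, float]
                           ) -> pd.Series:
    """Cause shares of total deaths in percent, summing to 100."""
    s = pd.Series(deaths_by_cause, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("total deaths must be positive")
    if (s < 0).any():
        raise ValueError("negative death counts")
    return 100.0 * s / total


def proportional_mortality_from_cube(cube: EstimateCube,
                                     population: pd.DataFrame,
                                     years: list[int] | None = None
                                     ) -> pd.DataFrame:
    """Cause shares of expected deaths per year at the cube's level.

    Expected deaths per cause = sum over strata of rate * person-years,
    from the posterior-mean rates.
    """
    w = _population_array(population, cube)
    exp_deaths = np.einsum("ypsac,ypsa->yc", np.exp(cube.log_mean), w)
    years_out = years or cube.years
    rows = []
    for y in years_out:
        iy = cube.years.index(y)
        shares = proportional_mortality(
            pd.Series(exp_deaths[iy], index=cube.causes))
        for cause in cube.causes:
            rows.append({"year": y, "level": "national", "cause": cause,
                         "share_percent": float(shares[cause])})
    return pd.DataFrame(rows)


def make_summary_table(asr: pd.DataFrame,
                       years: tuple[int, int, int] = (2001, 2015, 2030)
                       ) -> pd.DataFrame:
    """Wide per-province table: ASR at three years plus percent change.

    ``asr`` must hold national and provincial both-sex series for every
    cause at the three years.  The percent-change column is computed from
    the unrounded point ASRs of the last two years.
    """
    y0, y1, y2 = years
    missing = [y for y in years if y not in set(asr["year"])]
    if missing:
        raise ValueError(f"ASR series missing year {missing[0]}")
    rows = []
    provinces = sorted(asr["province_id"].unique())
    if "national" in provinces:  # national row first
        provinces = ["national"] + [p for p in provinces if p != "national"]
    for pid in provinces:
        row: dict[str, object] = {"province_id": pid}
        sub = asr[asr["province_id"] == pid].set_index(["cause", "year"])
        for cause in sorted(asr["cause"].unique()):
            for y in years:
                rec = sub.loc[(cause, y)]
                row[f"{cause}_asr_{y}"] = round(float(rec["asr"]), 1)
                row[f"{cause}_lo_{y}"] = round(float(rec["lo"]), 1)
                row[f"{cause}_hi_{y}"] = round(float(rec["hi"]), 1)
            row[f"{cause}_pct_change"] = percent_change(
                float(sub.loc[(cause, y1)]["asr"]),
                float(sub.loc[(cause, y2)]["asr"]))
        rows.append(row)
    return pd.DataFrame(rows)
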