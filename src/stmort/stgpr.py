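"""Three-stage spatio-temporal estimator for log mortality rates.

Stage 1 — Gaussian linear mixed model per (cause, sex): log rate on age-band
intercepts, three socioeconomic covariates and a province random intercept,
precision-weighted by delta-method sampling variances and fitted by a
conjugate Gibbs sampler (Normal priors on coefficients, Inverse-Gamma on
variances).

Stage 2 — residuals smoothed over age, time and space with separable
weights (tricube in time, exponential in age-band distance, geometric decay
in graph distance) and added back to the stage-1 prediction.

Stage 3 — an exact Gaussian-process posterior per (province, sex, age,
cause) time series, prior mean the stage-2 surface, Matern-5/2 (or RBF)
kernel, heteroskedastic observation noise.  Evaluating the posterior over
observed *and* future years yields projections whose uncertainty widens
with the horizon; stage-1 coefficient uncertainty is propagated into the
projected draws through the posterior's linear response to prior-mean
shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ages import AGE_GROUPS, SEXES
from .causes import CAUSES
from .synthetic import COVARIATES, MissingStratumError

logger = logging.getLogger(__name__)

KEY5 = ["year", "province_id", "sex", "age_group", "cause"]


# ---------------------------------------------------------------------------
# rate observations

def compute_log_rates(deaths: pd.DataFrame, population: pd.DataFrame,
                      causes: tuple[str, ...] = CAUSES) -> pd.DataFrame:
    """Log mortality rates with delta-method variances for every stratum.

    The stratum grid is the population table crossed with the cause list;
    death strata absent from the table count as zero.  Rates use a +0.5
    continuity correction when deaths < 1 and variance 1/max(deaths, 0.5),
    so zero-count strata stay finite with honestly inflated uncertainty.
    """
    pop = population.set_index(["year", "province_id", "sex", "age_group"])["population"]
    if (pop <= 0).any():
        raise ValueError("population must be strictly positive")
    grid = population[["year", "province_id", "sex", "age_group"]].drop_duplicates()
    grid = grid.merge(pd.DataFrame({"cause": list(causes)}), how="cross")
    extra = set(map(tuple, deaths[["year", "province_id", "sex", "age_group"]]
                    .drop_duplicates().itertuples(index=False))) - \
        set(map(tuple, grid[["year", "province_id", "sex", "age_group"]]
                .drop_duplicates().itertuples(index=False)))
    if extra:
        raise MissingStratumError(f"population missing for stratum {sorted(extra)[0]}")
    obs = grid.merge(deaths, on=KEY5, how="left").fillna({"deaths": 0.0})
    py = pop.loc[pd.MultiIndex.from_frame(
        obs[["year", "province_id", "sex", "age_group"]])].to_numpy()
    d = obs["deaths"].to_numpy(dtype=float)
    rate = np.where(d < 1.0, (d + 0.5) / py, d / py)
    obs["log_rate"] = np.log(rate)
    obs["variance"] = 1.0 / np.maximum(d, 0.5)
    obs["population"] = py
    return obs


# ---------------------------------------------------------------------------
# stage 1: conjugate Gibbs sampler for the weighted linear mixed model

def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


class MixedEffectsGibbs(BaseEstimator):
    """Bayesian weighted linear mixed model with one random-intercept grouping.

    Model: y_i ~ N(x_i' beta + u_{g(i)}, sigma2 * v_i) with known relative
    variances v_i; u_g ~ N(0, tau2); beta ~ N(0, prior_var I);
    sigma2, tau2 ~ Inverse-Gamma(ig_shape, ig_scale).  All full conditionals
    are conjugate, and the chain runs on precomputed sufficient statistics,
    so cost per sweep is O(p^2 + G) regardless of n.

    After each sweep the mean of the random effects is swept into the
    columns listed in ``recenter_cols`` (typically the age intercepts),
    which enforces the sum-to-zero parameterization draw by draw.
    """

    def __init__(self, iterations: int = 10_000, burnin: int = 5_000,
                 thin: int = 5, prior_var: float = 100.0,
                 ig_shape: float = 1.0, ig_scale: float = 1.0,
                 recenter_cols: list[int] | None = None,
                 random_state: int | None = 0):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.prior_var = prior_var
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale
        self.recenter_cols = recenter_cols
        self.random_state = random_state

    def fit(self, X, y, *, groups, obs_variance):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        v = np.asarray(obs_variance, dtype=float).ravel()
        n, p = X.shape
        if np.any(v <= 0):
            raise ValueError("observation variances must be positive")
        uniq, gidx = np.unique(groups, return_inverse=True)
        G = uniq.size
        w = 1.0 / v

        xtwx = (X * w[:, None]).T @ X
        if np.linalg.matrix_rank(xtwx) < p:
            raise np.linalg.LinAlgError("singular weighted design matrix")
        xtwy = X.T @ (w * y)
        gx = np.zeros((G, p))
        np.add.at(gx, gidx, X * w[:, None])
        gy = np.bincount(gidx, weights=w * y, minlength=G)
        sumw = np.bincount(gidx, weights=w, minlength=G)
        ywy = float(w @ (y * y))

        rng = np.random.default_rng(self.random_state)
        keep = max((self.iterations - self.burnin) // self.thin, 1)
        draws_beta = np.empty((keep, p))
        draws_u = np.empty((keep, G))
        draws_s2 = np.empty(keep)
        draws_t2 = np.empty(keep)

        beta = np.linalg.solve(xtwx + np.eye(p) / self.prior_var, xtwy)
        u = np.zeros(G)
        sigma2, tau2 = 1.0, 0.1
        rc = np.asarray(self.recenter_cols if self.recenter_cols is not None
                        else range(p), dtype=int)
        k = 0
        for it in range(self.iterations):
            # beta | u, sigma2
            prec = xtwx / sigma2 + np.eye(p) / self.prior_var
            rhs = (xtwy - gx.T @ u) / sigma2
            cf = cho_factor(prec, lower=True)
            mean = cho_solve(cf, rhs)
            z = solve_triangular(cf[0], rng.standard_normal(p),
                                 lower=True, trans="T")
            beta = mean + z
            # u | beta, sigma2, tau2
            pg = sumw / sigma2 + 1.0 / tau2
            mg = (gy - gx @ beta) / sigma2 / pg
            u = mg + rng.standard_normal(G) / np.sqrt(pg)
            # sweep mean(u) into the intercept columns
            ubar = u.mean()
            u -= ubar
            beta[rc] += ubar
            # sigma2 | beta, u  (weighted residual sum of squares)
            rss = (ywy - 2 * beta @ xtwy + beta @ xtwx @ beta
                   - 2 * u @ gy + 2 * u @ (gx @ beta) + (sumw * u * u).sum())
            sigma2 = 1.0 / rng.gamma(self.ig_shape + 0.5 * n,
                                     1.0 / (self.ig_scale + 0.5 * max(rss, 1e-12)))
            # tau2 | u
            tau2 = 1.0 / rng.gamma(self.ig_shape + 0.5 * G,
                                   1.0 / (self.ig_scale + 0.5 * float(u @ u)))
            if it >= self.burnin and (it - self.burnin) % self.thin == 0 and k < keep:
                draws_beta[k] = beta
                draws_u[k] = u
                draws_s2[k] = sigma2
                draws_t2[k] = tau2
                k += 1

        self.groups_ = uniq
        self.draws_ = {"beta": draws_beta[:k], "u": draws_u[:k],
                       "sigma2": draws_s2[:k], "tau2": draws_t2[:k]}
        self.coef_ = draws_beta[:k].mean(axis=0)
        self.group_effects_ = draws_u[:k].mean(axis=0)
        self.sigma2_ = float(draws_s2[:k].mean())
        self.tau2_ = float(draws_t2[:k].mean())
        self.ess_ = np.array([effective_sample_size(draws_beta[:k, j])
                              for j in range(p)])
        if np.any(self.ess_ < 100):
            logger.warning("MixedEffectsGibbs: low ESS %s", self.ess_.round(1))
        return self

    def predict(self, X, groups=None):
        check_is_fitted(self, "coef_")
        mu = np.asarray(X, dtype=float) @ self.coef_
        if groups is not None:
            lut = {g: e for g, e in zip(self.groups_, self.group_effects_)}
            mu = mu + np.asarray([lut.get(g, 0.0) for g in np.asarray(groups)])
        return mu

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(p, 2) equal-tailed interval for the fixed-effect coefficients."""
        check_is_fitted(self, "draws_")
        a = 100 * (1 - level) / 2
        return np.percentile(self.draws_["beta"], [a, 100 - a], axis=0).T


@dataclass
class Stage1Fit:
    """Per-(cause, sex) mixed-model fits plus the shared design layout.

    Design columns: 13 age-band indicators followed by the three covariates.
    """

    models: dict[tuple[str, str], MixedEffectsGibbs]
    provinces: list[str]
    age_groups: list[str] = field(default_factory=lambda: list(AGE_GROUPS))
    covariate_names: tuple[str, ...] = COVARIATES

    def beta(self, cause: str, sex: str) -> np.ndarray:
        """Posterior-mean covariate coefficients (3,)."""
        return self.models[(cause, sex)].coef_[len(self.age_groups):]

    def predict_grid(self, covariates: pd.DataFrame, years: list[int]
                     ) -> pd.DataFrame:
        """Stage-1 log-rate prediction for every stratum in the year list."""
        cov = covariates[covariates["year"].isin(years)]
        frames = []
        n_age = len(self.age_groups)
        for (cause, sex), model in self.models.items():
            sub = cov[cov["sex"] == sex]
            if sub.empty:
                continue
            covx = sub[list(self.covariate_names)].to_numpy()
            lut = {g: e for g, e in zip(model.groups_, model.group_effects_)}
            ueff = sub["province_id"].map(lut).fillna(0.0).to_numpy()
            base = covx @ model.coef_[n_age:] + ueff
            for a, age in enumerate(self.age_groups):
                f = sub[["year", "province_id", "sex"]].copy()
                f["age_group"] = age
                f["cause"] = cause
                f["stage1"] = base + model.coef_[a]
                frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _design(obs: pd.DataFrame, covariates: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    cov = covariates.set_index(["year", "province_id", "sex"])
    key = pd.MultiIndex.from_frame(obs[["year", "province_id", "sex"]])
    missing = key.difference(cov.index)
    if len(missing) > 0:
        raise MissingStratumError(f"covariates missing for stratum {tuple(missing[0])}")
    covx = cov.loc[key, list(COVARIATES)].to_numpy(dtype=float)
    ages = pd.Categorical(obs["age_group"], categories=list(AGE_GROUPS))
    agemat = np.eye(len(AGE_GROUPS))[ages.codes]
    X = np.hstack([agemat, covx])
    y = obs["log_rate"].to_numpy(dtype=float)
    v = obs["variance"].to_numpy(dtype=float)
    return X, y, obs["province_id"].to_numpy(), v


def fit_stage1(obs: pd.DataFrame, covariates: pd.DataFrame,
               iterations: int = 10_000, burnin: int = 5_000, thin: int = 5,
               seed: int = 0) -> Stage1Fit:
    """Fit the stage-1 mixed model separately per (cause, sex)."""
    if obs["province_id"].nunique() < 2 or obs["year"].nunique() < 3:
        raise ValueError("stage 1 needs >= 2 provinces and >= 3 years")
    models = {}
    n_age = len(AGE_GROUPS)
    combos = sorted(set(zip(obs["cause"], obs["sex"])))
    for k, (cause, sex) in enumerate(combos):
        sub = obs[(obs["cause"] == cause) & (obs["sex"] == sex)]
        X, y, groups, v = _design(sub, covariates)
        m = MixedEffectsGibbs(iterations=iterations, burnin=burnin, thin=thin,
                              recenter_cols=list(range(n_age)),
                              random_state=seed + 1000 * k)
        m.fit(X, y, groups=groups, obs_variance=v)
        models[(cause, sex)] = m
    return Stage1Fit(models=models, provinces=sorted(obs["province_id"].unique()))


# ---------------------------------------------------------------------------
# stage 2: age-space-time residual smoothing

@dataclass
class SmoothingConfig:
    """Separable residual-smoothing weights.

    w_time = (1 - (|dt| / (max|dt| + 1))^lambda_time)^3   (tricube-style)
    w_age  = exp(-omega_age * |da|)  with da in band steps
    w_space = zeta_space^g for graph distance g <= max_graph_distance, else 0
    """

    lambda_time: float = 2.0
    omega_age: float = 1.0
    zeta_space: float = 0.9
    max_graph_distance: int = 2

    def __post_init__(self) -> None:
        if self.lambda_time <= 0:
            raise ValueError("lambda_time must be > 0")
        if self.omega_age < 0:
            raise ValueError("omega_age must be >= 0")
        if not 0 < self.zeta_space <= 1:
            raise ValueError("zeta_space must be in (0, 1]")
        if self.max_graph_distance < 0:
            raise ValueError("max_graph_distance must be >= 0")


def time_weights(target_years: np.ndarray, obs_years: np.ndarray,
                 lambda_time: float) -> np.ndarray:
    """(T_target, T_obs) tricube-style weights, row-normalized range."""
    dt = np.abs(target_years[:, None] - obs_years[None, :]).astype(float)
    dmax = dt.max(axis=1, keepdims=True)
    return (1.0 - (dt / (dmax + 1.0)) ** lambda_time) ** 3


def space_weights(graph: nx.Graph, provinces: list[str],
                  zeta: float, max_distance: int) -> np.ndarray:
    dist = dict(nx.all_pairs_shortest_path_length(graph, cutoff=max_distance))
    P = len(provinces)
    W = np.zeros((P, P))
    for i, a in enumerate(provinces):
        da = dist.get(a, {a: 0})
        for j, b in enumerate(provinces):
            g = da.get(b)
            if g is not None and g <= max_distance:
                W[i, j] = zeta ** g
    return W


def smooth_residuals(stage1_pred: pd.DataFrame, obs: pd.DataFrame,
                     config: SmoothingConfig, graph: nx.Graph,
                     target_years: list[int] | None = None) -> pd.DataFrame:
    """Weighted-average residual surface added back onto stage-1 predictions.

    ``stage1_pred`` must carry a ``stage1`` column over the target strata
    (observed and, for projection, future years).  Residuals are computed on
    observed strata only; the smoothed residual at a target stratum is the
    weight-normalized average over all observed strata, with separable
    age/time/space weights.  Strata with an empty neighbourhood get a zero
    smoothed residual (logged).
    """
    obs_years = np.array(sorted(obs["year"].unique()))
    if target_years is None:
        target_years = [int(y) for y in obs_years]
    tgt_years = np.array(sorted(target_years))
    provinces = sorted(stage1_pred["province_id"].unique())
    p_idx = {p: i for i, p in enumerate(provinces)}
    a_idx = {a: i for i, a in enumerate(AGE_GROUPS)}
    t_idx = {int(t): i for i, t in enumerate(obs_years)}
    P, A, T = len(provinces), len(AGE_GROUPS), len(obs_years)

    Wt = time_weights(tgt_years, obs_years, config.lambda_time)
    Wa = np.exp(-config.omega_age
                * np.abs(np.arange(A)[:, None] - np.arange(A)[None, :]))
    Ws = space_weights(graph, provinces, config.zeta_space,
                       config.max_graph_distance)

    pred_obs = stage1_pred[stage1_pred["year"].isin(obs_years)]
    merged = obs.merge(pred_obs, on=KEY5, how="inner")
    merged["resid"] = merged["log_rate"] - merged["stage1"]

    out_frames = []
    for (cause, sex), grp in merged.groupby(["cause", "sex"]):
        R = np.zeros((P, A, T))
        M = np.zeros((P, A, T))
        pi = grp["province_id"].map(p_idx).to_numpy()
        ai = grp["age_group"].map(a_idx).to_numpy()
        ti = grp["year"].map(t_idx).to_numpy()
        R[pi, ai, ti] = grp["resid"].to_numpy()
        M[pi, ai, ti] = 1.0
        num = np.einsum("Pp,Aa,Tt,pat->PAT", Ws, Wa, Wt, R * M, optimize=True)
        den = np.einsum("Pp,Aa,Tt,pat->PAT", Ws, Wa, Wt, M, optimize=True)
        empty = den <= 0
        if empty.any():
            logger.warning("smooth_residuals: %d empty neighbourhoods for %s/%s",
                           int(empty.sum()), cause, sex)
        sm = np.where(empty, 0.0, num / np.where(empty, 1.0, den))
        tgt = stage1_pred[(stage1_pred["cause"] == cause)
                          & (stage1_pred["sex"] == sex)
                          & stage1_pred["year"].isin(tgt_years)].copy()
        ti2 = tgt["year"].map({int(t): i for i, t in enumerate(tgt_years)}).to_numpy()
        pi2 = tgt["province_id"].map(p_idx).to_numpy()
        ai2 = tgt["age_group"].map(a_idx).to_numpy()
        tgt["smoothed_resid"] = sm[pi2, ai2, ti2]
        tgt["stage2"] = tgt["stage1"] + tgt["smoothed_resid"]
        out_frames.append(tgt)
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stage 3: Gaussian-process smoothing and projection

@dataclass
class GPRConfig:
    kernel: str = "matern52"
    length_scale: float = 10.0
    amplitude_rule: str = "mad"
    amplitude: float = 0.1
    n_draws: int = 1000
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if self.kernel not in ("matern52", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be > 0")
        if self.amplitude_rule not in ("mad", "fixed"):
            raise ValueError(f"unknown amplitude_rule {self.amplitude_rule!r}")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


def kernel_matrix(t1: np.ndarray, t2: np.ndarray, kernel: str,
                  length_scale: float) -> np.ndarray:
    r = np.abs(t1[:, None] - t2[None, :]) / length_scale
    if kernel == "rbf":
        return np.exp(-0.5 * r * r)
    s = np.sqrt(5.0) * r
    return (1.0 + s + s * s / 3.0) * np.exp(-s)


def gp_posterior(t_obs: np.ndarray, y: np.ndarray, noise_var: np.ndarray,
                 t_all: np.ndarray, mean_all: np.ndarray, mean_obs: np.ndarray,
                 amplitude: float, config: GPRConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact GP posterior: (posterior mean, covariance, response operator).

    The response operator B maps a prior-mean shift evaluated at (all, obs)
    years to the induced posterior-mean shift: shift_post = d_all - B d_obs.
    """
    a2 = amplitude * amplitude
    Koo = a2 * kernel_matrix(t_obs, t_obs, config.kernel, config.length_scale)
    Koo[np.diag_indices_from(Koo)] += noise_var + config.jitter
    Kao = a2 * kernel_matrix(t_all, t_obs, config.kernel, config.length_scale)
    Kaa = a2 * kernel_matrix(t_all, t_all, config.kernel, config.length_scale)
    cf = cho_factor(Koo, lower=True)
    B = cho_solve(cf, Kao.T).T  # (n_all, n_obs)
    post_mean = mean_all + B @ (y - mean_obs)
    post_cov = Kaa - B @ Kao.T
    return post_mean, post_cov, B


def _chol_with_jitter(cov: np.ndarray, jitter: float, label: str) -> np.ndarray:
    eps = jitter
    for _ in range(8):
        try:
            return cholesky(cov + eps * np.eye(cov.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError(
        f"posterior covariance not positive definite for series {label}")


@dataclass
class EstimateCube:
    """Posterior log-rate surface over observed and projected years.

    ``log_mean`` has shape (year, province, sex, age, cause); ``draws``
    prepends a draw axis (float32).  Intervals are the 2.5/97.5 draw
    percentiles.
    """

    years: list[int]
    provinces: list[str]
    sexes: list[str]
    ages: list[str]
    causes: list[str]
    log_mean: np.ndarray
    draws: np.ndarray

    def percentiles(self, q=(2.5, 97.5)) -> np.ndarray:
        return np.percentile(self.draws, q, axis=0)

    def to_frame(self, per: float = 1e5) -> pd.DataFrame:
        """Long table of rates per ``per`` person-years with 95% intervals."""
        lo, hi = self.percentiles()
        idx = pd.MultiIndex.from_product(
            [self.years, self.provinces, self.sexes, self.ages, self.causes],
            names=KEY5)
        df = pd.DataFrame({
            "rate_mean": per * np.exp(self.log_mean).ravel(),
            "rate_lo": per * np.exp(lo.astype(float)).ravel(),
            "rate_hi": per * np.exp(hi.astype(float)).ravel(),
        }, index=idx).reset_index()
        return df


class STGPREstimator(BaseEstimator):
    """Full three-stage estimator with projection to a horizon year.

    fit() consumes the cleaned death table, person-years, a covariate table
    covering every year up to ``horizon_year``, and the province adjacency
    graph; the fitted attribute ``cube_`` holds posterior means and draws
    for all years from the first observed year to the horizon.  Stages 2
    and 3 can be disabled, which reduces the estimator to the mixed-model
    (or mixed-model + smoothing) prediction.
    """

    def __init__(self, iterations: int = 10_000, burnin: int = 5_000,
                 thin: int = 5, lambda_time: float = 2.0,
                 omega_age: float = 1.0, zeta_space: float = 0.9,
                 max_graph_distance: int = 2, kernel: str = "matern52",
                 length_scale: float = 10.0, amplitude_rule: str = "mad",
                 amplitude: float = 0.1, n_draws: int = 1000,
                 jitter: float = 1e-6, horizon_year: int | None = None,
                 use_stage2: bool = True, use_gpr: bool = True,
                 propagate_stage1: bool = True, random_state: int = 0):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.lambda_time = lambda_time
        self.omega_age = omega_age
        self.zeta_space = zeta_space
        self.max_graph_distance = max_graph_distance
        self.kernel = kernel
        self.length_scale = length_scale
        self.amplitude_rule = amplitude_rule
        self.amplitude = amplitude
        self.n_draws = n_draws
        self.jitter = jitter
        self.horizon_year = horizon_year
        self.use_stage2 = use_stage2
        self.use_gpr = use_gpr
        self.propagate_stage1 = propagate_stage1
        self.random_state = random_state

    # -- config helpers -----------------------------------------------------
    def _smoothing(self) -> SmoothingConfig:
        return SmoothingConfig(self.lambda_time, self.omega_age,
                               self.zeta_space, self.max_graph_distance)

    def _gpr(self) -> GPRConfig:
        return GPRConfig(self.kernel, self.length_scale, self.amplitude_rule,
                         self.amplitude, self.n_draws, self.jitter)

    # -----------------------------------------------------------------------
    def fit(self, deaths: pd.DataFrame, population: pd.DataFrame,
            covariates: pd.DataFrame, graph: nx.Graph):
        causes = tuple(sorted(deaths["cause"].unique()))
        obs = compute_log_rates(deaths, population, causes=causes)
        obs_years = sorted(int(y) for y in obs["year"].unique())
        horizon = self.horizon_year or obs_years[-1]
        all_years = list(range(obs_years[0], horizon + 1))
        cov_years = set(covariates["year"].unique())
        missing_years = [y for y in all_years if y not in cov_years]
        if missing_years:
            raise MissingStratumError(
                f"projected covariates missing for year {missing_years[0]}")

        self.obs_ = obs
        self._covariates_for_shifts = covariates
        self.stage1_ = fit_stage1(obs, covariates, self.iterations,
                                  self.burnin, self.thin, self.random_state)
        pred = self.stage1_.predict_grid(covariates, all_years)
        if self.use_stage2:
            surface = smooth_residuals(pred, obs, self._smoothing(), graph,
                                       target_years=all_years)
        else:
            surface = pred.copy()
            surface["stage2"] = surface["stage1"]
        self.stage2_ = surface
        self.cube_ = self._fit_gpr_cube(surface, obs, all_years, obs_years)
        return self

    # -----------------------------------------------------------------------
    def _stage1_shift_draws(self, covariates: pd.DataFrame,
                            all_years: list[int], provinces: list[str]
                            ) -> dict[tuple[str, str], np.ndarray]:
        """Per-draw prior-mean offsets (D, P, A, T) around the posterior mean."""
        shifts = {}
        n_age = len(AGE_GROUPS)
        cov = covariates.set_index(["year", "province_id", "sex"]).sort_index()
        for (cause, sex), model in self.stage1_.models.items():
            S = model.draws_["beta"].shape[0]
            take = (np.arange(self.n_draws) * S) // self.n_draws
            dbeta = model.draws_["beta"][take] - model.coef_[None, :]
            du_all = model.draws_["u"][take] - model.group_effects_[None, :]
            gpos = {g: i for i, g in enumerate(model.groups_)}
            key = pd.MultiIndex.from_product([all_years, provinces, [sex]])
            covx = cov.loc[key, list(COVARIATES)].to_numpy().reshape(
                len(all_years), len(provinces), 3)
            # (D, T, P): covariate part
            part_cov = np.einsum("dk,tpk->dtp", dbeta[:, n_age:], covx)
            du = np.stack([du_all[:, gpos[p]] if p in gpos else
                           np.zeros(self.n_draws) for p in provinces], axis=1)
            shift = (part_cov.transpose(0, 2, 1)[:, :, None, :]
                     + dbeta[:, :n_age][:, None, :, None]
                     + du[:, :, None, None])
            shifts[(cause, sex)] = shift.astype(np.float32)  # (D, P, A, T)
        return shifts

    def _fit_gpr_cube(self, surface: pd.DataFrame, obs: pd.DataFrame,
                      all_years: list[int], obs_years: list[int]
                      ) -> EstimateCube:
        provinces = sorted(surface["province_id"].unique())
        causes = sorted(surface["cause"].unique())
        sexes = [s for s in SEXES if s in set(surface["sex"])]
        ages = list(AGE_GROUPS)
        Y, P, S, A, C = (len(all_years), len(provinces), len(sexes),
                         len(ages), len(causes))
        t_all = np.asarray(all_years, dtype=float)
        t_obs = np.asarray(obs_years, dtype=float)
        obs_pos = [all_years.index(y) for y in obs_years]

        sur = surface.set_index(KEY5)["stage2"]
        m_arr = sur.loc[pd.MultiIndex.from_product(
            [all_years, provinces, sexes, ages, causes])].to_numpy().reshape(
            Y, P, S, A, C)
        om = obs.set_index(KEY5)
        y_arr = om["log_rate"].loc[pd.MultiIndex.from_product(
            [obs_years, provinces, sexes, ages, causes])].to_numpy().reshape(
            len(obs_years), P, S, A, C)
        v_arr = om["variance"].loc[pd.MultiIndex.from_product(
            [obs_years, provinces, sexes, ages, causes])].to_numpy().reshape(
            len(obs_years), P, S, A, C)

        if not self.use_gpr:
            draws = np.broadcast_to(
                m_arr[None].astype(np.float32), (self.n_draws, Y, P, S, A, C)).copy()
            return EstimateCube(all_years, provinces, sexes, ages, causes,
                                m_arr, draws)

        rng = np.random.default_rng(self.random_state + 7)
        shifts = (self._stage1_shift_draws(
            self._covariates_for_shifts, all_years, provinces)
            if self.propagate_stage1
            and getattr(self, "_covariates_for_shifts", None) is not None
            else None)

        mean_out = np.empty((Y, P, S, A, C))
        draw_out = np.empty((self.n_draws, Y, P, S, A, C), dtype=np.float32)
        cfg = self._gpr()
        # unit-amplitude kernels are shared by every series
        C_oo = kernel_matrix(t_obs, t_obs, cfg.kernel, cfg.length_scale)
        C_ao = kernel_matrix(t_all, t_obs, cfg.kernel, cfg.length_scale)
        C_aa = kernel_matrix(t_all, t_all, cfg.kernel, cfg.length_scale)
        for ci, cause in enumerate(causes):
            for si, sex in enumerate(sexes):
                for pi, prov in enumerate(provinces):
                    for ai in range(A):
                        m_all = m_arr[:, pi, si, ai, ci]
                        yy = y_arr[:, pi, si, ai, ci]
                        vv = v_arr[:, pi, si, ai, ci]
                        m_obs = m_all[obs_pos]
                        if cfg.amplitude_rule == "mad":
                            amp = max(1.4826 * float(np.median(np.abs(yy - m_obs))),
                                      0.01)
                        else:
                            amp = cfg.amplitude
                        a2 = amp * amp
                        Koo = a2 * C_oo
                        Koo[np.diag_indices_from(Koo)] += vv + cfg.jitter
                        cf = cho_factor(Koo, lower=True)
                        B = cho_solve(cf, (a2 * C_ao).T).T
                        pm = m_all + B @ (yy - m_obs)
                        pc = a2 * C_aa - B @ (a2 * C_ao).T
                        L = _chol_with_jitter(pc, cfg.jitter,
                                              f"{prov}/{sex}/{ages[ai]}/{cause}")
                        z = rng.standard_normal((self.n_draws, Y))
                        draws = pm[None, :] + z @ L.T
                        if shifts is not None:
                            d_all = shifts[(cause, sex)][:, pi, ai, :].astype(float)
                            d_obs = d_all[:, obs_pos]
                            draws = draws + d_all - d_obs @ B.T
                        mean_out[:, pi, si, ai, ci] = pm
                        draw_out[:, :, pi, si, ai, ci] = draws.astype(np.float32)
        return EstimateCube(all_years, provinces, sexes, ages, causes,
                            mean_out, draw_out)

    def fit_with_covariates(self, deaths, population, covariates, graph):
        """fit() while retaining the covariate table for draw propagation."""
        self._covariates_for_shifts = covariates
        return self.fit(deaths, population, covariates, graph)


# ---------------------------------------------------------------------------
# spec-shaped functional wrappers

def fit_gpr(stage2: pd.DataFrame, obs: pd.DataFrame, config: GPRConfig,
            seed: int = 0) -> EstimateCube:
    """GP smoothing over the observed years only (no projection)."""
    est = STGPREstimator(kernel=config.kernel, length_scale=config.length_scale,
                         amplitude_rule=config.amplitude_rule,
                         amplitude=config.amplitude, n_draws=config.n_draws,
                         jitter=config.jitter, propagate_stage1=False,
                         random_state=seed)
    obs_years = sorted(int(y) for y in obs["year"].unique())
    return est._fit_gpr_cube(stage2, obs, obs_years, obs_years)


def project_rates(deaths: pd.DataFrame, population: pd.DataFrame,
                  projected_covariates: pd.DataFrame, graph: nx.Graph,
                  horizon_year: int = 2030, seed: int = 0,
                  **params) -> STGPREstimator:
    """Fit the full three-stage estimator through ``horizon_year``."""
    est = STGPREstimator(horizon_year=horizon_year, random_state=seed, **params)
    est.fit_with_covariates(deaths, population, projected_covariates, graph)
    return est
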