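"""Two-step estimation of the LAI dynamics parameters from plot GF series.

Drought-plot series are often too noisy to fit on their own, so estimation is
staged:

1. *Genotype-level joint fit* -- all plots of a genotype (pooled across
   treatments within a year) are fitted together under the assumption that
   ``r_g``, ``r_s``, ``t_g`` and ``t_s`` are genotype properties shared across
   treatments, while ``lai_amp`` is free per plot.  ``(t_g, t_s)`` are found by
   grid search on a 7x7 lattice over (300, 1200) x (1400, 3000) degree-days;
   the remaining parameters are minimised by Nelder-Mead at each lattice point.
2. *Per-plot refinement* -- each plot is re-fitted alone, with the grid
   narrowed to +-200 (t_g) / +-400 (t_s) degree-days around the stage-1 optimum
   and the simplex started from the stage-1 values.

The cost is a heteroscedasticity-weighted sum of squares

    sum_d sum_i (y_{i,d} - yhat_{i,d})^2 / ybar_d

where ``ybar_d`` is the mean observed GF over all plots of the environment on
date ``d``: measurement noise of the green fraction grows roughly in
proportion to its mean, and the division keeps late (large-canopy) dates from
dominating the fit.  Dates whose mean GF is essentially zero are excluded to
avoid dividing by zero.

Positivity of ``lai_amp``, ``r_g`` and ``r_s`` is enforced by optimising their
logarithms, so the simplex itself is unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .growth import DEFAULT_EXTINCTION, DynamicsParams, gf_curve_arrays, gf_to_lai

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the two-step fit."""

    tg_range: tuple = (300.0, 1200.0)
    ts_range: tuple = (1400.0, 3000.0)
    n_grid: int = 7
    refine_tg_halfwidth: float = 200.0
    refine_ts_halfwidth: float = 400.0
    simplex_fatol: float = 1e-9
    simplex_xatol: float = 1e-6
    max_iter: int = 2000
    init_lai_amp: float | None = None  # None -> derived from each plot's max GF
    init_r_g: float = 0.01
    init_r_s: float = 0.004
    # candidate starts screened at each grid cell before the simplex runs;
    # guards against the slow-growth/huge-amplitude local optimum
    init_r_g_grid: tuple = (0.005, 0.01, 0.02, 0.04)
    init_r_s_grid: tuple = (0.001, 0.004, 0.012)
    ybar_floor: float = 1e-4
    k: float = DEFAULT_EXTINCTION

    def __post_init__(self):
        if self.tg_range[0] >= self.tg_range[1] or self.ts_range[0] >= self.ts_range[1]:
            raise ValueError("grid ranges must be ordered (lo, hi)")
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        if self.refine_tg_halfwidth <= 0 or self.refine_ts_halfwidth <= 0:
            raise ValueError("refinement halfwidths must be positive")


@dataclass
class Stage1Result:
    """Genotype-level joint fit: shared curve shape, one amplitude per plot."""

    genotype_id: str
    r_g: float
    r_s: float
    t_g: float
    t_s: float
    amp_by_plot: dict
    cost: float
    converged: bool
    degenerate: bool = False


@dataclass
class FitResult:
    """Final per-plot parameter estimate."""

    plot_id: str
    params: DynamicsParams
    cost: float
    stage: str  # 'genotype_joint' or 'plot_refined'
    converged: bool


def fit_cost(observed, predicted, daily_means) -> float:
    """Weighted residual cost  sum (y - yhat)^2 / ybar  over observations.

    ``daily_means`` carries the per-date mean GF aligned with the
    observations; a non-positive mean on a date with observations is an error
    (callers exclude such dates up front).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    ybar = np.asarray(daily_means, dtype=float)
    if not (y.shape == yhat.shape == ybar.shape):
        raise ValueError("observed, predicted and daily_means must align")
    if np.any(ybar <= 0):
        raise ValueError("daily means must be positive on all observed dates")
    return float(np.sum((y - yhat) ** 2 / ybar))


def _grid(lo: float, hi: float, n: int) -> np.ndarray:
    # inclusive endpoints: n points evenly distributed over the stated range
    return np.linspace(lo, hi, n)


def _init_amp(gf_max: float, config: FitConfig) -> float:
    if config.init_lai_amp is not None:
        return config.init_lai_amp
    gf_max = min(max(gf_max, 1e-3), 0.95)
    return max(float(gf_to_lai(gf_max, config.k)), 0.05)


def _minimize_cell(objective, theta0, config):
    res = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": config.max_iter,
            "fatol": config.simplex_fatol,
            "xatol": config.simplex_xatol,
        },
    )
    return res


def fit_genotype_joint(obs: pd.DataFrame, config: FitConfig | None = None) -> Stage1Result:
    """Stage 1: jointly fit all plots of one genotype.

    ``obs`` needs columns ``plot_id``, ``gdd``, ``gf`` and ``ybar`` (mean GF of
    the plot's environment on the observation date).  Rows whose ``ybar`` falls
    below the configured floor are excluded from the cost.
    """
    config = config or FitConfig()
    genotype_id = str(obs["genotype_id"].iloc[0]) if "genotype_id" in obs else ""
    kept = obs[obs["ybar"] >= config.ybar_floor]
    plots = list(dict.fromkeys(obs["plot_id"]))

    init = {
        p: _init_amp(kept.loc[kept["plot_id"] == p, "gf"].max() if (kept["plot_id"] == p).any() else 0.0, config)
        for p in plots
    }
    if len(kept) < 5 or kept["gf"].max() <= 0:
        logger.warning("genotype %s: degenerate series, carrying initial values", genotype_id)
        return Stage1Result(
            genotype_id=genotype_id,
            r_g=config.init_r_g,
            r_s=config.init_r_s,
            t_g=float(np.mean(config.tg_range)),
            t_s=float(np.mean(config.ts_range)),
            amp_by_plot=init,
            cost=np.inf,
            converged=False,
            degenerate=True,
        )

    gdd = kept["gdd"].to_numpy(dtype=float)
    gf = kept["gf"].to_numpy(dtype=float)
    ybar = kept["ybar"].to_numpy(dtype=float)
    plot_idx = pd.Categorical(kept["plot_id"], categories=plots).codes
    k = config.k
    # per-plot LAI ceiling implied by the largest observed GF; used to match
    # candidate amplitudes to the data at every grid cell
    lai_max = np.array(
        [
            max(float(gf_to_lai(min(max(gf[plot_idx == i].max(initial=0.0), 1e-3), 0.95), k)), 0.05)
            for i in range(len(plots))
        ]
    )

    def make_objective(tg, ts):
        def objective(theta):
            theta = np.clip(theta, -40.0, 40.0)  # keep simplex excursions finite
            r_g, r_s = np.exp(theta[0]), np.exp(theta[1])
            amps = np.exp(theta[2:])
            yhat = gf_curve_arrays(amps[plot_idx], r_g, r_s, tg, ts, gdd, k)
            return float(np.sum((gf - yhat) ** 2 / ybar))

        return objective

    rg_cands = tuple(dict.fromkeys((config.init_r_g,) + tuple(config.init_r_g_grid)))
    rs_cands = tuple(dict.fromkeys((config.init_r_s,) + tuple(config.init_r_s_grid)))

    def best_start(objective, tg, ts):
        best_c = None
        for rg0 in rg_cands:
            for rs0 in rs_cands:
                bracket = expit(rg0 * (gdd - tg)) - np.exp(np.minimum(rs0 * (gdd - ts), 50.0))
                bmax = max(float(bracket.max()), 0.05)
                theta = np.concatenate(
                    [[np.log(rg0), np.log(rs0)], np.log(np.maximum(lai_max / bmax, 0.05))]
                )
                c = objective(theta)
                if best_c is None or c < best_c[0]:
                    best_c = (c, theta)
        return best_c[1]

    best = None
    any_converged = False
    for tg in _grid(*config.tg_range, config.n_grid):
        for ts in _grid(*config.ts_range, config.n_grid):
            objective = make_objective(tg, ts)
            res = _minimize_cell(objective, best_start(objective, tg, ts), config)
            any_converged = any_converged or res.success
            # strict '<' keeps the first (lowest t_g, then t_s) among ties
            if best is None or res.fun < best[0]:
                best = (res.fun, tg, ts, res.x)

    cost, tg, ts, theta = best
    amps = np.exp(theta[2:])
    if not any_converged:
        logger.warning("genotype %s: no grid cell converged; flagged unfit", genotype_id)
        return Stage1Result(
            genotype_id=genotype_id,
            r_g=config.init_r_g,
            r_s=config.init_r_s,
            t_g=float(np.mean(config.tg_range)),
            t_s=float(np.mean(config.ts_range)),
            amp_by_plot=init,
            cost=float(cost),
            converged=False,
            degenerate=False,
        )
    return Stage1Result(
        genotype_id=genotype_id,
        r_g=float(np.exp(theta[0])),
        r_s=float(np.exp(theta[1])),
        t_g=float(tg),
        t_s=float(ts),
        amp_by_plot={p: float(a) for p, a in zip(plots, amps)},
        cost=float(cost),
        converged=True,
    )


def fit_plot_refine(
    obs: pd.DataFrame, stage1: Stage1Result, config: FitConfig | None = None
) -> FitResult:
    """Stage 2: refine the fit of a single plot around the stage-1 optimum."""
    config = config or FitConfig()
    plot_id = str(obs["plot_id"].iloc[0])
    amp1 = stage1.amp_by_plot.get(plot_id, _init_amp(obs["gf"].max(), config))
    stage1_params = DynamicsParams(amp1, stage1.r_g, stage1.r_s, stage1.t_g, stage1.t_s)

    kept = obs[obs["ybar"] >= config.ybar_floor]
    # three free simplex parameters plus the two grid axes
    if len(kept) < 5 or stage1.degenerate:
        logger.warning("plot %s: too few usable observations; keeping stage-1 params", plot_id)
        return FitResult(plot_id, stage1_params, stage1.cost, "genotype_joint", False)

    gdd = kept["gdd"].to_numpy(dtype=float)
    gf = kept["gf"].to_numpy(dtype=float)
    ybar = kept["ybar"].to_numpy(dtype=float)
    k = config.k

    tg_lo = max(stage1.t_g - config.refine_tg_halfwidth, config.tg_range[0])
    tg_hi = min(stage1.t_g + config.refine_tg_halfwidth, config.tg_range[1])
    ts_lo = max(stage1.t_s - config.refine_ts_halfwidth, config.ts_range[0])
    ts_hi = min(stage1.t_s + config.refine_ts_halfwidth, config.ts_range[1])

    def make_objective(tg, ts):
        def objective(theta):
            amp, r_g, r_s = np.exp(np.clip(theta, -40.0, 40.0))
            yhat = gf_curve_arrays(amp, r_g, r_s, tg, ts, gdd, k)
            return float(np.sum((gf - yhat) ** 2 / ybar))

        return objective

    lai_max = max(float(gf_to_lai(min(max(gf.max(initial=0.0), 1e-3), 0.95), k)), 0.05)
    rg_cands = tuple(dict.fromkeys((stage1.r_g,) + tuple(config.init_r_g_grid)))
    rs_cands = tuple(dict.fromkeys((stage1.r_s,) + tuple(config.init_r_s_grid)))

    def best_start(objective, tg, ts):
        theta0 = np.log([amp1, stage1.r_g, stage1.r_s])
        best_c = (objective(theta0), theta0)
        for rg0 in rg_cands:
            for rs0 in rs_cands:
                bracket = expit(rg0 * (gdd - tg)) - np.exp(np.minimum(rs0 * (gdd - ts), 50.0))
                theta = np.array(
                    [
                        np.log(max(lai_max / max(float(bracket.max()), 0.05), 0.05)),
                        np.log(rg0),
                        np.log(rs0),
                    ]
                )
                c = objective(theta)
                if c < best_c[0]:
                    best_c = (c, theta)
        return best_c[1]

    # the stage-1 optimum is kept on the lattice even when the window is
    # truncated at the global bounds, so refinement can never lose to stage 1
    tg_points = np.unique(np.append(_grid(tg_lo, tg_hi, config.n_grid), stage1.t_g))
    ts_points = np.unique(np.append(_grid(ts_lo, ts_hi, config.n_grid), stage1.t_s))
    best = None
    for tg in tg_points:
        for ts in ts_points:
            objective = make_objective(tg, ts)
            res = _minimize_cell(objective, best_start(objective, tg, ts), config)
            if best is None or res.fun < best[0]:
                best = (res.fun, tg, ts, res.x, res.success)

    cost, tg, ts, theta, ok = best
    # safeguard: never end above the plain stage-1 curve on this plot
    stage1_cost = make_objective(stage1.t_g, stage1.t_s)(
        np.log([amp1, stage1.r_g, stage1.r_s])
    )
    if stage1_cost < cost:
        return FitResult(plot_id, stage1_params, float(stage1_cost), "genotype_joint", True)
    amp, r_g, r_s = np.exp(theta)
    params = DynamicsParams(float(amp), float(r_g), float(r_s), float(tg), float(ts))
    return FitResult(plot_id, params, float(cost), "plot_refined", bool(ok))


def daily_mean_gf(pheno: pd.DataFrame) -> pd.Series:
    """Mean GF over all plots per (environment, date), the Eq-style weights."""
    return pheno.groupby(["environment_id", "date"])["gf"].transform("mean")


def fit_all(pheno: pd.DataFrame, config: FitConfig | None = None) -> pd.DataFrame:
    """Run both stages for every plot in a tidy phenotype table.

    ``pheno`` must carry ``plot_id, genotype_id, environment_id, year, block,
    date, gdd, gf``.  Stage 1 pools a genotype's plots across treatments within
    a year (environments are year x treatment; thermal time differs across
    years, so pooling across years is not attempted).  Returns a per-plot
    parameter table.
    """
    config = config or FitConfig()
    pheno = pheno.copy()
    pheno["ybar"] = daily_mean_gf(pheno)

    rows = []
    for (genotype, year), obs_g in pheno.groupby(["genotype_id", "year"], sort=True):
        stage1 = fit_genotype_joint(obs_g, config)
        for plot_id, obs_p in obs_g.groupby("plot_id", sort=True):
            result = fit_plot_refine(obs_p, stage1, config)
            p = result.params
            rows.append(
                {
                    "plot_id": plot_id,
                    "genotype_id": genotype,
                    "environment_id": obs_p["environment_id"].iloc[0],
                    "year": year,
                    "block": obs_p["block"].iloc[0],
                    "lai_amp": p.lai_amp,
                    "r_g": p.r_g,
                    "r_s": p.r_s,
                    "t_g": p.t_g,
                    "t_s": p.t_s,
                    "cost": result.cost,
                    "stage": result.stage,
                    "converged": result.converged,
                    "stage1_cost": stage1.cost,
                }
            )
    return pd.DataFrame(rows)
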