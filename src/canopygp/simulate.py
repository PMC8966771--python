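"""Synthetic multi-environment UAV trial generator.

Emulates the statistical structure of a germplasm field trial observed by
drone: a panel of inbred lines genotyped at biallelic SNPs, grown in several
environments (year x watering treatment) with two replicate blocks, whose
canopy green fraction is observed on a schedule of flight dates.

Per genotype x environment, the five LAI dynamics parameters are

    theta_j(g, env) = mean_j(env) * (1 + a_gj + w_gj)

where the additive genetic deviations ``a`` are linear in the markers with a
prescribed 5x5 genetic correlation matrix ``K_true`` and variance
``h2_j * cv^2``, and the non-genetic genotype deviations ``w`` are iid with
variance ``(1 - h2_j) * cv^2``, so the genotype-level heritability of each
parameter hits its target in expectation.  The drought treatment shrinks the
growth-related means (amplitude, growth rate, growth timing), mirroring how
water stress suppresses canopy expansion.

Plot-level lognormal jitter on the parameters separates genotypic from
residual variance in the genotypic-value model, and GF observations receive
additive Gaussian noise with standard deviation proportional to the mean GF
of the date (the same mean-proportional noise assumption that motivates the
weighted fitting cost), clipped to [0, 1).

Everything is deterministic given the config seed; regenerating with the same
config reproduces identical tables.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import PARAM_NAMES, ThermalTime, gf_curve_arrays

_DEFAULT_K_TRUE = np.array(
    [
        [1.0, 0.5, 0.2, 0.5, 0.2],
        [0.5, 1.0, 0.2, 0.4, 0.2],
        [0.2, 0.2, 1.0, 0.2, 0.4],
        [0.5, 0.4, 0.2, 1.0, 0.3],
        [0.2, 0.2, 0.4, 0.3, 1.0],
    ]
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and genetic-architecture settings of the simulator."""

    n_genotypes: int = 200
    n_markers: int = 2000
    #: markers come in linkage blocks: within a block, markers are noisy
    #: duplicates of one latent variant.  Real germplasm panels carry strong
    #: local LD, which is what gives genomic prediction its accuracy; fully
    #: independent markers would make every genomic model nearly uninformative
    #: at this panel size.
    ld_block_size: int = 10
    #: probability that a marker call deviates from its block's latent variant
    ld_mutation_rate: float = 0.05
    years: tuple = (2017, 2018, 2019)
    treatments: tuple = ("C", "D")
    n_blocks: int = 2
    flights_per_env: int = 16
    flight_start_day: int = 14
    flight_end_day: int = 75
    base_params: dict = field(
        default_factory=lambda: {
            "lai_amp": 3.5, "r_g": 0.02, "r_s": 0.004, "t_g": 700.0, "t_s": 2200.0
        }
    )
    # Drought suppresses canopy expansion: the amplitude shrinks strongly and
    # the growth rate and timing shift mildly.  The timing shrink is kept
    # small on purpose -- a logistic with a much earlier inflection would
    # overtake the control curve mid-season, and drought canopies sit below
    # control canopies throughout the season.
    drought_mult: dict = field(
        default_factory=lambda: {
            "lai_amp": 0.55, "r_g": 0.9, "r_s": 1.0, "t_g": 0.98, "t_s": 0.95
        }
    )
    year_mult: tuple = (1.0, 0.92, 0.85)  # lai_amp multiplier per year
    heritabilities: dict = field(
        default_factory=lambda: {
            "lai_amp": 0.8, "r_g": 0.6, "r_s": 0.3, "t_g": 0.7, "t_s": 0.3
        }
    )
    genetic_cv: float = 0.12          # total relative genotype deviation (sd)
    K_true: np.ndarray = field(default_factory=lambda: _DEFAULT_K_TRUE.copy())
    noise_cv: float = 0.05            # nu: GF noise sd = nu * mean GF of date
    plot_jitter_sd: float = 0.02      # lognormal sigma of plot-level jitter
    marker_missing_rate: float = 0.0
    base_temp: float = 8.0
    k: float = 0.5
    seed: int = 0

    def __post_init__(self):
        K = np.asarray(self.K_true, dtype=float)
        if K.shape != (5, 5) or not np.allclose(np.diag(K), 1.0):
            raise ValueError("K_true must be 5x5 with unit diagonal")
        if np.linalg.eigvalsh((K + K.T) / 2).min() < -1e-10:
            raise ValueError("K_true must be positive semi-definite")
        for h in self.heritabilities.values():
            if not 0.0 <= h <= 1.0:
                raise ValueError("heritabilities must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def environments(self) -> list:
        return [f"{y}-{t}" for y in self.years for t in self.treatments]

    def genotype_ids(self) -> list:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    params_by_env: dict            # env -> DataFrame genotype x PARAM_NAMES
    genetic_dev: pd.DataFrame      # genotype x param, marker-determined part
    nongenetic_dev: pd.DataFrame
    marker_effects: np.ndarray
    config: SimConfig


@dataclass
class SimData:
    pheno: pd.DataFrame
    temp: pd.DataFrame
    markers: pd.DataFrame
    truth: SimTruth
    thermal: dict                  # env -> ThermalTime
    flight_days: dict              # env -> ndarray of days after sowing


def simulate_markers(config: SimConfig, rng=None):
    """Biallelic SNP codes (-1/0/1, NaN missing) with U-shaped allele freqs.

    Markers are organised in LD blocks of ``ld_block_size``: each block has a
    latent variant and its markers copy the latent dosage except for rare
    deviations, giving the panel a realistic effective dimension.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, L = config.n_markers, max(int(config.ld_block_size), 1)
    n_blocks = (m + L - 1) // L
    block_freqs = np.clip(rng.beta(0.4, 0.4, size=n_blocks), 0.05, 0.95)
    block_dosage = rng.binomial(2, block_freqs, size=(config.n_genotypes, n_blocks))
    block_of = np.repeat(np.arange(n_blocks), L)[:m]
    freqs = block_freqs[block_of]
    dosage = block_dosage[:, block_of]
    flip = rng.random(dosage.shape) < config.ld_mutation_rate
    redraw = rng.binomial(2, freqs, size=dosage.shape)
    dosage = np.where(flip, redraw, dosage)
    codes = dosage.astype(float) - 1.0
    if config.marker_missing_rate > 0:
        miss = rng.random(codes.shape) < config.marker_missing_rate
        codes[miss] = np.nan
    df = pd.DataFrame(
        codes,
        index=pd.Index(config.genotype_ids(), name="genotype_id"),
        columns=[f"M{j + 1}" for j in range(config.n_markers)],
    )
    return df, freqs


def _env_means(config: SimConfig, env: str) -> dict:
    year, treatment = env.rsplit("-", 1)
    yi = list(config.years).index(int(year))
    means = dict(config.base_params)
    means["lai_amp"] = means["lai_amp"] * config.year_mult[yi]
    if treatment == "D":
        means = {p: means[p] * config.drought_mult[p] for p in means}
    return means


def simulate_genetic_values(markers: pd.DataFrame, config: SimConfig, rng=None) -> SimTruth:
    """True dynamics parameters per genotype x environment.

    Genetic deviations are built from the (imputed, scaled) marker matrix so
    they live exactly in the span the genomic relationship matrix can see.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    M = markers.to_numpy(dtype=float)
    M = np.where(np.isnan(M), np.nanmean(M, axis=0), M)
    sd = M.std(axis=0)
    Xs = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    m = Xs.shape[1]

    B = rng.standard_normal((m, 5)) / np.sqrt(m)
    raw = Xs @ B                                   # ~ independent unit columns
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    Lk = np.linalg.cholesky(config.K_true + 1e-10 * np.eye(5))
    corr = raw @ Lk.T                              # cov ~ K_true
    h2 = np.array([config.heritabilities[p] for p in PARAM_NAMES])
    cv = config.genetic_cv
    a = corr * (cv * np.sqrt(h2))[None, :]
    w = rng.standard_normal(corr.shape) * (cv * np.sqrt(1.0 - h2))[None, :]

    gids = list(markers.index)
    genetic = pd.DataFrame(a, index=gids, columns=list(PARAM_NAMES))
    nongenetic = pd.DataFrame(w, index=gids, columns=list(PARAM_NAMES))

    dev = 1.0 + a + w
    params_by_env = {}
    for env in config.environments:
        means = _env_means(config, env)
        vals = dev * np.array([means[p] for p in PARAM_NAMES])[None, :]
        df = pd.DataFrame(vals, index=gids, columns=list(PARAM_NAMES))
        df["lai_amp"] = df["lai_amp"].clip(lower=0.05)
        df["r_g"] = df["r_g"].clip(lower=1e-4)
        df["r_s"] = df["r_s"].clip(lower=1e-5)
        # keep senescence onset safely after the growth inflection
        df["t_s"] = np.maximum(df["t_s"], df["t_g"] + 300.0)
        params_by_env[env] = df
    return SimTruth(params_by_env, genetic, nongenetic, B, config)


def make_temperatures(config: SimConfig, rng=None):
    """Daily mean temperature per environment from sowing (first row = sowing)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n_days = config.flight_end_day + 6
    rows, thermal = [], {}
    for env in config.environments:
        year = int(env.rsplit("-", 1)[0])
        sowing = datetime.date(year, 7, 1)
        day = np.arange(n_days)
        tmean = 25.0 + 3.0 * np.sin(2 * np.pi * (day + 15) / 150.0) + rng.normal(0, 0.4, n_days)
        tmean = np.round(tmean, 3)  # written precision == in-memory precision
        thermal[env] = ThermalTime(sowing, tmean, config.base_temp)
        for di in day:
            rows.append(
                {
                    "environment_id": env,
                    "date": (sowing + datetime.timedelta(days=int(di))).isoformat(),
                    "tmean_c": float(tmean[di]),
                }
            )
    return pd.DataFrame(rows), thermal


def flight_schedule(config: SimConfig) -> np.ndarray:
    days = np.linspace(config.flight_start_day, config.flight_end_day, config.flights_per_env)
    return np.unique(np.round(days).astype(int))


def simulate_trial(truth: SimTruth, config: SimConfig, rng=None,
                   thermal: dict | None = None, temp: pd.DataFrame | None = None):
    """Plot-level GF observations for every genotype x environment x block."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    if thermal is None or temp is None:
        temp, thermal = make_temperatures(config, np.random.default_rng(config.seed + 2))
    gids = list(truth.params_by_env[config.environments[0]].index)
    days = flight_schedule(config)
    rows = []
    flight_days = {}
    for env in config.environments:
        tt = thermal[env]
        gdd = tt.gdd_at(days)
        flight_days[env] = days.copy()
        year, _ = env.rsplit("-", 1)
        base = truth.params_by_env[env][list(PARAM_NAMES)].to_numpy(dtype=float)
        n_g = len(gids)
        n_plots = n_g * config.n_blocks
        jitter = np.exp(rng.normal(0.0, config.plot_jitter_sd, size=(n_plots, 5)))
        P = np.repeat(base, config.n_blocks, axis=0) * jitter
        gf_true = gf_curve_arrays(
            P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4], P[:, 4:5],
            gdd[None, :], config.k,
        )
        mean_d = gf_true.mean(axis=0)
        noise = rng.normal(0.0, 1.0, size=gf_true.shape) * (config.noise_cv * mean_d)[None, :]
        obs = np.clip(gf_true + noise, 0.0, 0.999)
        plot_meta = [
            (f"{env}_{g}_B{b + 1}", g, f"B{b + 1}")
            for g in gids
            for b in range(config.n_blocks)
        ]
        for pi, (plot_id, g, block) in enumerate(plot_meta):
            for di, d in enumerate(days):
                rows.append(
                    {
                        "plot_id": plot_id,
                        "genotype_id": g,
                        "year": int(year),
                        "treatment": env.rsplit("-", 1)[1],
                        "block": block,
                        "date": (tt.sowing_date + datetime.timedelta(days=int(d))).isoformat(),
                        "gf": float(obs[pi, di]),
                    }
                )
    pheno = pd.DataFrame(rows)
    pheno["environment_id"] = pheno["year"].astype(str) + "-" + pheno["treatment"]
    return pheno, temp, flight_days


def simulate_experiment(config: SimConfig) -> SimData:
    """Full experiment: markers, truth, temperatures, plot observations."""
    markers, _ = simulate_markers(config, np.random.default_rng(config.seed))
    truth = simulate_genetic_values(markers, config, np.random.default_rng(config.seed + 1))
    temp, thermal = make_temperatures(config, np.random.default_rng(config.seed + 2))
    pheno, temp, flight_days = simulate_trial(
        truth, config, np.random.default_rng(config.seed + 3), thermal, temp
    )
    return SimData(pheno, temp, markers, truth, thermal, flight_days)


def gf_truth_panel(sim: SimData) -> pd.DataFrame:
    """Genotype-level true GF per flight date (noise- and jitter-free curves).

    Columns are labelled ``GF|<env>|d<day>`` to match the analysis panels.
    """
    config = sim.truth.config
    blocks = []
    for env in config.environments:
        days = sim.flight_days[env]
        gdd = sim.thermal[env].gdd_at(days)
        P = sim.truth.params_by_env[env][list(PARAM_NAMES)].to_numpy(dtype=float)
        gf = gf_curve_arrays(
            P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4], P[:, 4:5],
            gdd[None, :], config.k,
        )
        cols = [f"GF|{env}|d{int(d):03d}" for d in days]
        blocks.append(pd.DataFrame(gf, index=sim.truth.params_by_env[env].index, columns=cols))
    return pd.concat(blocks, axis=1)


def plot_param_table(sim: SimData, rng=None) -> pd.DataFrame:
    """Per-plot dynamics parameters with fresh plot jitter, as a fitted-style table.

    Convenience for studies of the genetic machinery in isolation: the table
    has the same layout as the output of the curve-fitting stage, but the
    parameters come from the simulation truth plus plot-level jitter instead
    of a fit, so no optimisation cost is incurred.
    """
    config = sim.truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    rows = []
    for env in config.environments:
        base = sim.truth.params_by_env[env]
        year, treatment = env.rsplit("-", 1)
        for g in base.index:
            for b in range(config.n_blocks):
                jitter = np.exp(rng.normal(0.0, config.plot_jitter_sd, 5))
                vals = base.loc[g].to_numpy(dtype=float) * jitter
                rows.append(
                    {
                        "plot_id": f"{env}_{g}_B{b + 1}",
                        "genotype_id": g,
                        "environment_id": env,
                        "year": int(year),
                        "block": f"B{b + 1}",
                        **{p: vals[j] for j, p in enumerate(PARAM_NAMES)},
                    }
                )
    return pd.DataFrame(rows)
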