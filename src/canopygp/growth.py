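"""Thermal-time forward model of canopy green-fraction (GF) dynamics.

The canopy is described by a five-parameter leaf-area-index (LAI) curve on a
growing-degree-day (GDD) time scale,

    LAI(T) = LAI_amp * { 1 / (1 + exp(-r_g (T - T_g)))  -  exp(r_s (T - T_s)) }

i.e. logistic growth minus exponential senescence, where ``T`` is cumulative
daily mean temperature above a base temperature (8 degC for soybean).  GF, the
fraction of green pixels in a nadir plot image, is linked to LAI through
Beer-Lambert light extinction,

    GF = 1 - exp(-k * LAI),        k = 0.5 for soybean.

The curve may cross zero past ``T_s`` (``T_s`` is defined as the degree-day at
which LAI returns to zero); LAI is clamped at zero before conversion to GF
because a pixel fraction cannot be negative.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

DEFAULT_BASE_TEMP = 8.0
DEFAULT_EXTINCTION = 0.5

#: canonical ordering of the five dynamics parameters
PARAM_NAMES = ("lai_amp", "r_g", "r_s", "t_g", "t_s")

# exp() overflows past ~709; senescence exponents are clipped here so the
# curve stays finite for any degree-day value (the result is huge but finite,
# and clamped to zero anyway before GF conversion).
_EXP_CLIP = 700.0


def compute_gdd(daily_mean_temp, base_temp: float = DEFAULT_BASE_TEMP) -> np.ndarray:
    """Cumulative growing degree days from sowing.

    Parameters
    ----------
    daily_mean_temp : array-like
        Daily mean temperatures (degC), day 0 = day of sowing.
    base_temp : float
        Base temperature; daily contributions below it count as zero.

    Returns
    -------
    ndarray of the same length, non-decreasing.
    """
    temp = np.asarray(daily_mean_temp, dtype=float)
    if temp.ndim != 1 or temp.size == 0:
        raise ValueError("daily_mean_temp must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(temp)):
        raise ValueError("daily_mean_temp contains non-finite values")
    return np.cumsum(np.maximum(temp - base_temp, 0.0))


@dataclass(frozen=True)
class ThermalTime:
    """Degree-day clock of one environment, anchored at the sowing date."""

    sowing_date: datetime.date
    daily_mean_temp: np.ndarray
    base_temp: float = DEFAULT_BASE_TEMP
    gdd: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        temp = np.asarray(self.daily_mean_temp, dtype=float)
        object.__setattr__(self, "daily_mean_temp", temp)
        object.__setattr__(self, "gdd", compute_gdd(temp, self.base_temp))

    def gdd_at(self, days_after_sowing) -> np.ndarray:
        """Degree days on given days after sowing (day of sowing = index 0)."""
        idx = np.asarray(days_after_sowing, dtype=int)
        if np.any(idx < 0) or np.any(idx >= self.gdd.size):
            raise IndexError(
                "days_after_sowing outside the temperature record "
                f"(0..{self.gdd.size - 1})"
            )
        return self.gdd[idx]

    def gdd_at_date(self, date: datetime.date) -> float:
        return float(self.gdd_at((date - self.sowing_date).days))


@dataclass(frozen=True)
class DynamicsParams:
    """The five parameters of the LAI dynamics curve.

    lai_amp : maximum LAI reached (dimensionless, > 0)
    r_g     : maximum growth rate (per degree-day, > 0)
    r_s     : senescence rate (per degree-day, > 0)
    t_g     : degree-day of maximum growth rate (logistic inflection)
    t_s     : degree-day at which LAI returns to zero; must exceed t_g
    """

    lai_amp: float
    r_g: float
    r_s: float
    t_g: float
    t_s: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("dynamics parameters must all be finite")
        if self.lai_amp <= 0 or self.r_g <= 0 or self.r_s <= 0:
            raise ValueError("lai_amp, r_g and r_s must be strictly positive")
        if self.t_s <= self.t_g:
            raise ValueError("t_s must exceed t_g")

    def as_array(self) -> np.ndarray:
        return np.array([self.lai_amp, self.r_g, self.r_s, self.t_g, self.t_s])

    @classmethod
    def from_array(cls, arr) -> "DynamicsParams":
        return cls(*(float(v) for v in np.asarray(arr, dtype=float)))


@dataclass
class GFSeries:
    """Dated GF observations of one plot."""

    plot_id: str
    genotype_id: str
    environment_id: str
    block_id: str
    obs_days: np.ndarray
    obs_gdd: np.ndarray
    gf: np.ndarray

    def __post_init__(self):
        self.obs_days = np.asarray(self.obs_days, dtype=int)
        self.obs_gdd = np.asarray(self.obs_gdd, dtype=float)
        self.gf = np.asarray(self.gf, dtype=float)
        if not (self.obs_days.size == self.obs_gdd.size == self.gf.size):
            raise ValueError("obs_days, obs_gdd and gf must have equal length")
        if np.any(np.diff(self.obs_days) <= 0):
            raise ValueError("obs_days must be strictly increasing")
        if np.any((self.gf < 0) | (self.gf > 1)):
            raise ValueError("gf values must lie in [0, 1]")


def lai_to_gf(lai, k: float = DEFAULT_EXTINCTION):
    """Beer-Lambert conversion LAI -> GF = 1 - exp(-k*LAI)."""
    return -np.expm1(-k * np.asarray(lai, dtype=float))


def gf_to_lai(gf, k: float = DEFAULT_EXTINCTION):
    """Inverse conversion GF -> LAI = -log(1 - GF)/k; requires 0 <= GF < 1."""
    gf = np.asarray(gf, dtype=float)
    if np.any((gf < 0) | (gf >= 1)):
        raise ValueError("gf must lie in [0, 1) for LAI conversion")
    return -np.log1p(-gf) / k


def lai_curve_arrays(lai_amp, r_g, r_s, t_g, t_s, gdd):
    """LAI curve on raw parameter arrays (no validity checks; broadcasting).

    Used by fitting and prediction code where intermediate parameter values
    may be unconstrained; :func:`lai_curve` is the validated front door.
    """
    gdd = np.asarray(gdd, dtype=float)
    growth = expit(r_g * (gdd - t_g))
    sen = np.exp(np.minimum(r_s * (gdd - t_s), _EXP_CLIP))
    return lai_amp * (growth - sen)


def lai_curve(params: DynamicsParams, gdd):
    """Evaluate the LAI dynamics curve at the given degree days.

    May return negative values past ``t_s``; callers converting to GF clamp
    at zero first (see :func:`predict_gf_curve`).
    """
    return lai_curve_arrays(
        params.lai_amp, params.r_g, params.r_s, params.t_g, params.t_s, gdd
    )


def predict_gf_curve(params: DynamicsParams, gdd, k: float = DEFAULT_EXTINCTION):
    """GF trajectory implied by the dynamics curve; values in [0, 1)."""
    lai = np.maximum(lai_curve(params, gdd), 0.0)
    return lai_to_gf(lai, k)


def gf_curve_arrays(lai_amp, r_g, r_s, t_g, t_s, gdd, k: float = DEFAULT_EXTINCTION):
    """Unvalidated, broadcasting version of :func:`predict_gf_curve`."""
    lai = np.maximum(lai_curve_arrays(lai_amp, r_g, r_s, t_g, t_s, gdd), 0.0)
    return -np.expm1(-k * lai)
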