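"""The six growth-prediction models: GP, TGP, MGP, TMGP, TGPG, TMGPG.

* GP    -- single-trait G-BLUP of the green fraction on each flight date.
* TGP   -- two-step: G-BLUP of the five dynamics parameters, then the GF
           trajectory reconstructed from the predicted parameters.
* MGP   -- multi-trait G-BLUP of the target date's GF together with ten
           supporting variates chosen by the s(h^2)+s(|r|) criterion.
* TMGP  -- two-step with the multi-trait model over the dynamics parameters.
* TGPG / TMGPG -- the two-step models conditioned on early-season GF by
  approximate Bayesian computation: a cloud of parameter draws (asymptotic
  predictive normals around the single-trait BLUPs for TGPG; raw MCMC draws
  for TMGPG) is turned into candidate GF trajectories, the draws whose
  early-period trajectory lies closest (Euclidean distance on the GF scale)
  to the observed early GF are kept, and the prediction is the mean of the
  kept trajectories over all dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import DEFAULT_EXTINCTION, PARAM_NAMES, gf_curve_arrays
from .multitrait import ChainConfig, MultiTraitFit, fit_multitrait
from .quantgen import GblupResult, gblup

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ABCConfig:
    """Rejection-sampling settings for the growth-conditioned models."""

    n_samples: int = 60000
    n_keep: int = 60

    def __post_init__(self):
        if self.n_keep > self.n_samples:
            raise ValueError("n_keep must not exceed n_samples")


@dataclass
class TrajectoryPrediction:
    """Predicted GF per genotype per date for one environment."""

    model: str
    environment_id: str
    gf: pd.DataFrame              # genotypes x dates (columns = date labels)
    params: pd.DataFrame | None = None   # genotypes x 5 predicted parameters
    flagged: list = field(default_factory=list)  # e.g. t_s <= t_g genotypes
    kept_idx: dict | None = None  # ABC audit: genotype -> kept draw indices


def trajectory_from_params(params: pd.DataFrame, gdd, k: float = DEFAULT_EXTINCTION,
                           columns=None) -> pd.DataFrame:
    """GF trajectories for a genotype x parameter table at the given gdd."""
    gdd = np.asarray(gdd, dtype=float)
    P = params[list(PARAM_NAMES)].to_numpy(dtype=float)
    gf = gf_curve_arrays(
        P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4], P[:, 4:5], gdd[None, :], k
    )
    cols = columns if columns is not None else list(gdd)
    return pd.DataFrame(gf, index=params.index, columns=cols)


def predict_gp(panel: pd.DataFrame, grm: pd.DataFrame, target, test_ids,
               eig=None) -> GblupResult:
    """Per-date G-BLUP; training genotypes are those observed for the target."""
    return gblup(panel[target], grm, test_ids=test_ids, eig=eig)


def predict_params_gblup(param_panel: pd.DataFrame, grm: pd.DataFrame,
                         test_ids) -> dict:
    """Independent G-BLUP of each dynamics parameter; returns name -> result."""
    out = {}
    for name in PARAM_NAMES:
        out[name] = gblup(param_panel[name], grm, test_ids=test_ids)
    return out


def predict_tgp(param_panel: pd.DataFrame, grm: pd.DataFrame, test_ids, gdd,
                k: float = DEFAULT_EXTINCTION, environment_id: str = "",
                columns=None) -> TrajectoryPrediction:
    """Two-step prediction: parameter G-BLUPs -> GF trajectory.

    ``param_panel`` columns must be the five parameter names (values = per
    genotype genotypic values, NaN for unobserved/test genotypes).  Predicted
    parameter sets with t_s <= t_g are still evaluated (the clamped curve is
    defined) but flagged.
    """
    fits = predict_params_gblup(param_panel, grm, test_ids)
    params = pd.DataFrame({name: fits[name].pred for name in PARAM_NAMES})
    flagged = [g for g in params.index if params.loc[g, "t_s"] <= params.loc[g, "t_g"]]
    if flagged:
        logger.warning("TGP: %d genotypes with predicted t_s <= t_g", len(flagged))
    traj = trajectory_from_params(params, gdd, k, columns=columns)
    pred = TrajectoryPrediction("TGP", environment_id, traj, params, flagged)
    pred.gblup_fits = fits
    return pred


def predict_mgp(panel: pd.DataFrame, grm: pd.DataFrame, target, supports,
                test_ids, chain: ChainConfig | None = None):
    """Multi-trait prediction of one target variate with chosen supports."""
    if panel[target].notna().sum() == 0:
        raise ValueError(f"target variate {target!r} unobserved in training")
    sub = panel[[target] + list(supports)]
    fit = fit_multitrait(sub, grm, chain)
    return fit.predict(target, test_ids), fit


def predict_tmgp(param_panel: pd.DataFrame, grm: pd.DataFrame, test_ids, gdd,
                 k: float = DEFAULT_EXTINCTION, chain: ChainConfig | None = None,
                 support_panel: pd.DataFrame | None = None,
                 environment_id: str = "", columns=None) -> TrajectoryPrediction:
    """Two-step prediction with one joint multi-trait fit of the parameters.

    ``support_panel`` may append further variates (e.g. the same parameters
    estimated in other environments) to the joint model; only the five target
    parameters feed the trajectory.
    """
    panel = param_panel[list(PARAM_NAMES)]
    if support_panel is not None:
        panel = pd.concat([panel, support_panel], axis=1)
    fit = fit_multitrait(panel, grm, chain)
    params = pd.DataFrame(
        {name: fit.predict(name, test_ids) for name in PARAM_NAMES}
    )
    flagged = [g for g in params.index if params.loc[g, "t_s"] <= params.loc[g, "t_g"]]
    traj = trajectory_from_params(params, gdd, k, columns=columns)
    pred = TrajectoryPrediction("TMGP", environment_id, traj, params, flagged)
    pred.mt_fit = fit
    return pred


def sample_param_draws(fits: dict, test_ids, n_samples: int, rng) -> np.ndarray:
    """Asymptotic predictive draws of the five parameters from G-BLUP fits.

    Draws each parameter independently from N(pred, pred_var) per test
    genotype (the REML plug-in conditional distribution).  Returns an array
    (n_samples, n_test, 5) ordered like PARAM_NAMES.
    """
    n_test = len(test_ids)
    out = np.empty((n_samples, n_test, len(PARAM_NAMES)))
    for j, name in enumerate(PARAM_NAMES):
        fit = fits[name]
        mu = fit.pred.loc[list(test_ids)].to_numpy(dtype=float)
        sd = np.sqrt(fit.pred_var.loc[list(test_ids)].to_numpy(dtype=float))
        out[:, :, j] = mu[None, :] + sd[None, :] * rng.standard_normal((n_samples, n_test))
    return out


def abc_refine(draws: np.ndarray, early_gdd, early_gf, out_gdd, n_keep: int,
               k: float = DEFAULT_EXTINCTION):
    """Select the parameter draws whose early-season GF best matches data.

    Parameters
    ----------
    draws : (S, 5) array of parameter draws for one genotype (PARAM_NAMES order).
    early_gdd, early_gf : observed early-period degree days and GF values.
    out_gdd : degree days at which the prediction is emitted (all dates).
    n_keep : number of closest draws to retain.

    Returns ``(prediction, kept_idx, fallback)``: the mean GF trajectory of
    the kept draws over ``out_gdd``, the kept draw indices, and a flag set
    when every draw had non-finite distance (prediction then falls back to
    the mean over all draws).  Draws with non-positive rates or amplitude get
    infinite distance rather than being dropped, preserving the draw count.
    """
    draws = np.asarray(draws, dtype=float)
    early_gdd = np.asarray(early_gdd, dtype=float)
    early_gf = np.asarray(early_gf, dtype=float)
    out_gdd = np.asarray(out_gdd, dtype=float)
    if early_gdd.size == 0:
        raise ValueError("early observations are required for ABC refinement")
    if n_keep > draws.shape[0]:
        raise ValueError("n_keep exceeds the number of draws")

    all_gdd = np.concatenate([early_gdd, out_gdd])
    amp, rg, rs, tg, ts = (draws[:, j:j + 1] for j in range(5))
    gf = gf_curve_arrays(amp, rg, rs, tg, ts, all_gdd[None, :], k)
    ne = early_gdd.size
    dist = np.sqrt(np.sum((gf[:, :ne] - early_gf[None, :]) ** 2, axis=1))
    invalid = (draws[:, 0] <= 0) | (draws[:, 1] <= 0) | (draws[:, 2] <= 0)
    invalid |= ~np.all(np.isfinite(draws), axis=1) | ~np.isfinite(dist)
    dist = np.where(invalid, np.inf, dist)

    if not np.any(np.isfinite(dist)):
        logger.warning("ABC: all draw distances non-finite; using plain posterior mean")
        return gf[:, ne:].mean(axis=0), np.arange(draws.shape[0]), True

    kept = np.argsort(dist, kind="stable")[:n_keep]
    return gf[kept][:, ne:].mean(axis=0), kept, False


def abc_trajectories(draws: np.ndarray, test_ids, early_gf: pd.DataFrame,
                     early_gdd, out_gdd, n_keep: int,
                     k: float = DEFAULT_EXTINCTION, columns=None,
                     model: str = "TGPG", environment_id: str = "") -> TrajectoryPrediction:
    """Apply :func:`abc_refine` per genotype over a draw array (S, n_test, 5).

    ``early_gf`` is genotypes x early dates, aligned with ``early_gdd``.  When
    there are no early dates at all the selection degrades gracefully to the
    plain posterior-mean trajectory over all draws (no conditioning).
    """
    out_gdd = np.asarray(out_gdd, dtype=float)
    early_gdd = np.asarray(early_gdd, dtype=float)
    rows, kept_map, flagged = [], {}, []
    for i, gid in enumerate(test_ids):
        if early_gdd.size == 0:
            amp, rg, rs, tg, ts = (draws[:, i, j:j + 1] for j in range(5))
            gf = gf_curve_arrays(amp, rg, rs, tg, ts, out_gdd[None, :], k)
            rows.append(gf.mean(axis=0))
            kept_map[gid] = np.arange(draws.shape[0])
            continue
        obs = early_gf.loc[gid].to_numpy(dtype=float)
        pred, kept, fb = abc_refine(draws[:, i, :], early_gdd, obs, out_gdd, n_keep, k)
        rows.append(pred)
        kept_map[gid] = kept
        if fb:
            flagged.append(gid)
    cols = columns if columns is not None else list(out_gdd)
    gf_df = pd.DataFrame(np.vstack(rows), index=pd.Index(list(test_ids)), columns=cols)
    return TrajectoryPrediction(model, environment_id, gf_df, None, flagged, kept_map)
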