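"""Multi-trait G-BLUP by Gibbs sampling, and supporting-variate selection.

The model stacks J variates measured on the same panel of genotypes,

    g_j = m_j 1 + u_j + eps_j ,   j = 1..J,

with the joint genetic effect u_all ~ N(0, K (x) G) and residual
eps_all ~ N(0, R (x) I), where G is the genomic relationship matrix, K the
J x J genetic covariance among variates and R the J x J residual covariance.
K and R carry weakly informative inverse-Wishart priors (J+2 degrees of
freedom, 0.5*I scale on internally standardised variates); means are flat.
Variates are standardised to unit variance inside the sampler and all
outputs rescaled, so callers see the original units.  Missing cells (untested genotypes /
environments) are data-augmented each sweep, which keeps every conditional
conjugate:

* u  | K, R, m, g  -- after rotating genotypes into the eigenbasis of G the
  posterior factorises over eigencomponents into J-dimensional Gaussians,
  sampled in one batched linear-algebra pass;
* K  | u            -- inverse-Wishart with scale Psi0 + u^T G^{-1} u;
* R  | residuals    -- inverse-Wishart with scale Psi0 + E^T E;
* m  | u, R, g      -- Gaussian, R/n covariance;
* g_missing | rest  -- Gaussian conditional of the residual rows.

The supporting-variate criterion ranks candidate variates by
``s(h^2) + s(|r|)`` where ``s`` standardises a vector to zero mean and unit
variance over the candidate set, ``h^2`` is the variate's genomic
heritability and ``r`` its correlation with the target over training
genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

logger = logging.getLogger(__name__)

_JITTER = 1e-8


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings; retained draws = (iterations - burn_in) / thin."""

    iterations: int = 15000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class MultiTraitFit:
    variates: list
    genotype_ids: list
    K_hat: np.ndarray
    R_hat: np.ndarray
    m_hat: np.ndarray
    u_mean: np.ndarray            # n x J posterior mean of genetic effects
    u_draws: np.ndarray           # S x n x J retained draws
    m_draws: np.ndarray           # S x J
    chain: ChainConfig

    def _vix(self, variate) -> int:
        return self.variates.index(variate)

    def _gix(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return np.array([lookup[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"unknown genotype {exc.args[0]!r}") from exc

    def predict(self, variate, ids) -> pd.Series:
        """Posterior-mean genotypic value m_j + u for the given genotypes."""
        j = self._vix(variate)
        gi = self._gix(ids)
        vals = self.m_hat[j] + self.u_mean[gi, j]
        return pd.Series(vals, index=pd.Index(list(ids)))

    def draws(self, variate, ids) -> np.ndarray:
        """Retained draws of m_j + u_ij, shape (S, len(ids))."""
        j = self._vix(variate)
        gi = self._gix(ids)
        return self.m_draws[:, j][:, None] + self.u_draws[:, gi, j]

    def param_draws(self, ids, variates=None) -> np.ndarray:
        """Draws of genotypic values for several variates, (S, n_ids, J')."""
        variates = list(variates) if variates is not None else self.variates
        cols = [self._vix(v) for v in variates]
        gi = self._gix(ids)
        return self.m_draws[:, cols][:, None, :] + self.u_draws[:, gi][:, :, cols]


def _draw_invwishart(df, scale, rng):
    scale = (scale + scale.T) / 2.0
    try:
        return np.atleast_2d(invwishart.rvs(df=df, scale=scale, random_state=rng))
    except np.linalg.LinAlgError:
        logger.debug("non-PD scale in inverse-Wishart update; adding jitter")
        eps = _JITTER * max(float(np.trace(scale)) / scale.shape[0], 1e-30)
        scale = scale + eps * np.eye(scale.shape[0])
        return np.atleast_2d(invwishart.rvs(df=df, scale=scale, random_state=rng))


def _safe_inv(A):
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.inv(A + _JITTER * np.eye(A.shape[0]))


def fit_multitrait(
    panel: pd.DataFrame,
    grm: pd.DataFrame,
    chain: ChainConfig | None = None,
    prior_df: int | None = None,
    prior_scale: float = 0.5,
) -> MultiTraitFit:
    """Fit the K (x) G multi-trait model to a genotype x variate panel.

    ``panel`` rows are genotypes (all must appear in ``grm``), columns are
    variates; NaN marks unobserved cells, which are imputed by data
    augmentation so the corresponding genotypes still receive genetic-effect
    draws.  Every variate needs at least one observed value.
    """
    chain = chain or ChainConfig()
    variates = list(panel.columns)
    J = len(variates)
    gids = list(panel.index)
    n = len(gids)
    if panel.notna().sum(axis=0).min() == 0:
        raise ValueError("every variate needs at least one observed value")

    G = grm.loc[gids, gids].to_numpy(dtype=float)
    d, U = np.linalg.eigh((G + G.T) / 2.0)
    d = np.maximum(d, _JITTER * max(d.max(), 1.0))

    # variates are standardised internally (an amplitude and a rate per
    # degree-day differ by orders of magnitude; the covariance updates would
    # otherwise be hopelessly ill-conditioned) and results rescaled on exit
    Y_raw = panel.to_numpy(dtype=float)
    mask = np.isnan(Y_raw)
    col_sd = np.sqrt(np.nanvar(Y_raw, axis=0))
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    Y = Y_raw / col_sd
    col_mean = np.nanmean(Y, axis=0)
    g_cur = np.where(mask, col_mean, Y)

    nu0 = prior_df if prior_df is not None else J + 2
    Psi0 = prior_scale * np.eye(J)
    K = 0.5 * np.eye(J)
    R = 0.5 * np.eye(J)
    m = col_mean.copy()
    u = np.zeros((n, J))

    # group missing rows by pattern so imputation is one vector op per pattern
    patterns = {}
    for i in range(n):
        key = tuple(np.flatnonzero(mask[i]))
        if key:
            patterns.setdefault(key, []).append(i)
    patterns = {k: np.array(v) for k, v in patterns.items()}

    rng = np.random.default_rng(chain.seed)
    S = chain.n_retained
    u_draws = np.empty((S, n, J))
    m_draws = np.empty((S, J))
    K_sum = np.zeros((J, J))
    R_sum = np.zeros((J, J))
    s_out = 0

    for it in range(1, chain.iterations + 1):
        Kinv = _safe_inv(K)
        Rinv = _safe_inv(R)

        # --- genetic effects, batched over eigencomponents of G
        rt = U.T @ (g_cur - m)                       # n x J
        P = Rinv[None, :, :] + Kinv[None, :, :] / d[:, None, None]
        rhs = rt @ Rinv
        mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(P)
        z = rng.standard_normal((n, J))
        ut = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
        u = U @ ut

        # --- genetic covariance K | u
        Su = ut.T @ (ut / d[:, None])
        K = _draw_invwishart(nu0 + n, Psi0 + Su, rng)

        # --- residual covariance R | residuals
        eps = g_cur - m - u
        R = _draw_invwishart(nu0 + n, Psi0 + eps.T @ eps, rng)

        # --- means m | u, R
        m = (g_cur - u).mean(axis=0) + np.linalg.cholesky(R / n) @ rng.standard_normal(J)

        # --- impute missing cells from the residual conditional
        for mis_key, rows in patterns.items():
            mis = np.array(mis_key)
            obs = np.setdiff1d(np.arange(J), mis)
            z2 = rng.standard_normal((rows.size, mis.size))
            if obs.size == 0:
                cov = R
                eps_mis = z2 @ np.linalg.cholesky(cov).T
            else:
                C = np.linalg.solve(R[np.ix_(obs, obs)], R[np.ix_(obs, mis)]).T
                eps_obs = g_cur[np.ix_(rows, obs)] - m[obs] - u[np.ix_(rows, obs)]
                cov = R[np.ix_(mis, mis)] - C @ R[np.ix_(obs, mis)]
                eps = _JITTER * max(float(np.trace(cov)) / mis.size, 1e-30)
                cov = (cov + cov.T) / 2.0 + eps * np.eye(mis.size)
                eps_mis = eps_obs @ C.T + z2 @ np.linalg.cholesky(cov).T
            g_cur[np.ix_(rows, mis)] = m[mis] + u[np.ix_(rows, mis)] + eps_mis

        if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and s_out < S:
            u_draws[s_out] = u
            m_draws[s_out] = m
            K_sum += K
            R_sum += R
            s_out += 1

    scale = np.asarray(col_sd)
    u_draws *= scale[None, None, :]
    m_draws *= scale[None, :]
    return MultiTraitFit(
        variates=variates,
        genotype_ids=gids,
        K_hat=(K_sum / S) * np.outer(scale, scale),
        R_hat=(R_sum / S) * np.outer(scale, scale),
        m_hat=m_draws.mean(axis=0),
        u_mean=u_draws.mean(axis=0),
        u_draws=u_draws,
        m_draws=m_draws,
        chain=chain,
    )


def predict_from_fit(fit: MultiTraitFit, target, test_ids):
    """Point predictions (posterior means) and raw draws for a target variate."""
    return fit.predict(target, test_ids), fit.draws(target, test_ids)


def _scale(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def select_supporting_variates(
    h2: pd.Series, r_with_target: pd.Series, n_select: int
) -> list:
    """Rank candidate variates by s(h^2) + s(|r|) and return the top n.

    Both inputs are indexed by candidate variate; the candidate set must
    already exclude the target itself (and, under environment-held-out
    cross-validation, variates from the held-out environment).  Ties break on
    higher h^2 then lexicographic label.  If there are fewer candidates than
    requested, all are returned (with a warning).
    """
    if not h2.index.equals(r_with_target.index):
        r_with_target = r_with_target.reindex(h2.index)
    score = _scale(h2.to_numpy(float)) + _scale(np.abs(r_with_target.to_numpy(float)))
    table = pd.DataFrame(
        {
            "label": [str(v) for v in h2.index],
            "variate": list(h2.index),
            "score": score,
            "h2": h2.to_numpy(float),
        }
    )
    table = table.sort_values(
        ["score", "h2", "label"], ascending=[False, False, True], kind="stable"
    )
    if n_select > len(table):
        logger.warning("only %d candidates for %d requested supports", len(table), n_select)
        n_select = len(table)
    return list(table["variate"].iloc[:n_select])
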