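"""Marker QC, genomic relationship matrix, and single-trait mixed models.

Genotypic values are extracted from replicated plot phenotypes with

    y = mu*1 + L*beta + W*s + e,    s ~ N(0, sigma_s^2 I),  e ~ N(0, sigma_e^2 I)

(block effects beta fixed, genotype effects s random), and the genotypic value
of a line is g = mu + BLUP(s).

Genetic signal in g is then modelled with G-BLUP,

    g = m*1 + Z*u + eps,   u ~ N(0, sigma_u^2 G),  eps ~ N(0, sigma_e^2 I)

where G = X X^T / c is built from centred and scaled marker codes
(-1 ref-hom / 0 het / +1 alt-hom) with c = trace(X X^T)/n so that the mean
diagonal equals one; genomic heritability is h^2 = sigma_u^2 /
(sigma_u^2 + sigma_e^2).

All variance components are exact REML estimates obtained by a spectral
decomposition of the covariance kernel: after rotating into the kernel's
eigenbasis the restricted likelihood is a smooth function of the single ratio
lambda = sigma_e^2 / sigma_u^2, which is profiled on a log scale.  This is the
classic eigendecomposition trick for one-random-effect models and involves no
iterative convergence risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: bounds of the profiled variance ratio lambda = sigma_e^2/sigma_u^2
LAMBDA_BOUNDS = (1e-5, 1e5)


# ---------------------------------------------------------------------------
# marker QC and GRM
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_failed_missing: int
    n_failed_maf: int
    n_pruned_ld: int
    n_kept: int


def qc_and_impute(
    codes: pd.DataFrame,
    maf: float = 0.025,
    max_missing: float = 0.05,
    ld_r2: float = 0.95,
    window: int = 50,
    step: int = 5,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter biallelic marker codes and mean-impute what remains.

    ``codes`` is genotypes x markers with entries in {-1, 0, 1} and NaN for
    missing calls.  Markers failing missing-rate (< ``max_missing``) or MAF
    (>= ``maf``) are dropped; remaining markers are greedily LD-pruned in
    sliding windows (``window`` markers, advancing by ``step``), removing the
    later marker of any pair with r^2 >= ``ld_r2``.  Missing codes are then
    replaced by the marker mean.
    """
    X = codes.to_numpy(dtype=float)
    n, m = X.shape
    miss = np.isnan(X)
    miss_rate = miss.mean(axis=0)
    keep_missing = miss_rate < max_missing

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        colmean = np.nanmean(np.where(keep_missing, X, np.nan), axis=0)
    # allele frequency of the alt allele under -1/0/1 coding
    p_alt = (colmean + 1.0) / 2.0
    maf_col = np.minimum(p_alt, 1.0 - p_alt)
    keep = keep_missing & (maf_col >= maf)
    n_failed_missing = int((~keep_missing).sum())
    n_failed_maf = int((keep_missing & ~keep).sum())

    kept_idx = np.flatnonzero(keep)
    Xk = X[:, kept_idx]
    # mean-impute before LD so correlations are defined on complete columns
    mu = np.nanmean(Xk, axis=0)
    Xi = np.where(np.isnan(Xk), mu, Xk)

    alive = np.ones(Xi.shape[1], dtype=bool)
    sd = Xi.std(axis=0)
    start = 0
    while start < Xi.shape[1]:
        win = [j for j in range(start, min(start + window, Xi.shape[1])) if alive[j] and sd[j] > 0]
        for a_pos in range(len(win)):
            ja = win[a_pos]
            if not alive[ja]:
                continue
            xa = Xi[:, ja] - Xi[:, ja].mean()
            for jb in win[a_pos + 1:]:
                if not alive[jb]:
                    continue
                xb = Xi[:, jb] - Xi[:, jb].mean()
                denom = np.sqrt((xa @ xa) * (xb @ xb))
                if denom == 0:
                    continue
                r2 = (xa @ xb) ** 2 / denom**2
                if r2 >= ld_r2:
                    alive[jb] = False
        start += step
    n_pruned = int((~alive).sum())

    final_idx = kept_idx[alive]
    out = pd.DataFrame(
        Xi[:, alive], index=codes.index, columns=codes.columns[final_idx]
    )
    report = QCReport(m, n_failed_missing, n_failed_maf, n_pruned, out.shape[1])
    if out.shape[1] == 0:
        raise ValueError("no markers survive QC")
    return out, report


def compute_grm(markers: pd.DataFrame) -> pd.DataFrame:
    """Genomic relationship matrix G = X X^T / c from coded markers.

    Columns are centred and scaled to unit variance; zero-variance columns are
    excluded (with a warning).  The normalisation constant c = trace(X X^T)/n
    makes the mean diagonal equal one, putting heritabilities on the usual
    scale.
    """
    M = markers.to_numpy(dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 1:
        raise ValueError("need at least 2 genotypes and 1 marker")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance markers from GRM")
        M = M[:, sd > 0]
        sd = sd[sd > 0]
        if M.shape[1] == 0:
            raise ValueError("all markers have zero variance")
    X = (M - M.mean(axis=0)) / sd
    XXt = X @ X.T
    c = np.trace(XXt) / X.shape[0]
    G = XXt / c
    G = (G + G.T) / 2.0
    return pd.DataFrame(G, index=markers.index, columns=markers.index)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)


@dataclass
class _EigenKernel:
    """Cached eigendecomposition of a covariance kernel over fixed ids."""

    ids: tuple
    d: np.ndarray
    U: np.ndarray


def kernel_eigen(K: np.ndarray, ids=None) -> _EigenKernel:
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.maximum(d, 0.0)
    return _EigenKernel(tuple(ids) if ids is not None else None, d, U)


def _reml_profile(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled REML over lambda for rotated data (kernel eigenbasis)."""
    n, p = Xt.shape

    def neg2_reml(log_lam):
        lam = np.exp(log_lam)
        w = d + lam
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        q = float(r @ (r / w))
        q = max(q, 1e-300)
        return (n - p) * np.log(q) + float(np.log(w).sum()) + logdet_xwx

    res = minimize_scalar(
        neg2_reml,
        bounds=(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    w = d + lam
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_u = float(r @ (r / w)) / (n - p)
    sigma2_e = lam * sigma2_u
    return lam, beta, VarianceComponents(sigma2_u, sigma2_e)


def reml_mixed(y: np.ndarray, X: np.ndarray, eig: _EigenKernel):
    """Exact REML fit of y = X beta + u + e with u ~ N(0, sigma_u^2 K).

    Returns (beta, vc, u_hat, lam) where u_hat is the BLUP of u.
    """
    yt = eig.U.T @ y
    Xt = eig.U.T @ X
    lam, beta, vc = _reml_profile(yt, Xt, eig.d)
    r = yt - Xt @ beta
    u_hat = eig.U @ (eig.d / (eig.d + lam) * r)
    return beta, vc, u_hat, lam


# ---------------------------------------------------------------------------
# genotypic values from replicated plots
# ---------------------------------------------------------------------------

@dataclass
class GenotypicValues:
    """Per-genotype values g = mu + BLUP(s) with the stage's variance parts."""

    g: pd.Series
    mu: float
    sigma2_s: float | None
    sigma2_e: float | None
    fallback_means: bool = False


def estimate_genotypic_values(
    plots: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype_id",
    block_col: str = "block",
) -> GenotypicValues:
    """Genotypic values from plot records via the block + genotype mixed model.

    Block effects are fixed (coded sum-to-zero so the intercept is the general
    mean); genotype effects are random.  Without any replication the genotypic
    variance is unidentifiable and the function falls back to plot means,
    flagged on the result.
    """
    df = plots.dropna(subset=[value_col])
    y = df[value_col].to_numpy(dtype=float)
    genos = df[genotype_col].astype(str)
    counts = genos.value_counts()
    geno_levels = sorted(counts.index)

    if counts.max() <= 1:
        logger.warning("no replication: returning plot means as genotypic values")
        means = df.groupby(genos)[value_col].mean().reindex(geno_levels)
        return GenotypicValues(means, float(y.mean()), None, None, fallback_means=True)

    W = pd.get_dummies(pd.Categorical(genos, categories=geno_levels)).to_numpy(dtype=float)
    blocks = df[block_col].astype(str)
    block_levels = sorted(blocks.unique())
    if len(block_levels) > 1:
        B = pd.get_dummies(pd.Categorical(blocks, categories=block_levels)).to_numpy(dtype=float)
        B = B[:, 1:] - B[:, 1:].mean(axis=0)  # drop-one, centred: intercept = mean
        X = np.column_stack([np.ones(len(y)), B])
    else:
        X = np.ones((len(y), 1))

    eig = kernel_eigen(W @ W.T)
    beta, vc, u_hat, lam = reml_mixed(y, X, eig)
    # genotype-level BLUP: s = sigma_s^2 W^T V^{-1} (y - X beta)
    r = y - X @ beta
    Vinv_r = eig.U @ ((eig.U.T @ r) / (eig.d + lam))
    s_hat = W.T @ Vinv_r
    mu = float(beta[0])
    g = pd.Series(mu + s_hat, index=pd.Index(geno_levels, name=genotype_col))
    return GenotypicValues(g, mu, vc.sigma2_u, vc.sigma2_e)


# ---------------------------------------------------------------------------
# G-BLUP
# ---------------------------------------------------------------------------

@dataclass
class GblupResult:
    mean: float
    vc: VarianceComponents
    u_train: pd.Series
    u_test: pd.Series
    pred: pd.Series       # mean + u_test, genotypic-value scale
    pred_var: pd.Series   # predictive variance of u_test (REML plug-in)

    @property
    def h2(self) -> float:
        return self.vc.h2


def gblup(
    g: pd.Series,
    grm: pd.DataFrame,
    train_ids=None,
    test_ids=(),
    eig: _EigenKernel | None = None,
) -> GblupResult:
    """Single-trait G-BLUP with exact REML variance components.

    ``g`` holds genotypic values indexed by genotype (NaN allowed); training
    defaults to its non-missing ids.  Test predictions are the conditional
    mean  G_te,tr (G_tr + lambda I)^{-1} (g_tr - m),  reported on the
    genotypic-value scale (mean added back), with the REML plug-in conditional
    variance for each test genotype.

    A precomputed eigendecomposition of the training-block GRM (``eig``) can
    be supplied when many variates share one training set.
    """
    if train_ids is None:
        train_ids = [i for i in g.index if np.isfinite(g.get(i, np.nan))]
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    if not train_ids:
        raise ValueError("training set is empty")
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test ids must be disjoint")
    missing = [i for i in train_ids + test_ids if i not in grm.index]
    if missing:
        raise KeyError(f"genotypes not in GRM: {missing[:5]}")

    y = g.loc[train_ids].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("training values contain NaN")
    G_rr = grm.loc[train_ids, train_ids].to_numpy(dtype=float)
    if eig is None:
        eig = kernel_eigen(G_rr, ids=train_ids)
    elif eig.ids != tuple(train_ids):
        raise ValueError("cached eigendecomposition does not match train_ids")

    X = np.ones((len(y), 1))
    beta, vc, u_hat, lam = reml_mixed(y, X, eig)
    m = float(beta[0])
    r = y - m
    alpha = eig.U @ ((eig.U.T @ r) / (eig.d + lam))  # (G_rr + lam I)^{-1} r
    u_train = pd.Series(u_hat, index=pd.Index(train_ids))

    if test_ids:
        G_tr = grm.loc[test_ids, train_ids].to_numpy(dtype=float)
        u_test_vals = G_tr @ alpha
        Bt = eig.U.T @ G_tr.T  # n_train x n_test
        quad = np.sum(Bt**2 / (eig.d + lam)[:, None], axis=0)
        g_tt = np.diag(grm.loc[test_ids, test_ids].to_numpy(dtype=float))
        var = vc.sigma2_u * np.maximum(g_tt - quad, 0.0)
    else:
        u_test_vals = np.array([])
        var = np.array([])
    u_test = pd.Series(u_test_vals, index=pd.Index(test_ids))
    return GblupResult(
        mean=m,
        vc=vc,
        u_train=u_train,
        u_test=u_test,
        pred=m + u_test,
        pred_var=pd.Series(var, index=pd.Index(test_ids)),
    )


def accuracy(g_true, u_pred) -> float:
    """Pearson correlation between genotypic values and predictions."""
    a = np.asarray(g_true, dtype=float)
    b = np.asarray(u_pred, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("accuracy undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])
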