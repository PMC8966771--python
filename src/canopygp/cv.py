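"""Cross-validation designs for growth prediction, and accuracy reporting.

Three designs probe different breeding questions:

* **CV1** -- untested genotypes: a fold of genotypes is removed from every
  environment's training data and predicted everywhere.
* **CV2** -- untested genotype x environment combinations: genotype folds and
  leave-one-environment-out run simultaneously; only the test genotypes' data
  *in the held-out environment* are removed, so multi-trait models can borrow
  the same genotypes' records from other environments.
* **CV3** -- future growth: like CV2, but the test genotypes' early-season GF
  in the target environment is kept in the training data and accuracy is
  scored on the late-season dates only.  The growth cycle is split so both
  periods hold an equal number of flights (the extra flight of an odd count
  goes to the early period).

Accuracy is the Pearson correlation between genotypic values and predictions
over the test genotypes, per environment x date, and model comparisons are
reported as ratio improvements (mean_A / mean_B - 1) x 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import PARAM_NAMES
from .multitrait import ChainConfig, select_supporting_variates
from .quantgen import accuracy, estimate_genotypic_values, gblup, kernel_eigen
from .schemes import (
    ABCConfig,
    abc_trajectories,
    predict_mgp,
    predict_tgp,
    predict_tmgp,
    sample_param_draws,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# plans and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    scheme: str = "CV1"
    n_folds: int = 10
    repeats: int = 3
    seed: int = 0
    #: evaluate only the first ``max_folds`` folds (None = all); a deliberate
    #: scale-down for expensive model stacks -- each fold is still a valid
    #: random test set, but genotypes are then no longer each tested once
    max_folds: int | None = None

    def __post_init__(self):
        if self.scheme not in {"CV1", "CV2", "CV3"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def select_folds(self, folds: list) -> list:
        return folds if self.max_folds is None else folds[: self.max_folds]


def make_folds(genotype_ids, n_folds: int, seed: int) -> list:
    """Balanced random partition of genotypes; fold sizes differ by <= 1."""
    ids = list(genotype_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(ids):
        raise ValueError("more folds than genotypes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [sorted(ids[i] for i in chunk) for chunk in np.array_split(perm, n_folds)]


# ---------------------------------------------------------------------------
# experiment data container
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """Genotypic-value panel plus the metadata the models need.

    ``panel``: genotype x variate genotypic values (NaN where a genotype was
    absent from an environment).  ``var_meta`` rows describe each variate:
    ``variate, kind ('gf'|'param'), environment_id, day, gdd, param``.
    """

    panel: pd.DataFrame
    var_meta: pd.DataFrame
    grm: pd.DataFrame
    k: float = 0.5

    def environments(self) -> list:
        return sorted(self.var_meta["environment_id"].unique())

    def gf_variates(self, env) -> list:
        rows = self.var_meta[
            (self.var_meta["kind"] == "gf") & (self.var_meta["environment_id"] == env)
        ].sort_values("day")
        return list(rows["variate"])

    def param_variate(self, env, param) -> str:
        return f"{param}|{env}"

    def param_panel(self, env, panel=None) -> pd.DataFrame:
        panel = panel if panel is not None else self.panel
        cols = {p: self.param_variate(env, p) for p in PARAM_NAMES}
        out = panel[[cols[p] for p in PARAM_NAMES]].copy()
        out.columns = list(PARAM_NAMES)
        return out

    def env_variates(self, env) -> list:
        return list(self.var_meta.loc[self.var_meta["environment_id"] == env, "variate"])

    def gdd_for(self, variates) -> np.ndarray:
        meta = self.var_meta.set_index("variate")
        return meta.loc[list(variates), "gdd"].to_numpy(dtype=float)

    def split_early_late(self, env) -> tuple[list, list]:
        """Equal-count early/late flight split; odd counts favour early."""
        gf = self.gf_variates(env)
        n_early = (len(gf) + 1) // 2
        return gf[:n_early], gf[n_early:]


def build_panel(
    pheno: pd.DataFrame,
    param_table: pd.DataFrame | None,
    grm: pd.DataFrame,
    thermal: dict,
    k: float = 0.5,
) -> ExperimentData:
    """Assemble the genotype x variate panel of genotypic values.

    GF genotypic values are estimated per environment x flight date from the
    plot observations; dynamics-parameter genotypic values per environment
    from the per-plot parameter table (fitted or simulated).  ``thermal`` maps
    environment id -> :class:`~canopygp.growth.ThermalTime` and provides the
    degree-day stamp of each flight.
    """
    columns, meta_rows = {}, []
    pheno = pheno.copy()
    pheno["date"] = pd.to_datetime(pheno["date"]).dt.date
    for env, obs_env in pheno.groupby("environment_id", sort=True):
        tt = thermal[env]
        for date, obs in obs_env.groupby("date", sort=True):
            day = (date - tt.sowing_date).days
            name = f"GF|{env}|d{day:03d}"
            gv = estimate_genotypic_values(obs, value_col="gf")
            columns[name] = gv.g
            meta_rows.append(
                {
                    "variate": name, "kind": "gf", "environment_id": env,
                    "day": day, "gdd": float(tt.gdd_at(day)), "param": None,
                }
            )
    if param_table is not None:
        for env, rows in param_table.groupby("environment_id", sort=True):
            for p in PARAM_NAMES:
                name = f"{p}|{env}"
                gv = estimate_genotypic_values(rows, value_col=p)
                columns[name] = gv.g
                meta_rows.append(
                    {
                        "variate": name, "kind": "param", "environment_id": env,
                        "day": None, "gdd": None, "param": p,
                    }
                )
    panel = pd.DataFrame(columns).reindex(grm.index)
    return ExperimentData(panel, pd.DataFrame(meta_rows), grm, k)


# ---------------------------------------------------------------------------
# masking and leakage audit
# ---------------------------------------------------------------------------

def mask_panel(panel: pd.DataFrame, test_ids, variates=None) -> pd.DataFrame:
    masked = panel.copy()
    cols = list(variates) if variates is not None else list(panel.columns)
    masked.loc[list(test_ids), cols] = np.nan
    return masked


def assert_no_leakage(masked: pd.DataFrame, test_ids, variates) -> None:
    """Audit that no held-out (genotype, variate) value survives masking."""
    block = masked.loc[list(test_ids), list(variates)]
    if block.notna().any().any():
        bad = block.notna().stack()
        raise AssertionError(f"leakage: {bad[bad].index.tolist()[:5]} present in training panel")


# ---------------------------------------------------------------------------
# prediction models
# ---------------------------------------------------------------------------

class _EigenCache:
    def __init__(self, grm):
        self.grm = grm
        self._cache = {}

    def get(self, train_ids):
        key = tuple(train_ids)
        if key not in self._cache:
            self._cache[key] = kernel_eigen(
                self.grm.loc[list(key), list(key)].to_numpy(dtype=float), ids=key
            )
        return self._cache[key]


class Model:
    """Interface: predict the target GF variates of one environment."""

    name = "model"

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        raise NotImplementedError


class OracleModel(Model):
    """Returns the true genotypic values; accuracy 1 by construction."""

    name = "oracle"

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        return data.panel.loc[list(test_ids), list(target_vars)]


class ConstantModel(Model):
    """Predicts a constant; accuracy is undefined (zero variance)."""

    name = "constant"

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        return pd.DataFrame(
            0.0, index=pd.Index(list(test_ids)), columns=list(target_vars)
        )


class GPModel(Model):
    """Per-date single-trait G-BLUP of the green fraction."""

    name = "GP"

    def __init__(self):
        self._eigen = None

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        if self._eigen is None or self._eigen.grm is not data.grm:
            self._eigen = _EigenCache(data.grm)
        out = {}
        for var in target_vars:
            col = masked[var]
            train = list(col.index[np.isfinite(col)])
            if not train:
                logger.warning("GP: variate %s has no training data; skipped", var)
                continue
            res = gblup(masked[var], data.grm, train_ids=train,
                        test_ids=list(test_ids), eig=self._eigen.get(train))
            out[var] = res.pred
        return pd.DataFrame(out)


class MGPModel(Model):
    """Multi-trait G-BLUP with criterion-selected supporting variates."""

    name = "MGP"

    def __init__(self, chain: ChainConfig | None = None, n_supports: int = 10,
                 n_forced_cv3: int = 3):
        self.chain = chain or ChainConfig()
        self.n_supports = n_supports
        self.n_forced_cv3 = n_forced_cv3
        self._eigen = None

    def _candidates(self, data, env, target, scheme):
        all_vars = list(data.panel.columns)
        if scheme == "CV1":
            return [v for v in all_vars if v != target]
        # held-out environment variates are never support candidates
        env_vars = set(data.env_variates(env))
        return [v for v in all_vars if v != target and v not in env_vars]

    def _score_inputs(self, data, masked, candidates, target):
        if self._eigen is None or self._eigen.grm is not data.grm:
            self._eigen = _EigenCache(data.grm)
        h2, r = {}, {}
        target_obs = masked[target]
        for var in candidates:
            col = masked[var]
            train = col.index[np.isfinite(col)]
            if len(train) < 3:
                continue
            res = gblup(col, data.grm, train_ids=list(train),
                        eig=self._eigen.get(tuple(train)))
            h2[var] = res.h2
            both = col.index[np.isfinite(col) & np.isfinite(target_obs)]
            if len(both) >= 3 and col.loc[both].std() > 0 and target_obs.loc[both].std() > 0:
                r[var] = float(np.corrcoef(col.loc[both], target_obs.loc[both])[0, 1])
            else:
                r[var] = 0.0
        idx = pd.Index(sorted(h2))
        return pd.Series(h2).reindex(idx), pd.Series(r).reindex(idx)

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        out = {}
        for target in target_vars:
            candidates = self._candidates(data, env, target, scheme)
            forced = []
            if scheme == "CV3":
                early, _ = data.split_early_late(env)
                forced = early[-self.n_forced_cv3:]
                candidates = [v for v in candidates if v not in forced]
            n_pick = self.n_supports - len(forced)
            h2, r = self._score_inputs(data, masked, candidates, target)
            supports = select_supporting_variates(h2, r, n_pick) + forced
            pred, _ = predict_mgp(masked, data.grm, target, supports,
                                  list(test_ids), self.chain)
            out[target] = pred
        return pd.DataFrame(out)


class TGPModel(Model):
    """Two-step: per-parameter G-BLUP, then trajectory reconstruction."""

    name = "TGP"

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        pp = data.param_panel(env, masked)
        pred = predict_tgp(pp, data.grm, list(test_ids),
                           data.gdd_for(target_vars), data.k,
                           environment_id=env, columns=list(target_vars))
        return pred.gf


class TMGPModel(Model):
    """Two-step with a joint multi-trait fit of the dynamics parameters.

    Under CV2/CV3 the same parameters from the non-target environments join
    the model as supporting variates: the test genotypes carry observations
    there, which is what lets the multi-trait model transfer information into
    the held-out environment.
    """

    name = "TMGP"

    def __init__(self, chain: ChainConfig | None = None, use_other_envs: bool = True):
        self.chain = chain or ChainConfig()
        self.use_other_envs = use_other_envs

    def _support_panel(self, data, masked, env, scheme):
        if scheme == "CV1" or not self.use_other_envs:
            return None
        others = [e for e in data.environments() if e != env]
        cols = [data.param_variate(e, p) for e in others for p in PARAM_NAMES
                if data.param_variate(e, p) in masked.columns]
        return masked[cols] if cols else None

    def fit_env(self, data, masked, env, target_vars, test_ids, scheme):
        pp = data.param_panel(env, masked)
        return predict_tmgp(
            pp, data.grm, list(test_ids), data.gdd_for(target_vars), data.k,
            chain=self.chain,
            support_panel=self._support_panel(data, masked, env, scheme),
            environment_id=env, columns=list(target_vars),
        )

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        return self.fit_env(data, masked, env, target_vars, test_ids, scheme).gf


class TGPGModel(Model):
    """TGP refined by ABC on the early-season GF (CV3).

    Parameter draws come from the asymptotic predictive normal around each
    single-trait BLUP.  Outside CV3 (no early observations) the selection
    degrades gracefully to the mean over all draws.
    """

    name = "TGPG"

    def __init__(self, abc: ABCConfig | None = None):
        self.abc = abc or ABCConfig()

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        pp = data.param_panel(env, masked)
        from .schemes import predict_params_gblup

        fits = predict_params_gblup(pp, data.grm, list(test_ids))
        draws = sample_param_draws(fits, list(test_ids), self.abc.n_samples, rng)
        early_vars, early_gdd, early_gf = _early_context(data, masked, env,
                                                         test_ids, scheme)
        pred = abc_trajectories(
            draws, list(test_ids), early_gf, early_gdd,
            data.gdd_for(target_vars), self.abc.n_keep, data.k,
            columns=list(target_vars), model=self.name, environment_id=env,
        )
        return pred.gf


class TMGPGModel(Model):
    """TMGP refined by ABC; the draw cloud is the raw MCMC sample."""

    name = "TMGPG"

    def __init__(self, chain: ChainConfig | None = None,
                 abc: ABCConfig | None = None, use_other_envs: bool = True):
        self.tmgp = TMGPModel(chain, use_other_envs)
        self.abc = abc or ABCConfig()

    def predict_env(self, data, masked, env, target_vars, test_ids, rng, scheme):
        fit = self.tmgp.fit_env(data, masked, env, target_vars, test_ids, scheme).mt_fit
        draws = fit.param_draws(list(test_ids), list(PARAM_NAMES))
        n_use = min(self.abc.n_samples, draws.shape[0])
        draws = draws[:n_use]
        early_vars, early_gdd, early_gf = _early_context(data, masked, env,
                                                         test_ids, scheme)
        n_keep = min(self.abc.n_keep, n_use)
        pred = abc_trajectories(
            draws, list(test_ids), early_gf, early_gdd,
            data.gdd_for(target_vars), n_keep, data.k,
            columns=list(target_vars), model=self.name, environment_id=env,
        )
        return pred.gf


def _early_context(data, masked, env, test_ids, scheme):
    """Early-season conditioning data for the growth-conditioned models."""
    if scheme != "CV3":
        return [], np.array([]), None
    early, _ = data.split_early_late(env)
    early_gf = masked.loc[list(test_ids), early]
    keep = [v for v in early if early_gf[v].notna().all()]
    return keep, data.gdd_for(keep), early_gf[keep]


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def _score(data, preds: pd.DataFrame, target_vars, test_ids, base_row: dict) -> list:
    rows = []
    meta = data.var_meta.set_index("variate")
    for var in target_vars:
        row = dict(base_row)
        row.update(
            variate=var, day=meta.at[var, "day"], n_test=len(test_ids),
            accuracy=np.nan, note="",
        )
        if var not in preds.columns:
            row["note"] = "not_predicted"
            rows.append(row)
            continue
        truth = data.panel.loc[list(test_ids), var]
        pred = preds.loc[list(test_ids), var]
        ok = truth.notna() & pred.notna()
        try:
            row["accuracy"] = accuracy(truth[ok], pred[ok])
        except ValueError as exc:
            row["note"] = f"undefined: {exc}"
        row["n_test"] = int(ok.sum())
        rows.append(row)
    return rows


def _seeded_rng(plan, repeat, fold):
    return np.random.default_rng((plan.seed, repeat, fold))


def run_cv1(data: ExperimentData, models, plan: CVPlan) -> pd.DataFrame:
    """Untested-genotype cross-validation over every environment and date."""
    rows = []
    gids = list(data.panel.index)
    for rep in range(plan.repeats):
        folds = plan.select_folds(make_folds(gids, plan.n_folds, plan.seed + rep))
        for f, test_ids in enumerate(folds):
            masked = mask_panel(data.panel, test_ids)
            assert_no_leakage(masked, test_ids, data.panel.columns)
            for env in data.environments():
                target_vars = data.gf_variates(env)
                for model in models:
                    rng = _seeded_rng(plan, rep, f)
                    preds = model.predict_env(data, masked, env, target_vars,
                                              test_ids, rng, "CV1")
                    rows += _score(data, preds, target_vars, test_ids,
                                   dict(scheme="CV1", model=model.name,
                                        environment_id=env, fold=f, repeat=rep))
    return pd.DataFrame(rows)


def run_cv2(data: ExperimentData, models, plan: CVPlan) -> pd.DataFrame:
    """Simultaneous genotype-fold and leave-one-environment-out validation."""
    rows = []
    gids = list(data.panel.index)
    if len(data.environments()) < 2:
        raise ValueError("CV2 needs at least two environments")
    for rep in range(plan.repeats):
        folds = plan.select_folds(make_folds(gids, plan.n_folds, plan.seed + rep))
        for env in data.environments():
            env_vars = data.env_variates(env)
            target_vars = data.gf_variates(env)
            for f, test_ids in enumerate(folds):
                masked = mask_panel(data.panel, test_ids, env_vars)
                assert_no_leakage(masked, test_ids, env_vars)
                for model in models:
                    rng = _seeded_rng(plan, rep, f)
                    preds = model.predict_env(data, masked, env, target_vars,
                                              test_ids, rng, "CV2")
                    rows += _score(data, preds, target_vars, test_ids,
                                   dict(scheme="CV2", model=model.name,
                                        environment_id=env, fold=f, repeat=rep))
    return pd.DataFrame(rows)


def run_cv3(data: ExperimentData, models, plan: CVPlan) -> pd.DataFrame:
    """Late-period prediction given the test genotypes' early-season GF."""
    rows = []
    gids = list(data.panel.index)
    for rep in range(plan.repeats):
        folds = plan.select_folds(make_folds(gids, plan.n_folds, plan.seed + rep))
        for env in data.environments():
            gf_vars = data.gf_variates(env)
            if len(gf_vars) < 4:
                raise ValueError(f"CV3 needs >= 4 flight dates in {env}")
            early, late = data.split_early_late(env)
            param_vars = [data.param_variate(env, p) for p in PARAM_NAMES]
            held_out = late + param_vars
            for f, test_ids in enumerate(folds):
                masked = mask_panel(data.panel, test_ids, held_out)
                assert_no_leakage(masked, test_ids, held_out)
                for model in models:
                    rng = _seeded_rng(plan, rep, f)
                    preds = model.predict_env(data, masked, env, late,
                                              test_ids, rng, "CV3")
                    rows += _score(data, preds, late, test_ids,
                                   dict(scheme="CV3", model=model.name,
                                        environment_id=env, fold=f, repeat=rep))
    return pd.DataFrame(rows)


def run_cv(data: ExperimentData, models, plan: CVPlan) -> pd.DataFrame:
    runner = {"CV1": run_cv1, "CV2": run_cv2, "CV3": run_cv3}[plan.scheme]
    return runner(data, models, plan)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (scheme, model, environment) and overall."""
    if results.empty:
        raise ValueError("empty results table")
    per_env = (
        results.groupby(["scheme", "model", "environment_id"])["accuracy"]
        .mean()
        .reset_index()
    )
    overall = (
        results.groupby(["scheme", "model"])["accuracy"].mean().reset_index()
    )
    overall["environment_id"] = "ALL"
    return pd.concat([per_env, overall], ignore_index=True)


def improvement(results: pd.DataFrame, model_a: str, model_b: str,
                scheme: str | None = None) -> float:
    """Ratio improvement of A over B, (mean_A / mean_B - 1) x 100 (%)."""
    sub = results if scheme is None else results[results["scheme"] == scheme]
    mean_a = sub.loc[sub["model"] == model_a, "accuracy"].mean()
    mean_b = sub.loc[sub["model"] == model_b, "accuracy"].mean()
    if not np.isfinite(mean_b) or mean_b <= 0:
        logger.warning("improvement undefined: mean of %s is %s", model_b, mean_b)
        return float("nan")
    return float((mean_a / mean_b - 1.0) * 100.0)
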