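import numpy as np
import pandas as pd
import pytest

from canopygp.growth import PARAM_NAMES, DynamicsParams, predict_gf_curve
from canopygp.multitrait import ChainConfig
from canopygp.quantgen import gblup
from canopygp.schemes import (
    ABCConfig,
    abc_refine,
    abc_trajectories,
    predict_gp,
    predict_params_gblup,
    predict_tgp,
    sample_param_draws,
    trajectory_from_params,
)

GDD = np.linspace(100, 2600, 14)


def _param_frame(rng, ids):
    base = dict(lai_amp=3.5, r_g=0.02, r_s=0.004, t_g=700.0, t_s=2200.0)
    data = {
        p: base[p] * (1 + 0.1 * rng.standard_normal(len(ids))) for p in PARAM_NAMES
    }
    return pd.DataFrame(data, index=ids)


class TestTrajectoryAssembly:
    def test_matches_forward_model(self):
        rng = np.random.default_rng(0)
        params = _param_frame(rng, ["a", "b"])
        traj = trajectory_from_params(params, GDD)
        for g in ("a", "b"):
            expected = predict_gf_curve(DynamicsParams(*params.loc[g]), GDD)
            np.testing.assert_allclose(traj.loc[g].to_numpy(), expected, atol=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        traj = trajectory_from_params(_param_frame(rng, list("abcdef")), GDD)
        assert ((traj >= 0) & (traj < 1)).all().all()


class TestGPandTGP:
    def test_gp_is_gblup(self, random_grm):
        rng = np.random.default_rng(2)
        ids = list(random_grm.index)
        panel = pd.DataFrame({"v": rng.normal(0, 1, len(ids))}, index=ids)
        test = ids[-8:]
        panel.loc[test, "v"] = np.nan
        res = predict_gp(panel, random_grm, "v", test)
        ref = gblup(panel["v"], random_grm, test_ids=test)
        pd.testing.assert_series_equal(res.pred, ref.pred)

    def test_tgp_is_composition_of_gblup_and_curve(self, random_grm):
        rng = np.random.default_rng(3)
        ids = list(random_grm.index)
        panel = _param_frame(rng, ids)
        test = ids[-8:]
        panel.loc[test, :] = np.nan
        pred = predict_tgp(panel, random_grm, test, GDD)
        fits = predict_params_gblup(panel, random_grm, test)
        manual = pd.DataFrame({p: fits[p].pred for p in PARAM_NAMES})
        traj = trajectory_from_params(manual, GDD)
        np.testing.assert_allclose(pred.gf.to_numpy(), traj.to_numpy(), atol=1e-12)
        assert ((pred.gf >= 0) & (pred.gf < 1)).all().all()

    def test_average_relative_predicts_training_mean(self):
        # a test genotype whose GRM row is the average of the training rows
        # regresses to the population mean parameters
        rng = np.random.default_rng(4)
        n = 30
        ids = [f"g{i}" for i in range(n)] + ["avg"]
        A = np.eye(n) * 0.9 + 0.1
        row = A.mean(axis=0)
        G = np.zeros((n + 1, n + 1))
        G[:n, :n] = A
        G[n, :n] = row
        G[:n, n] = row
        G[n, n] = row.mean() + 1e-3
        grm = pd.DataFrame(G, index=ids, columns=ids)
        panel = _param_frame(rng, ids)
        panel.loc["avg", :] = np.nan
        pred = predict_tgp(panel, grm, ["avg"], GDD)
        for p in PARAM_NAMES:
            mean_p = panel[p].iloc[:n].mean()
            assert pred.params.loc["avg", p] == pytest.approx(mean_p, rel=0.1)


class TestABCRefine:
    def _draws(self, rng, n):
        return np.column_stack(
            [
                rng.uniform(2, 5, n),
                rng.uniform(0.01, 0.04, n),
                rng.uniform(0.002, 0.01, n),
                rng.uniform(400, 1000, n),
                rng.uniform(1600, 2800, n),
            ]
        )

    def test_zero_distance_draw_always_kept(self):
        rng = np.random.default_rng(5)
        draws = self._draws(rng, 100)
        truth = draws[37]
        early_gdd = GDD[:7]
        early_gf = predict_gf_curve(DynamicsParams(*truth), early_gdd)
        _, kept, fb = abc_refine(draws, early_gdd, early_gf, GDD, n_keep=5)
        assert 37 in kept and not fb

    def test_keep_all_equals_posterior_mean(self):
        rng = np.random.default_rng(6)
        draws = self._draws(rng, 50)
        early_gdd = GDD[:7]
        early_gf = np.full(7, 0.4)
        pred, kept, _ = abc_refine(draws, early_gdd, early_gf, GDD, n_keep=50)
        all_traj = np.array(
            [predict_gf_curve(DynamicsParams(*d), GDD) for d in draws]
        )
        np.testing.assert_allclose(pred, all_traj.mean(axis=0), atol=1e-12)

    def test_kept_set_matches_brute_force_sort(self):
        rng = np.random.default_rng(7)
        draws = self._draws(rng, 100)
        early_gdd = GDD[:7]
        early_gf = np.full(7, 0.5)
        _, kept, _ = abc_refine(draws, early_gdd, early_gf, GDD, n_keep=10)
        dists = np.array(
            [
                np.sqrt(np.sum((predict_gf_curve(DynamicsParams(*d), early_gdd) - early_gf) ** 2))
                for d in draws
            ]
        )
        expected = np.argsort(dists, kind="stable")[:10]
        np.testing.assert_array_equal(np.sort(kept), np.sort(expected))

    def test_invalid_draws_get_infinite_distance_but_are_counted(self):
        rng = np.random.default_rng(8)
        draws = self._draws(rng, 20)
        draws[3, 1] = -0.01  # non-positive growth rate
        early_gdd = GDD[:5]
        early_gf = np.full(5, 0.4)
        _, kept, fb = abc_refine(draws, early_gdd, early_gf, GDD, n_keep=19)
        assert 3 not in kept and not fb

    def test_all_invalid_falls_back_to_posterior_mean(self):
        rng = np.random.default_rng(9)
        draws = self._draws(rng, 10)
        draws[:, 0] = -1.0
        pred, kept, fb = abc_refine(draws, GDD[:5], np.full(5, 0.4), GDD, n_keep=3)
        assert fb and len(kept) == 10 and np.all(np.isfinite(pred))

    def test_validation(self):
        rng = np.random.default_rng(10)
        draws = self._draws(rng, 5)
        with pytest.raises(ValueError):
            abc_refine(draws, np.array([]), np.array([]), GDD, n_keep=2)
        with pytest.raises(ValueError):
            abc_refine(draws, GDD[:3], np.full(3, 0.4), GDD, n_keep=6)

    def test_no_early_dates_degrades_to_plain_mean(self):
        rng = np.random.default_rng(11)
        draws = np.stack([self._draws(rng, 30), self._draws(rng, 30)], axis=1)
        pred = abc_trajectories(
            draws, ["a", "b"], None, np.array([]), GDD, n_keep=5
        )
        for i, g in enumerate(("a", "b")):
            all_traj = np.array(
                [predict_gf_curve(DynamicsParams(*d), GDD) for d in draws[:, i, :]]
            )
            np.testing.assert_allclose(pred.gf.loc[g].to_numpy(), all_traj.mean(axis=0), atol=1e-12)


class TestPredictiveDraws:
    def test_draw_moments_match_gblup(self, random_grm):
        rng = np.random.default_rng(12)
        ids = list(random_grm.index)
        panel = _param_frame(rng, ids)
        test = ids[-5:]
        panel.loc[test, :] = np.nan
        fits = predict_params_gblup(panel, random_grm, test)
        draws = sample_param_draws(fits, test, 4000, np.random.default_rng(0))
        assert draws.shape == (4000, 5, 5)
        for j, p in enumerate(PARAM_NAMES):
            mu = fits[p].pred.loc[test].to_numpy()
            sd = np.sqrt(fits[p].pred_var.loc[test].to_numpy())
            np.testing.assert_allclose(draws[:, :, j].mean(axis=0), mu, atol=4 * sd.max() / 60 + 1e-9)


class TestABCConfig:
    def test_defaults_and_validation(self):
        cfg = ABCConfig()
        assert cfg.n_samples == 60000 and cfg.n_keep == 60
        with pytest.raises(ValueError):
            ABCConfig(n_samples=10, n_keep=20)
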