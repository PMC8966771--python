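import numpy as np
import pandas as pd
import pytest

from canopygp.quantgen import (
    accuracy,
    compute_grm,
    estimate_genotypic_values,
    gblup,
    qc_and_impute,
)


def _random_codes(rng, n, m):
    codes = pd.DataFrame(
        rng.binomial(2, np.clip(rng.beta(0.5, 0.5, m), 0.05, 0.95), (n, m)).astype(float) - 1,
        index=[f"g{i:03d}" for i in range(n)],
    )
    return codes.loc[:, codes.std() > 0]


class TestQC:
    def test_monomorphic_column_removed(self):
        codes = pd.DataFrame(
            {"m1": [-1, -1, -1, -1], "m2": [-1, 1, 0, -1], "m3": [1, -1, 1, -1]},
            index=list("abcd"), dtype=float,
        )
        out, report = qc_and_impute(codes)
        assert "m1" not in out.columns and {"m2", "m3"} <= set(out.columns)
        assert report.n_failed_maf == 1

    def test_high_missing_column_removed(self):
        codes = pd.DataFrame(
            {"m1": [np.nan, np.nan, 0.0, 1.0], "m2": [-1, 1, 0, -1]},
            index=list("abcd"), dtype=float,
        )
        out, report = qc_and_impute(codes)
        assert "m1" not in out.columns
        assert report.n_failed_missing == 1

    def test_duplicated_column_pruned(self):
        codes = pd.DataFrame(
            {"m1": [-1, 1, 0, -1], "m2": [-1, 1, 0, -1], "m3": [1, -1, 1, 0]},
            index=list("abcd"), dtype=float,
        )
        out, report = qc_and_impute(codes)
        assert "m1" in out.columns and "m2" not in out.columns
        assert "m3" in out.columns
        assert report.n_pruned_ld == 1

    def test_imputation_fills_column_mean(self):
        codes = pd.DataFrame(
            {"m1": [-1.0, 1.0, 0.0, np.nan, -1.0, 1.0, 0.0, 1.0, -1.0, 0.0,
                    1.0, -1.0, 0.0, 1.0, -1.0, 0.0, 1.0, -1.0, 0.0, 1.0, -1.0]}
        )
        out, _ = qc_and_impute(codes)
        assert not out.isna().any().any()
        assert out.iloc[3, 0] == pytest.approx(codes["m1"].mean())

    def test_everything_filtered_raises(self):
        codes = pd.DataFrame({"m1": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            qc_and_impute(codes)


class TestGRM:
    def test_two_genotype_oracle(self):
        codes = pd.DataFrame([[-1.0], [1.0]], index=["a", "b"], columns=["m1"])
        G = compute_grm(codes)
        np.testing.assert_allclose(G.values, [[1, -1], [-1, 1]], atol=1e-12)

    def test_identical_rows_match_diagonal(self):
        rng = np.random.default_rng(2)
        codes = _random_codes(rng, 5, 40)
        codes.iloc[1] = codes.iloc[0]
        G = compute_grm(codes)
        assert G.iloc[0, 1] == pytest.approx(G.iloc[0, 0], abs=1e-10)
        assert G.iloc[0, 1] == pytest.approx(G.iloc[1, 1], abs=1e-10)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        codes = _random_codes(rng, 10, 50)
        G = compute_grm(codes)
        M = codes.to_numpy()
        X = (M - M.mean(axis=0)) / M.std(axis=0)
        n = len(codes)
        expected = np.empty((n, n))
        c = sum(X[i] @ X[i] for i in range(n)) / n
        for i in range(n):
            for j in range(n):
                expected[i, j] = (X[i] @ X[j]) / c
        np.testing.assert_allclose(G.values, expected, atol=1e-10)

    def test_symmetric_psd_unit_mean_diagonal(self):
        rng = np.random.default_rng(4)
        G = compute_grm(_random_codes(rng, 25, 200))
        np.testing.assert_allclose(G.values, G.values.T, atol=1e-10)
        ev = np.linalg.eigvalsh(G.values)
        assert ev.min() >= -1e-8 * ev.max()
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=1e-12)


class TestGenotypicValues:
    def test_identical_blocks_give_genotype_means(self):
        genos = [f"g{i}" for i in range(10)]
        vals = np.arange(10, dtype=float)
        df = pd.DataFrame(
            {
                "genotype_id": genos * 2,
                "block": ["B1"] * 10 + ["B2"] * 10,
                "value": np.tile(vals, 2),
            }
        )
        gv = estimate_genotypic_values(df)
        assert gv.sigma2_e == pytest.approx(0.0, abs=1e-4)
        np.testing.assert_allclose(gv.g.to_numpy(), vals, atol=1e-3)

    def test_constant_trait_gives_zero_genetic_variance(self):
        df = pd.DataFrame(
            {"genotype_id": list("abcde") * 2, "block": ["B1"] * 5 + ["B2"] * 5,
             "value": 3.0}
        )
        gv = estimate_genotypic_values(df)
        assert gv.sigma2_s == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(gv.g.to_numpy(), 3.0, atol=1e-6)

    def test_no_replication_falls_back_to_means(self):
        df = pd.DataFrame(
            {"genotype_id": list("abc"), "block": "B1", "value": [1.0, 2.0, 3.0]}
        )
        gv = estimate_genotypic_values(df)
        assert gv.fallback_means
        np.testing.assert_allclose(gv.g.to_numpy(), [1, 2, 3])

    def test_variance_recovery_and_shrinkage(self):
        rng = np.random.default_rng(5)
        n_g = 50
        s = rng.normal(0, 1.0, n_g)
        rows = []
        for b, beta in (("B1", 0.3), ("B2", -0.3)):
            for i in range(n_g):
                rows.append(
                    {"genotype_id": f"g{i:02d}", "block": b,
                     "value": 10 + beta + s[i] + rng.normal(0, 1.0)}
                )
        df = pd.DataFrame(rows)
        gv = estimate_genotypic_values(df)
        assert gv.sigma2_s == pytest.approx(1.0, rel=0.5)
        assert gv.sigma2_e == pytest.approx(1.0, rel=0.5)
        means = df.groupby("genotype_id")["value"].mean()
        # BLUPs shrink toward the general mean relative to raw means
        assert np.all(np.abs(gv.g - gv.mu) <= np.abs(means - means.mean()) + 1e-8)
        assert gv.g.var() <= means.var()


class TestGblup:
    def test_identity_grm_predicts_mean_only(self):
        rng = np.random.default_rng(6)
        ids = [f"g{i}" for i in range(20)]
        G = pd.DataFrame(np.eye(20), index=ids, columns=ids)
        y = pd.Series(rng.normal(0, 1, 20), index=ids)
        res = gblup(y, G, train_ids=ids[:15], test_ids=ids[15:])
        np.testing.assert_allclose(res.u_test.to_numpy(), 0.0, atol=1e-10)

    def test_duplicate_genotype_gets_its_fitted_value(self, random_grm):
        # a test genotype genetically identical to a training genotype
        rng = np.random.default_rng(7)
        G = random_grm.copy()
        ids = list(G.index)
        dup, src = ids[-1], ids[0]
        G.loc[dup, :] = G.loc[src, :]
        G.loc[:, dup] = G.loc[:, src]
        G.loc[dup, dup] = G.loc[src, src]
        y = pd.Series(rng.normal(0, 1, len(ids)), index=ids)
        res = gblup(y, G, train_ids=ids[:-1], test_ids=[dup])
        assert res.u_test.loc[dup] == pytest.approx(res.u_train.loc[src], abs=1e-8)

    def test_equals_ridge_regression_on_markers(self):
        rng = np.random.default_rng(8)
        n, m = 30, 100
        codes = _random_codes(rng, n, m)
        ids = list(codes.index)
        G = compute_grm(codes)
        M = codes.to_numpy()
        X = (M - M.mean(axis=0)) / M.std(axis=0)
        y = pd.Series(X @ rng.normal(0, 0.3, X.shape[1]) + rng.normal(0, 1, n), index=ids)
        train, test = ids[:22], ids[22:]
        res = gblup(y, G, train_ids=train, test_ids=test)
        # RR-BLUP with penalty c * sigma_e^2/sigma_u^2 on the same scaled markers
        c = np.trace(X @ X.T) / n
        lam = res.vc.sigma2_e / res.vc.sigma2_u
        itr = [ids.index(i) for i in train]
        ite = [ids.index(i) for i in test]
        alpha = np.linalg.solve(X[itr] @ X[itr].T + c * lam * np.eye(len(train)),
                                y.loc[train].to_numpy() - res.mean)
        u_ridge = X[ite] @ (X[itr].T @ alpha)
        np.testing.assert_allclose(res.u_test.to_numpy(), u_ridge, atol=1e-6)

    def test_h2_identity(self, random_grm):
        rng = np.random.default_rng(9)
        ids = list(random_grm.index)
        y = pd.Series(rng.normal(0, 1, len(ids)), index=ids)
        res = gblup(y, random_grm, train_ids=ids)
        assert res.h2 == pytest.approx(
            res.vc.sigma2_u / (res.vc.sigma2_u + res.vc.sigma2_e), abs=1e-10
        )

    def test_input_validation(self, random_grm):
        ids = list(random_grm.index)
        y = pd.Series(1.0, index=ids)
        with pytest.raises(ValueError):
            gblup(y, random_grm, train_ids=[], test_ids=ids[:2])
        with pytest.raises(ValueError):
            gblup(y, random_grm, train_ids=ids[:5], test_ids=ids[4:6])
        with pytest.raises(KeyError):
            gblup(y, random_grm, train_ids=ids[:5], test_ids=["nope"])


class TestAccuracy:
    def test_perfect_and_inverted(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert accuracy([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # Pearson r of (1,2,3) vs (1,2,4) = 0.98198...
        assert accuracy([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981980506, abs=1e-8)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            accuracy([1, 2], [1, 2])
        with pytest.raises(ValueError):
            accuracy([1, 1, 1], [1, 2, 3])
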