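import numpy as np
import pandas as pd
import pytest

from emspart import (
    Coordinates,
    build_pcnm,
    build_temporal_dummies,
    build_tsa_terms,
    community_with_shares,
    forward_select,
    partial_rda_test,
    per_variable_F,
    rda_adjusted_r2,
    variation_partition,
)


def coords_from(xy, ids=None):
    ids = ids or [f"S{i}" for i in range(len(xy))]
    return Coordinates(pd.DataFrame(xy, columns=["x", "y"], index=ids))


class TestTrendSurface:
    def test_monomials_of_centred_site(self):
        # 12 sites whose mean is zero, so site 0 has centred coords (2, 3)
        base = np.zeros((12, 2))
        base[0] = [2, 3]
        base[1:] = [[-2 / 11, -3 / 11]] * 11
        sp = build_tsa_terms(coords_from(base))
        cx, cy = base[:, 0] - base[:, 0].mean(), base[:, 1] - base[:, 1].mean()
        full = np.column_stack([cx, cy, cx**2, cy**2, cx * cy,
                                cx**3, cy**3, cx**2 * cy, cx * cy**2])
        expected = full[0] - full.mean(axis=0)
        assert sp.data.iloc[0].tolist() == pytest.approx(expected.tolist())
        # and the uncentred monomials of (2, 3) are the textbook row
        assert full[0].tolist() == pytest.approx(
            [2, 3, 4, 9, 6, 8, 27, 12, 18]
        )

    def test_exactly_nine_centred_columns(self, rng):
        sp = build_tsa_terms(coords_from(rng.uniform(0, 1e4, (30, 2))))
        assert sp.data.shape[1] == 9
        scale = sp.data.std(axis=0).to_numpy()
        assert np.abs(sp.data.mean(axis=0).to_numpy() / scale).max() < 1e-12

    def test_translation_leaves_fit_unchanged(self, rng):
        xy = rng.uniform(0, 1000, (40, 2))
        Y = rng.standard_normal((40, 5))
        r1 = rda_adjusted_r2(Y, build_tsa_terms(coords_from(xy)).data)
        r2 = rda_adjusted_r2(
            Y, build_tsa_terms(coords_from(xy + [5000, -2000])).data
        )
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_collinear_sites_warn(self):
        xy = np.column_stack([np.arange(12.0), np.zeros(12)])
        with pytest.warns(UserWarning, match="rank"):
            build_tsa_terms(coords_from(xy))


class TestPCNM:
    def test_line_matches_dense_eigendecomposition(self):
        xy = np.column_stack([np.arange(4.0), np.zeros(4)])
        sp = build_pcnm(coords_from(xy), truncation=1.0)
        # independent oracle: explicit PCoA of the truncated matrix
        D = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        Dt = np.where(D <= 1.0, D, 4.0)
        np.fill_diagonal(Dt, 0)
        J = np.eye(4) - 0.25
        G = J @ (-0.5 * Dt**2) @ J
        w, v = np.linalg.eigh(G)
        keep = w > 1e-10
        expected = np.abs(v[:, keep] * np.sqrt(w[keep]))
        got = np.abs(sp.data.to_numpy())
        # compare as column sets (order by eigenvalue descending)
        expected = expected[:, np.argsort(-w[keep])]
        assert got == pytest.approx(expected, abs=1e-8)

    def test_retained_count_equals_positive_eigenvalues(self, rng):
        sp = build_pcnm(coords_from(rng.uniform(0, 100, (25, 2))))
        assert (sp.eigenvalues > 0).all()
        assert sp.data.shape[1] == len(sp.eigenvalues)

    def test_grid_first_eigenvector_is_broad_wave(self):
        gx, gy = np.meshgrid(np.arange(7.0), np.arange(7.0))
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        sp = build_pcnm(coords_from(xy))
        v1 = sp.data.iloc[:, 0].to_numpy()
        # the leading PCNM on a grid is a half-period wave along one
        # diagonal/axis: strongly monotone in a coordinate direction
        r = max(abs(np.corrcoef(v1, xy[:, 0])[0, 1]),
                abs(np.corrcoef(v1, xy[:, 1])[0, 1]),
                abs(np.corrcoef(v1, xy[:, 0] + xy[:, 1])[0, 1]),
                abs(np.corrcoef(v1, xy[:, 0] - xy[:, 1])[0, 1]))
        assert r > 0.8

    def test_duplicate_coordinates_rejected(self):
        xy = np.array([[0.0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="duplicate"):
            build_pcnm(coords_from(xy))


class TestRdaAdjustedR2:
    def test_matches_univariate_ols_adjusted_r2(self, rng):
        import statsmodels.api as sm
        x = rng.standard_normal(50)
        y = 2 * x + rng.standard_normal(50)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert rda_adjusted_r2(y[:, None], x[:, None]) == pytest.approx(
            fit.rsquared_adj
        )

    def test_ezekiel_formula_arithmetic(self):
        # construct exact R2 = 0.5 with n = 11, p = 1
        x = np.arange(11.0)
        xc = x - x.mean()
        noise = np.array([1.0, -1, 1, -1, 1, -1, 1, -1, 1, -1, 0])
        noise = noise - noise.mean()
        noise -= xc * (xc @ noise) / (xc @ xc)
        y = xc + noise * np.sqrt((xc @ xc) / (noise @ noise))
        got = rda_adjusted_r2(y[:, None], x[:, None])
        assert got == pytest.approx(1 - (1 - 0.5) * 10 / 9)

    def test_own_leading_component_recovers_variance_share(self, rng):
        Y = rng.standard_normal((60, 5)) @ np.diag([3, 1, 1, 0.5, 0.2])
        Yc = Y - Y.mean(axis=0)
        U, sv, Vt = np.linalg.svd(Yc, full_matrices=False)
        share = sv[0] ** 2 / (sv**2).sum()
        raw = 1 - (1 - rda_adjusted_r2(Y, U[:, :1])) * 1  # adjusted
        n = 60
        expected = 1 - (1 - share) * (n - 1) / (n - 2)
        assert rda_adjusted_r2(Y, U[:, :1]) == pytest.approx(expected)

    def test_pure_noise_adjusted_near_zero_on_average(self, rng):
        vals = []
        for _ in range(200):
            Y = rng.standard_normal((100, 3))
            X = rng.standard_normal((100, 1))
            vals.append(rda_adjusted_r2(Y, X))
        assert abs(np.mean(vals)) < 0.01

    def test_rank_deficient_block_warns(self, rng):
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        Y = rng.standard_normal((30, 3))
        with pytest.warns(UserWarning, match="rank deficient"):
            rda_adjusted_r2(Y, X)


class TestPartialRdaTest:
    def test_empty_conditioning_reduces_to_simple_rda(self, rng):
        Y = rng.standard_normal((40, 4))
        X = rng.standard_normal((40, 2))
        F1, _ = partial_rda_test(Y, X, None, n_perm=99, seed=1)
        F2, _ = partial_rda_test(Y, X, np.empty((40, 0)), n_perm=99, seed=1)
        assert F1 == pytest.approx(F2)

    def test_x_nested_in_z_degenerates(self, rng):
        Y = rng.standard_normal((40, 4))
        Z = rng.standard_normal((40, 2))
        X = Z[:, :1]
        F, p = partial_rda_test(Y, X, Z, n_perm=99, seed=1)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert p > 0.9

    def test_too_few_permutations_refused(self, rng):
        Y = rng.standard_normal((20, 2))
        X = rng.standard_normal((20, 1))
        with pytest.raises(ValueError, match="permutations"):
            partial_rda_test(Y, X, None, n_perm=50)

    def test_strong_signal_detected(self, rng):
        x = rng.standard_normal(50)
        Y = np.outer(x, [1, -1, 0.5]) + 0.3 * rng.standard_normal((50, 3))
        F, p = partial_rda_test(Y, x, None, n_perm=199, seed=3)
        assert p <= 0.01


class TestForwardSelect:
    def test_true_predictor_selected_first(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(100)
            Y = np.outer(x, rng.standard_normal(8)) \
                + rng.standard_normal((100, 8))
            X = pd.DataFrame({
                "true": x,
                **{f"noise{i}": rng.standard_normal(100) for i in range(5)},
            })
            sel = forward_select(Y, X, n_perm=199, seed=seed)
            hits += bool(sel) and sel[0] == "true"
        assert hits >= 19  # >= 95% of seeds

    def test_pure_noise_selects_little(self, rng):
        sizes = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            Y = r.standard_normal((80, 5))
            X = pd.DataFrame(
                {f"n{i}": r.standard_normal(80) for i in range(6)})
            sizes.append(len(forward_select(Y, X, n_perm=199, seed=seed)))
        assert np.mean(sizes) < 1.0

    def test_no_duplicate_selection(self, rng):
        x = rng.standard_normal(60)
        Y = np.outer(x, rng.standard_normal(4)) \
            + 0.5 * rng.standard_normal((60, 4))
        X = pd.DataFrame({"a": x, "b": x + 0.01 * rng.standard_normal(60),
                          "c": rng.standard_normal(60)})
        sel = forward_select(Y, X, n_perm=199, seed=0)
        assert len(sel) == len(set(sel))

    def test_missing_value_columns_excluded(self, rng):
        Y = rng.standard_normal((30, 3))
        X = pd.DataFrame({"ok": rng.standard_normal(30),
                          "bad": np.r_[np.nan, rng.standard_normal(29)]})
        with pytest.warns(UserWarning, match="missing"):
            sel = forward_select(Y, X, n_perm=99, seed=0)
        assert "bad" not in sel


class TestVariationPartition:
    def test_fractions_sum_to_one_exactly(self, rng):
        for seed in range(5):
            Y, E, S, T = community_with_shares(60, 8, 0.15, 0.1, 0.05,
                                               seed=seed)
            res = variation_partition(Y, E, S, T)
            assert sum(res.fractions.values()) == pytest.approx(
                1.0, abs=1e-10
            )
            assert res.total_explained == pytest.approx(
                1 - res.fractions["residual"], abs=1e-10
            )

    def test_orthogonal_generators_give_pure_fractions(self):
        Y, E, S, _ = community_with_shares(150, 12, 0.2, 0.2, seed=3)
        res = variation_partition(Y, E, S)
        assert res.fractions["pure_env"] == pytest.approx(0.2, abs=0.03)
        assert res.fractions["pure_space"] == pytest.approx(0.2, abs=0.03)
        assert abs(res.fractions["env_space"]) < 0.03

    def test_identical_blocks_share_everything(self, rng):
        Y, E, _, _ = community_with_shares(100, 8, 0.3, 0.0, seed=1)
        res = variation_partition(Y, E, E.copy())
        assert abs(res.fractions["pure_env"]) < 1e-8
        assert abs(res.fractions["pure_space"]) < 1e-8
        assert res.fractions["env_space"] > 0.2

    def test_single_block_degrades_gracefully(self, rng):
        Y, E, _, _ = community_with_shares(80, 6, 0.25, 0.0, seed=2)
        res = variation_partition(Y, E=E)
        assert res.fractions["pure_env"] == pytest.approx(
            res.total_explained
        )
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_negative_fractions_reported_unless_truncated(self, rng):
        Y = rng.standard_normal((25, 4))
        E = rng.standard_normal((25, 3))
        S = rng.standard_normal((25, 3))
        res = variation_partition(Y, E, S)
        trunc = variation_partition(Y, E, S, truncate_negative=True)
        assert min(trunc.fractions.values()) >= 0.0
        if min(res.fractions.values()) < 0:
            assert min(res.fractions.values()) < 0

    def test_no_blocks_rejected(self, rng):
        with pytest.raises(ValueError, match="block"):
            variation_partition(rng.standard_normal((10, 2)))


class TestPerVariableF:
    def test_orthogonal_equal_predictors_split_evenly(self):
        rng = np.random.default_rng(8)
        raw = rng.standard_normal((200, 2))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        E = pd.DataFrame(Q * np.sqrt(199), columns=["a", "b"])
        Y = (E[["a"]].to_numpy() + E[["b"]].to_numpy()) \
            @ np.ones((1, 5)) + rng.standard_normal((200, 5))
        tab = per_variable_F(Y, E, n_perm=99, seed=2)
        shares = dict(zip(tab.variable, tab.share))
        assert shares["a"] == pytest.approx(0.5, abs=0.1)

    def test_noise_variable_gets_tiny_share(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(150)
        E = pd.DataFrame({"strong": x, "junk": rng.standard_normal(150)})
        Y = np.outer(x, [1, 1, -1]) + 0.3 * rng.standard_normal((150, 3))
        tab = per_variable_F(Y, E, n_perm=99, seed=3)
        shares = dict(zip(tab.variable, tab.share))
        assert shares["junk"] < 0.05

    def test_single_variable_share_is_one(self, rng):
        E = pd.DataFrame({"only": rng.standard_normal(40)})
        Y = rng.standard_normal((40, 3))
        tab = per_variable_F(Y, E, n_perm=99, seed=1)
        assert tab.share.iloc[0] == pytest.approx(1.0)


class TestTemporalDummies:
    def test_centred_dummy_coding(self):
        years = pd.Series([2009, 2009, 2010, 2010])
        sessions = pd.Series([1, 2, 1, 2])
        T = build_temporal_dummies(years, sessions)
        assert set(T.columns) == {"year_2010", "session_2"}
        assert T.mean(axis=0).to_numpy() == pytest.approx([0.0, 0.0])


class TestSpatialMethodOrdering:
    def test_pcnm_spatial_fraction_at_least_tsa(self, rng):
        """Finer-scale spatial basis captures at least the broad trend."""
        xy = rng.uniform(0, 10000, (90, 2))
        coords = coords_from(xy)
        # structure finer than a cubic trend surface can follow
        z = np.sin(xy[:, 0] / 800) + np.cos(xy[:, 1] / 600)
        Y = np.outer(z, rng.standard_normal(6)) \
            + rng.standard_normal((90, 6))
        r_tsa = rda_adjusted_r2(Y, build_tsa_terms(coords).data)
        r_pcnm = rda_adjusted_r2(Y, build_pcnm(coords).data)
        assert r_pcnm >= r_tsa - 1e-9
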