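"""Fixed-effects IV machinery: within transform, instruments, estimators,
cluster-robust inference and weak-instrument diagnostics."""

import numpy as np
import pandas as pd
import pytest

from agriair import paneliv as piv
from agriair.paneliv import PanelIVModel, build_instruments
from agriair.synth import SynthConfig, generate_panel


class TestWithinTransform:
    def test_balanced_panel_residual_means_vanish(self, rng):
        county = np.repeat(np.arange(10), 5)
        year = np.tile(np.arange(5), 10)
        X = rng.normal(size=(50, 3))
        Xt = piv.within_transform(X, [county, year])
        for ids in (county, year):
            means = pd.DataFrame(Xt).groupby(ids).mean().to_numpy()
            assert np.abs(means).max() < 1e-12

    def test_county_constant_column_absorbed(self, rng):
        county = np.repeat(np.arange(6), 4)
        year = np.tile(np.arange(4), 6)
        col = county.astype(float) * 3.1
        out = piv.within_transform(col, [county, year])
        assert np.abs(out).max() < 1e-10

    def test_matches_dummy_regression_on_toy_panel(self, rng):
        county = np.repeat(np.arange(6), 4)
        year = np.tile(np.arange(4), 6)
        x = rng.normal(size=(24, 2))
        y = x @ [1.5, -0.7] + 0.3 * county + 0.1 * year + rng.normal(size=24)
        Xt = piv.within_transform(np.column_stack([y, x]), [county, year])
        b_within = np.linalg.lstsq(Xt[:, 1:], Xt[:, 0], rcond=None)[0]
        dummies = np.column_stack(
            [np.eye(6)[county][:, 1:], np.eye(4)[year][:, 1:], np.ones(24)]
        )
        b_dummy = np.linalg.lstsq(np.column_stack([x, dummies]), y, rcond=None)[0][:2]
        assert np.allclose(b_within, b_dummy, atol=1e-10)

    def test_unbalanced_panel_converges(self, rng):
        county = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
        year = np.array([0, 1, 2, 0, 2, 0, 1, 2, 3])
        X = rng.normal(size=(9, 2))
        Xt = piv.within_transform(X, [county, year])
        for ids in (county, year):
            means = pd.DataFrame(Xt).groupby(ids).mean().to_numpy()
            assert np.abs(means).max() < 1e-9


class TestInstruments:
    def test_single_group_gives_three_columns(self, tiny_panel):
        panel, _ = tiny_panel
        p = panel.copy()
        p["group"] = 1
        Z = build_instruments(p)
        assert Z.shape[1] == 3

    def test_column_count_bounded_by_three_per_group(self, small_panel):
        panel, _ = small_panel
        Z = build_instruments(panel)
        assert Z.shape[1] <= 3 * panel["group"].nunique()

    def test_fifty_groups_give_at_most_150_columns(self, small_panel):
        panel, _ = small_panel
        p = panel.copy()
        p["group"] = (p["county"] % 50) + 1  # the full-scale grouping regime
        Z = build_instruments(p)
        assert Z.shape[1] <= 150

    def test_bin_counts_partition_the_year(self, small_panel):
        panel, _ = small_panel
        total = panel[[f"wd_bin_{a}" for a in range(4)]].sum(axis=1)
        assert np.allclose(total, 365.0)

    def test_duplicate_columns_dropped(self, tiny_panel):
        panel, _ = tiny_panel
        p = panel.copy()
        p["wd_dup"] = p["wd_bin_0"]
        Z = build_instruments(p, wind_cols=("wd_bin_0", "wd_dup", "wd_bin_1"))
        per_group = Z.shape[1] / p["group"].nunique()
        assert per_group <= 2.0  # the duplicated column vanishes in each group


class TestEstimatorIdentities:
    def test_self_instrumented_2sls_equals_ols(self, small_panel):
        panel, _ = small_panel
        base = PanelIVModel.from_panel(panel)
        inst = panel[["ozone_annual", "pm25"]].rename(
            columns={"ozone_annual": "z1", "pm25": "z2"}
        )
        m = PanelIVModel(
            panel, "log_tfp", ["ozone_annual", "pm25"], base.control_names,
            instruments=inst,
        )
        assert np.allclose(m.fit("2sls").params, m.fit("ols").params, atol=1e-9)

    def test_just_identified_liml_equals_2sls(self, small_panel):
        panel, _ = small_panel
        base = PanelIVModel.from_panel(panel)
        inst = build_instruments(panel).iloc[:, :2]
        m = PanelIVModel(
            panel, "log_tfp", ["ozone_annual", "pm25"], base.control_names,
            instruments=inst,
        )
        r2, rl = m.fit("2sls"), m.fit("liml")
        assert np.allclose(r2.params, rl.params, atol=1e-8)

    def test_liml_kappa_at_least_one(self, small_panel):
        panel, _ = small_panel
        assert PanelIVModel.from_panel(panel).fit("liml").kappa >= 1.0

    def test_wald_ratio_closed_form_scalar_case(self, rng):
        n_c, n_y = 25, 2
        county = np.repeat(np.arange(n_c), n_y)
        year = np.tile(np.arange(n_y), n_c)
        z = rng.normal(size=n_c * n_y)
        x = 0.8 * z + rng.normal(size=n_c * n_y)
        y = -1.3 * x + rng.normal(size=n_c * n_y)
        panel = pd.DataFrame(
            {"county": county, "year": year, "y": y, "x": x, "cluster": county}
        )
        inst = pd.DataFrame({"z": z})
        m = PanelIVModel(panel, "y", ["x"], [], cluster="county", instruments=inst)
        b = m.fit("2sls").params["x"]
        tilde = piv.within_transform(np.column_stack([y, x, z]), [county, year])
        wald = (tilde[:, 2] @ tilde[:, 0]) / (tilde[:, 2] @ tilde[:, 1])
        assert b == pytest.approx(wald, abs=1e-10)

    def test_outcome_shift_leaves_slopes_unchanged(self, small_panel):
        panel, _ = small_panel
        shifted = panel.copy()
        shifted["log_tfp"] = shifted["log_tfp"] + 5.0
        r1 = PanelIVModel.from_panel(panel).fit("2sls")
        r2 = PanelIVModel.from_panel(shifted).fit("2sls")
        assert np.allclose(r1.params, r2.params, atol=1e-9)

    def test_2sls_residual_orthogonality(self, small_panel):
        # residuals orthogonal to the instrument projection of the design
        panel, _ = small_panel
        m = PanelIVModel.from_panel(panel)
        res = m.fit("2sls")
        y, Xe, C, Z, _, _ = m._matrices()
        X = np.column_stack([Xe, C])
        Zfull = np.column_stack([Z, C])
        Xhat = Zfull @ np.linalg.lstsq(Zfull, X, rcond=None)[0]
        u = y - X @ res.params.to_numpy()
        assert np.abs(Xhat.T @ u).max() / len(y) < 1e-8


class TestClusterVcov:
    def test_own_cluster_equals_hc1(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = X @ [1.0, 2.0] + rng.normal(size=60)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        V = piv.cluster_vcov(X, y - X @ b, np.arange(60))
        V_hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
        assert np.allclose(V, V_hc1, rtol=1e-8)

    def test_hand_computed_sandwich_six_rows(self):
        X = np.column_stack([np.ones(6), np.arange(1.0, 7.0)])
        u = np.array([0.5, -0.2, 0.1, 0.3, -0.4, 0.2])
        cl = np.array([0, 0, 1, 1, 2, 2])
        bread = np.linalg.inv(X.T @ X)
        meat = sum(
            np.outer(X[cl == g].T @ u[cl == g], X[cl == g].T @ u[cl == g])
            for g in range(3)
        )
        expected = (3 / 2) * (5 / 4) * bread @ meat @ bread
        assert np.allclose(piv.cluster_vcov(X, u, cl), expected)

    def test_duplicating_clusters_preserves_coefficients(self, tiny_panel):
        panel, _ = tiny_panel
        doubled = pd.concat(
            [panel, panel.assign(county=panel["county"] + 10_000)], ignore_index=True
        )
        r1 = PanelIVModel.from_panel(panel).fit("2sls")
        r2 = PanelIVModel.from_panel(doubled).fit("2sls")
        assert np.allclose(r1.params, r2.params, atol=1e-8)

    def test_single_cluster_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            piv.cluster_vcov(X, rng.normal(size=10), np.zeros(10))


class TestWeakInstrumentDiagnostics:
    def test_kp_equals_first_stage_wald_scalar_iid(self, rng):
        n = 300
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        kp = piv.kp_f(x[:, None], z[:, None], np.arange(n))
        pi = (z @ x) / (z @ z)
        eps = x - z * pi
        factor = n / (n - 1)
        v_pi = factor * np.sum(z**2 * eps**2) / (z @ z) ** 2
        assert kp == pytest.approx(pi**2 / v_pi, rel=1e-10)

    def test_irrelevant_instruments_give_small_kp(self, rng):
        stats = []
        for _ in range(200):
            z = rng.normal(size=(120, 3))
            x = rng.normal(size=(120, 1))  # no first stage at all
            stats.append(piv.kp_f(x, z, np.arange(120)))
        assert np.median(stats) < 2.0

    def test_cragg_donald_reported_with_kp(self, small_panel):
        panel, _ = small_panel
        res = PanelIVModel.from_panel(panel).fit("2sls")
        assert res.kp_f > 10.0
        assert res.cragg_donald > 10.0

    def test_liml_less_median_biased_with_many_weak_instruments(self, rng):
        n_c, n_y, L = 150, 2, 15
        beta = 1.0
        bias2, biasl = [], []
        for _ in range(200):
            county = np.repeat(np.arange(n_c), n_y)
            year = np.tile(np.arange(n_y), n_c)
            Z = rng.normal(size=(n_c * n_y, L))
            pi = np.full(L, 0.06)
            e = rng.normal(size=n_c * n_y)
            u = 0.8 * e + 0.6 * rng.normal(size=n_c * n_y)
            x = Z @ pi + e
            y = beta * x + u
            panel = pd.DataFrame({"county": county, "year": year, "y": y, "x": x})
            inst = pd.DataFrame(Z, columns=[f"z{j}" for j in range(L)])
            m = PanelIVModel(panel, "y", ["x"], [], instruments=inst)
            bias2.append(m.fit("2sls").params["x"] - beta)
            biasl.append(m.fit("liml").params["x"] - beta)
        assert abs(np.median(biasl)) <= abs(np.median(bias2))

    def test_underidentification_rejected(self, small_panel):
        panel, _ = small_panel
        inst = build_instruments(panel).iloc[:, :1]
        base = PanelIVModel.from_panel(panel)
        m = PanelIVModel(
            panel, "log_tfp", ["ozone_annual", "pm25"], base.control_names,
            instruments=inst,
        )
        with pytest.raises(ValueError, match="under-identified"):
            m.fit("2sls")


class TestPanelHygiene:
    def test_duplicate_county_year_rejected(self, tiny_panel):
        panel, _ = tiny_panel
        dup = pd.concat([panel, panel.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            PanelIVModel.from_panel(dup)

    def test_listwise_deletion_of_missing_rows(self, tiny_panel):
        panel, _ = tiny_panel
        p = panel.copy()
        # one missing year in each of five different counties
        p.loc[p.index[[0, 10, 20, 30, 40]], "pm25"] = np.nan
        m = PanelIVModel.from_panel(p)
        assert m.data.shape[0] == len(p) - 5

    def test_seasonal_specification_runs(self, small_panel):
        panel, _ = small_panel
        res = PanelIVModel.from_panel(panel, ozone="seasonal").fit("2sls")
        assert {"ozone_winter", "ozone_nonwinter", "pm25"} <= set(res.params.index)

    def test_cumulative_index_outcome_choice(self, small_panel):
        panel, _ = small_panel
        res = PanelIVModel.from_panel(panel, ozone="aot40").fit("2sls")
        assert res.params["aot40"] < 0  # ozone burden depresses TFP

    def test_zero_winter_effect_yields_insignificant_winter_coefficient(self):
        # DGP with the whole ozone effect on nonwinter exposure: the
        # seasonal specification should find a null winter coefficient
        hits = 0
        n_reps = 20
        for seed in range(n_reps):
            cfg = SynthConfig(
                n_counties=80, n_years=8, seed=2000 + seed, effect_basis="nonwinter"
            )
            panel, _ = generate_panel(cfg)
            res = PanelIVModel.from_panel(panel, ozone="seasonal").fit("2sls")
            if abs(res.tvalues["ozone_winter"]) < 1.96:
                hits += 1
            assert res.params["ozone_nonwinter"] == pytest.approx(-0.0224, abs=0.01)
        assert hits >= 0.9 * n_reps

    def test_summary_renders(self, small_panel):
        panel, _ = small_panel
        text = PanelIVModel.from_panel(panel).fit("2sls").summary()
        assert "KP F" in text and "ozone_annual" in text
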