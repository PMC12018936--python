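import math

import numpy as np
import pytest

from paleocroc import allometry as A
from paleocroc import io_formats as io
from paleocroc.io_formats import AllometryRecord

from _oracles import gls_conditional_mean


def records_from(points: dict[str, tuple[float, float]]) -> list[AllometryRecord]:
    return [
        AllometryRecord(taxon=t, specimen="1", hw_cm=hw, tl_cm=tl)
        for t, (hw, tl) in points.items()
    ]


def star_tree(taxa, depth=10.0):
    newick = "(" + ",".join(f"{t}:{depth}" for t in taxa) + ");"
    return io.read_newick(newick)


class TestFitRegression:
    def test_collinear_points_recovered_exactly(self):
        # log10 TL = 1.0 + 0.9 log10 HW
        pts = {f"s{i}": (hw, 10 ** (1.0 + 0.9 * math.log10(hw))) for i, hw in enumerate([5, 10, 20, 40])}
        model = A.fit_regression(records_from(pts), mode="OLS")
        assert model.slope == pytest.approx(0.9, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.sigma2 == pytest.approx(0.0, abs=1e-16)

    def test_ols_matches_normal_equations(self, rng):
        hw = rng.uniform(5, 80, size=5)
        tl = 10 ** (1.1 + 0.85 * np.log10(hw) + rng.normal(0, 0.05, size=5))
        pts = {f"s{i}": (hw[i], tl[i]) for i in range(5)}
        model = A.fit_regression(records_from(pts), mode="OLS")
        X = np.column_stack([np.ones(5), np.log10(sorted(hw[np.argsort([f"s{i}" for i in range(5)])]))])
        # order taxa as the model does (sorted labels)
        order = sorted(pts)
        X = np.column_stack([np.ones(5), [math.log10(pts[t][0]) for t in order]])
        y = np.array([math.log10(pts[t][1]) for t in order])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_pgls_with_star_tree_lambda0_equals_ols(self, rng):
        taxa = [f"s{i}" for i in range(6)]
        hw = rng.uniform(5, 80, size=6)
        tl = 10 ** (1.0 + 0.9 * np.log10(hw) + rng.normal(0, 0.05, size=6))
        pts = {t: (hw[i], tl[i]) for i, t in enumerate(taxa)}
        tree = star_tree(taxa)
        ols = A.fit_regression(records_from(pts), mode="OLS")
        pgls = A.fit_regression(records_from(pts), tree, mode="PGLS", lam=0.0)
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-10)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-10)

    def test_specimens_averaged_on_log_scale(self):
        recs = [
            AllometryRecord("A", "1", 10.0, 100.0),
            AllometryRecord("A", "2", 1000.0, 100.0),
            AllometryRecord("B", "1", 20.0, 200.0),
            AllometryRecord("C", "1", 40.0, 400.0),
        ]
        means = A.taxon_log_means(recs)
        assert means.loc["A", "log_hw"] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_too_few_taxa_rejected(self):
        pts = {"a": (10, 100), "b": (20, 200)}
        with pytest.raises(A.AllometryError, match=">=3"):
            A.fit_regression(records_from(pts))


class TestEstimateLambda:
    def test_constant_trait_rejected(self):
        tree = star_tree(["a", "b", "c", "d"])
        with pytest.raises(A.AllometryError, match="constant"):
            A.estimate_lambda(tree, {t: 1.0 for t in "abcd"})

    def test_lambda0_likelihood_equals_iid_normal(self, rng):
        taxa = [f"s{i}" for i in range(6)]
        tree = star_tree(taxa, depth=7.0)  # ultrametric: unit diagonal after scaling
        y = rng.normal(0, 1, size=6)
        X = np.ones((6, 1))
        V = A.scaled_vcv(tree, taxa)
        ll = A._loglik_lambda(0.0, X, y, V)
        mu = y.mean()
        s2 = np.mean((y - mu) ** 2)
        iid = -0.5 * (6 * math.log(2 * math.pi * s2) + 6)
        assert ll == pytest.approx(iid, abs=1e-8)

    def test_optimizer_matches_grid_search(self, rng):
        tree = io.read_newick("(((a:2,b:2):3,c:5):5,(d:4,e:4):6);")
        taxa = list("abcde")
        y = {t: v for t, v in zip(taxa, [0.1, 0.3, 1.2, -0.5, -0.2])}
        lam_hat = A.estimate_lambda(tree, y)
        V = A.scaled_vcv(tree, taxa)
        yv = np.array([y[t] for t in taxa])
        X = np.ones((5, 1))
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        lls = [A._loglik_lambda(l, X, yv, V) for l in grid]
        lam_grid = float(grid[int(np.argmax(lls))])
        assert abs(lam_hat - lam_grid) <= 1e-3

    def test_recovers_strong_signal(self, rng):
        # data simulated with lambda = 1 on a deep balanced tree
        from paleocroc import synthetic_data as S

        cfg = S.SimConfig(n_taxa=100, seed=4, birth=0.08, death=0.0)
        tree, _ = S.simulate_tree(cfg)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        V = A.scaled_vcv(tree, taxa)
        chol = np.linalg.cholesky(V + 1e-10 * np.eye(len(taxa)))
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = chol @ rng.standard_normal(len(taxa))
            lam = A.estimate_lambda(tree, dict(zip(taxa, y)))
            hits += 0.8 <= lam <= 1.0
        assert hits >= 90


class TestPredictTl:
    def test_degenerate_kriging_recovers_duplicated_tip(self):
        # fossil F sits at zero distance from extant E with the same head width
        tree = io.read_newick("(((E:0.001,F:0.001):9.999,B:10):5,(C:10,D:10):5);")
        pts = {"E": (30.0, 320.0), "B": (12.0, 150.0), "C": (50.0, 500.0), "D": (8.0, 90.0)}
        res = A.predict_tl(
            tree,
            records_from(pts),
            {"F": 30.0},
            mcmc=A.McmcConfig(n_iter=2000, burn_in=200, thin=2, seed=9),
            lam=1.0,
        )[0]
        assert res.mean_cm == pytest.approx(320.0, rel=0.01)
        assert res.q975_cm - res.q025_cm < 0.05 * res.mean_cm

    def test_mcmc_mean_matches_closed_form_gls(self, rng):
        tree = io.read_newick(
            "(((a:2,b:2):3,X:5):5,((c:4,d:4):2,(e:3,f:3):3):4);"
        )
        taxa = sorted("abcdef")
        hw = dict(zip(taxa, [10.0, 14.0, 20.0, 30.0, 45.0, 60.0]))
        tl = {t: 10 ** (1.0 + 0.9 * math.log10(h) + rng.normal(0, 0.03)) for t, h in hw.items()}
        pts = {t: (hw[t], tl[t]) for t in taxa}
        lam = 0.8
        res = A.predict_tl(
            tree,
            records_from(pts),
            {"X": 25.0},
            mcmc=A.McmcConfig(n_iter=20000, burn_in=2000, thin=5, seed=3),
            lam=lam,
        )[0]
        labels = taxa + ["X"]
        V = A.lambda_transform(A.scaled_vcv(tree, labels), lam)
        X = np.column_stack([np.ones(6), [math.log10(hw[t]) for t in taxa]])
        y = np.array([math.log10(tl[t]) for t in taxa])
        expected_log = gls_conditional_mean(X, y, [[1.0, math.log10(25.0)]], V, 6)[0]
        assert math.log10(res.mean_cm) == pytest.approx(expected_log, abs=0.01)

    def test_predictive_mean_monotone_in_head_width(self):
        tree = io.read_newick("(((a:2,b:2):3,F:5):5,((c:4,d:4):2,e:6):4);")
        pts = {"a": (10, 110), "b": (14, 150), "c": (20, 210), "d": (30, 320), "e": (45, 470)}
        mcfg = A.McmcConfig(n_iter=4000, burn_in=400, thin=2, seed=5)
        small = A.predict_tl(tree, records_from(pts), {"F": 20.0}, mcmc=mcfg, lam=0.9)[0]
        large = A.predict_tl(tree, records_from(pts), {"F": 60.0}, mcmc=mcfg, lam=0.9)[0]
        assert large.mean_cm > small.mean_cm

    def test_lambda0_mean_converges_to_ols_point_prediction(self):
        taxa = ["a", "b", "c", "d", "e"]
        tree = io.read_newick("(a:10,b:10,c:10,d:10,e:10,F:10);")
        pts = {"a": (10, 110), "b": (14, 150), "c": (20, 210), "d": (30, 320), "e": (45, 470)}
        res = A.predict_tl(
            tree,
            records_from(pts),
            {"F": 25.0},
            model_mode="OLS",
            mcmc=A.McmcConfig(n_iter=30000, burn_in=3000, thin=3, seed=7),
        )[0]
        ols = A.fit_regression(records_from(pts), mode="OLS")
        expected = ols.intercept + ols.slope * math.log10(25.0)
        assert math.log10(res.mean_cm) == pytest.approx(expected, abs=0.01)

    def test_quantile_ordering_and_positivity(self, rng):
        from paleocroc import synthetic_data as S

        cfg = S.SimConfig(n_taxa=10, seed=11)
        tree, _ = S.simulate_tree(cfg)
        recs, fossil_hw, _ = S.simulate_allometry(tree, cfg)
        res = A.predict_tl(
            tree, recs, fossil_hw,
            mcmc=A.McmcConfig(n_iter=1500, burn_in=300, thin=2, seed=2),
        )
        assert res
        for r in res:
            assert 0 < r.q025_cm <= r.mean_cm <= r.q975_cm
            assert r.ess > 50

    def test_missing_head_width_skipped_with_warning(self, caplog):
        tree = io.read_newick("((a:2,b:2):3,(c:4,F:4):1);")
        pts = {"a": (10, 110), "b": (14, 150), "c": (20, 210)}
        import logging

        with caplog.at_level(logging.WARNING):
            res = A.predict_tl(
                tree, records_from(pts), {"F": float("nan")},
                mcmc=A.McmcConfig(n_iter=100, burn_in=10, thin=1, seed=1),
            )
        assert res == []
        assert "no head width" in caplog.text

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            A.McmcConfig(n_iter=10, burn_in=10)
        with pytest.raises(ValueError):
            A.McmcConfig(thin=0)


class TestEffectiveSampleSize:
    def test_iid_draws_near_nominal(self, rng):
        x = rng.standard_normal(2000)
        ess = A.effective_sample_size(x)
        assert 1000 < ess <= 2600

    def test_autocorrelated_chain_reduced(self, rng):
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.95 * x[i - 1] + rng.standard_normal()
        assert A.effective_sample_size(x) < 500
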