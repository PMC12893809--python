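import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from shapely.geometry import box

from urbanrange.habitat import Raster
from urbanrange.maxent import (
    FeatureMap,
    FeatureSpec,
    auc_score,
    binarize_and_account,
    buffer_area_km2,
    cross_validate,
    fit_maxent,
    max_sss_threshold,
    penalized_objective,
    predict_features,
    sample_background,
)


def _toy_features(rng, n_pres=50, n_bg=500):
    bg = pd.DataFrame(rng.uniform(0, 1, (n_bg, 2)), columns=["a", "b"])
    pres = pd.DataFrame(rng.beta(3.0, 1.5, (n_pres, 2)), columns=["a", "b"])
    spec = FeatureSpec(classes=("linear", "quadratic", "product"))
    fm = FeatureMap.fit(pd.concat([pres, bg], ignore_index=True), spec)
    return fm.transform(pres), fm.transform(bg), fm


class TestSampleBackground:
    region = box(0, 0, 1000, 1000)
    water = [box(400, 400, 600, 600)]

    def test_ratio_ten_to_one(self):
        pts = sample_background(self.region, self.water, 20, ratio=10, seed=0)
        assert pts.shape == (200, 2)

    def test_outside_water(self):
        pts = sample_background(self.region, self.water, 30, seed=1)
        for x, y in pts:
            assert not (400 < x < 600 and 400 < y < 600)
            assert 0 <= x <= 1000 and 0 <= y <= 1000

    def test_deterministic_under_seed(self):
        a = sample_background(self.region, self.water, 15, seed=42)
        b = sample_background(self.region, self.water, 15, seed=42)
        assert np.array_equal(a, b)

    def test_empty_usable_area_errors(self):
        with pytest.raises(ValueError):
            sample_background(self.region, [self.region], 5, seed=0)


class TestFeatures:
    def test_minimum_maps_to_zero(self, rng):
        t = pd.DataFrame({"x": np.linspace(2.0, 8.0, 30)})
        fm = FeatureMap.fit(t, FeatureSpec(classes=("linear", "quadratic", "hinge"),
                                           hinge_knots_per_var=4))
        f = fm.transform(pd.DataFrame({"x": [2.0]}))
        lin_quad = f[0, :2]
        fwd = f[0, 2:6]
        assert np.allclose(lin_quad, 0.0)
        assert np.allclose(fwd, 0.0)  # forward hinges vanish at the minimum

    def test_hinge_value_at_half_knot(self):
        t = pd.DataFrame({"x": [0.0, 1.0]})
        fm = FeatureMap.fit(t, FeatureSpec(classes=("hinge",), hinge_knots_per_var=3),
                            indicator_cols=[])
        f = fm.transform(pd.DataFrame({"x": [0.75]}))
        # knots at 0.25/0.5/0.75: forward hinge at 0.5 = (0.75-0.5)/(1-0.5) = 0.5
        assert f[0, 1] == pytest.approx(0.5)
        assert f[0, 2] == pytest.approx(0.0)  # forward at 0.75
        assert np.allclose(f[0, 3:], [0.0, 0.0, 0.0])  # reverse hinges vanish

    def test_product_feature_count(self, rng):
        p = 4
        t = pd.DataFrame(rng.uniform(0, 1, (20, p)), columns=[f"v{i}" for i in range(p)])
        fm = FeatureMap.fit(t, FeatureSpec(classes=("product",)))
        assert fm.transform(t).shape[1] == math.comb(p, 2)

    def test_indicator_passthrough(self, rng):
        t = pd.DataFrame({"x": rng.uniform(0, 1, 40),
                          "h_1": rng.integers(0, 2, 40).astype(float)})
        fm = FeatureMap.fit(t, FeatureSpec(classes=("linear", "quadratic")))
        assert fm.indicator == ["h_1"]
        f = fm.transform(t)
        assert np.array_equal(f[:, -1], t["h_1"].to_numpy())

    def test_zero_variance_dropped(self, rng, caplog):
        import logging

        t = pd.DataFrame({"x": rng.uniform(0, 1, 20), "k": np.full(20, 2.0)})
        with caplog.at_level(logging.WARNING, logger="urbanrange.maxent"):
            fm = FeatureMap.fit(t, FeatureSpec(classes=("linear",)))
        assert fm.continuous == ["x"]


class TestFitMaxent:
    def test_no_signal_gives_zero_lambda(self, rng):
        f = rng.integers(0, 2, (600, 1)).astype(float)
        pres, bg = f[:100], f  # identical means by construction? enforce:
        pres = f[:100]
        # make presence mean match background mean exactly
        target = f.mean()
        k = int(round(target * 100))
        pres = np.vstack([np.ones((k, 1)), np.zeros((100 - k, 1))])
        model = fit_maxent(pres, f, 1.0)
        assert abs(model.lam[0]) < 1e-6

    def test_objective_matches_convex_solver_oracle(self, rng):
        fp, fb, _ = _toy_features(rng)
        model = fit_maxent(fp, fb, 1.0)
        betas = model.betas
        J = fp.shape[1]

        def neg(ab):
            lam = ab[:J] - ab[J:]
            return -(penalized_objective(lam, fp, fb, np.zeros(J))
                     - float(np.sum(betas * (ab[:J] + ab[J:]))))

        res = optimize.minimize(neg, np.zeros(2 * J), method="L-BFGS-B",
                                bounds=[(0, None)] * (2 * J),
                                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 10000})
        assert model.objective == pytest.approx(-res.fun, abs=1e-4)

    def test_l1_norm_monotone_in_multiplier(self, rng):
        fp, fb, _ = _toy_features(rng)
        l1 = [np.abs(fit_maxent(fp, fb, m).lam).sum() for m in (1, 2, 3, 4, 5)]
        assert all(a >= b - 1e-9 for a, b in zip(l1, l1[1:]))

    def test_gain_non_increasing_in_multiplier(self, rng):
        fp, fb, _ = _toy_features(rng)
        gains = []
        for m in (1, 2, 3, 4, 5):
            model = fit_maxent(fp, fb, m)
            gains.append(penalized_objective(model.lam, fp, fb, np.zeros_like(model.lam)))
        assert all(a >= b - 1e-9 for a, b in zip(gains, gains[1:]))

    def test_objective_at_least_origin(self, rng):
        fp, fb, _ = _toy_features(rng)
        for m in (1, 3, 5):
            model = fit_maxent(fp, fb, m)
            assert model.objective >= penalized_objective(
                np.zeros_like(model.lam), fp, fb, model.betas) - 1e-12

    def test_too_few_presences(self, rng):
        fp, fb, _ = _toy_features(rng, n_pres=3)
        with pytest.raises(ValueError):
            fit_maxent(fp[:3], fb, 1.0)


class TestPredict:
    def test_zero_lambda_uniform_raw(self, rng):
        fp, fb, _ = _toy_features(rng)
        model = fit_maxent(fp, fb, 100.0)  # heavy penalty -> lambda = 0
        assert np.allclose(model.lam, 0.0)
        raw = predict_features(model, fb)
        assert np.allclose(raw, 1.0 / len(fb))

    def test_raw_sums_to_one_over_background(self, rng):
        fp, fb, _ = _toy_features(rng)
        model = fit_maxent(fp, fb, 1.0)
        assert predict_features(model, fb).sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_monotone_in_raw(self, rng):
        fp, fb, _ = _toy_features(rng)
        model = fit_maxent(fp, fb, 1.0)
        raw = predict_features(model, fb)
        logi = predict_features(model, fb, output="logistic")
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) >= -1e-15)

    def test_auc_invariant_under_monotone_transform(self, rng):
        p = rng.uniform(0.2, 1.0, 40)
        b = rng.uniform(0.0, 0.8, 200)
        a1 = auc_score(p, b)
        a2 = auc_score(np.log(p + 1), np.log(b + 1))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAucOracle:
    def test_matches_brute_force_mann_whitney(self, rng):
        pres = np.round(rng.uniform(0, 1, 12), 1)  # induces ties
        bg = np.round(rng.uniform(0, 1, 18), 1)
        wins = 0.0
        for p, b in itertools.product(pres, bg):
            if p > b:
                wins += 1.0
            elif p == b:
                wins += 0.5
        assert auc_score(pres, bg) == pytest.approx(wins / (len(pres) * len(bg)), abs=1e-12)


class TestMaxSss:
    def test_perfect_separation(self):
        thr, sens, spec = max_sss_threshold(np.array([0.8, 0.9]), np.array([0.1, 0.2]))
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        pres = rng.uniform(0, 1, 10)
        bg = rng.uniform(0, 1, 10)
        thr, sens, spec = max_sss_threshold(pres, bg)
        best = -1.0
        best_thr = None
        for cand in sorted(np.concatenate([pres, bg])):
            s1 = np.mean(pres >= cand)
            s2 = np.mean(bg < cand)
            if s1 + s2 > best + 1e-12:
                best = s1 + s2
                best_thr = cand
        assert thr == pytest.approx(best_thr)
        assert sens + spec == pytest.approx(best)

    def test_degenerate_equal_predictions(self):
        thr, sens, spec = max_sss_threshold(np.full(5, 0.4), np.full(7, 0.4))
        assert sens + spec - 1.0 == pytest.approx(0.0)


class TestCrossValidate:
    def _tables(self, seed, n_pres=60):
        rng = np.random.default_rng(seed)
        bg = pd.DataFrame({"tree": rng.uniform(0, 100, n_pres * 10)})
        # presence sampled by a logistic suitability in tree cover
        cand = rng.uniform(0, 100, 20000)
        p = 1 / (1 + np.exp(-(cand - 60) / 8.0))
        keep = rng.random(len(cand)) < p
        pres = pd.DataFrame({"tree": cand[keep][:n_pres]})
        return pres, bg

    def test_recovers_signal(self):
        pres, bg = self._tables(0)
        model, best, results = cross_validate(
            pres, bg, k=5, seed=1, hinge_knots=6, multipliers=(1, 2),
            combos={"H": ("hinge",)}, tol=1e-4,
        )
        assert best.auc > 0.7
        assert len(results) == 2

    def test_shuffled_labels_auc_near_half(self):
        aucs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            pool = rng.uniform(0, 100, 660)
            pres = pd.DataFrame({"tree": pool[:60]})
            bg = pd.DataFrame({"tree": pool[60:]})
            _, best, _ = cross_validate(pres, bg, k=5, seed=seed, hinge_knots=6,
                                        multipliers=(1,), combos={"H": ("hinge",)},
                                        tol=1e-4)
            aucs.append(best.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_shared_folds_and_tiebreaks(self):
        pres, bg = self._tables(3)
        _, best, results = cross_validate(
            pres, bg, k=5, seed=2, hinge_knots=4, multipliers=(1, 2),
            combos={"H": ("hinge",), "HP": ("hinge", "product")}, tol=1e-4,
        )
        top = max(r.auc for r in results)
        contenders = [r for r in results if r.auc == top]
        assert best in contenders


class TestBinarize:
    def _suit(self, vals, cell=50.0):
        vals = np.asarray(vals, dtype=float)
        return Raster((0.0, vals.shape[0] * cell), cell, vals)

    def test_nest_buffer_close_to_pi_km2(self):
        n = 100
        suit = self._suit(np.ones((n, n)))
        nest = np.array([[2525.0, 2525.0]])  # on a cell centre
        _, report = binarize_and_account(suit, 0.5, occupied_nests=nest)
        excluded = report.total_suitable_km2 - report.unoccupied_suitable_km2
        assert abs(excluded / math.pi - 1.0) < 0.01
        assert buffer_area_km2(1000.0, 50.0) == pytest.approx(excluded, rel=1e-9)

    def test_threshold_above_max_gives_zero(self, rng):
        suit = self._suit(rng.uniform(0, 1, (20, 20)))
        _, report = binarize_and_account(suit, 1.5)
        assert report.total_suitable_km2 == 0.0

    def test_per_class_matches_brute_force(self, rng):
        vals = rng.uniform(0, 1, (30, 30))
        suit = self._suit(vals)
        hab = Raster(suit.origin, suit.cell_size, rng.integers(0, 4, (30, 30)),
                     kind="categorical")
        thr = 0.6
        binary, report = binarize_and_account(suit, thr, habitat=hab)
        cell_km2 = (50.0 / 1000.0) ** 2
        for code in range(4):
            expected = np.sum((vals >= thr) & (hab.values == code)) * cell_km2
            assert report.by_habitat_class_km2[code] == pytest.approx(expected)
        assert sum(report.by_habitat_class_km2.values()) == pytest.approx(
            report.total_suitable_km2)
        assert np.array_equal(binary.values.astype(bool), vals >= thr)

    def test_mask_polygons_exclude(self, rng):
        suit = self._suit(np.ones((10, 10)))
        mask = [box(0, 0, 250, 500)]  # 50 cells
        _, report = binarize_and_account(suit, 0.5, mask_polygons=mask)
        assert report.total_suitable_km2 == pytest.approx((100 - 50) * 0.0025)

    def test_grid_mismatch_errors(self, rng):
        suit = self._suit(np.ones((10, 10)))
        hab = Raster((0.0, 100.0), 10.0, np.zeros((10, 10), dtype=np.int64),
                     kind="categorical")
        with pytest.raises(ValueError):
            binarize_and_account(suit, 0.5, habitat=hab)
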