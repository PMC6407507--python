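import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipsexp.grid import GridSpec
from ipsexp import synthgen
from ipsexp.sdm import (
    FeatureSet,
    SuitabilityModel,
    build_hinge_features,
    cross_validate,
    fit_maxent,
    sample_background,
)
from ipsexp.sdm.features import VariableFeatures


class TestSampleBackground:
    def test_uniform_limit_gof(self):
        """bandwidth=None -> uniform over eligible pixels (chi-square, α=0.01)."""
        grid = GridSpec(120, 160)
        occ = pd.DataFrame({"lon": [], "lat": []})
        bg = sample_background(occ, grid, n_max=10_000, bias_bandwidth=None, seed=0)
        block = (bg.rows // 40) * 4 + (bg.cols // 40)
        observed = np.bincount(block, minlength=12)
        res = stats.chisquare(observed)  # equal expected counts
        assert res.pvalue > 0.01

    def test_bias_concentrates_near_occurrences(self):
        grid = GridSpec(40, 60, cell_size=0.5)
        rng = np.random.default_rng(1)
        # occurrences confined to the south-west quadrant
        lon = grid.origin_lon + rng.uniform(0, 15, 200)
        lat = grid.origin_lat + rng.uniform(0, 5, 200)
        occ = pd.DataFrame({"lon": lon, "lat": lat})
        bg = sample_background(occ, grid, n_max=500, bias_bandwidth=2.0, seed=2)
        in_quadrant = (bg.rows < 20) & (bg.cols < 30)
        assert in_quadrant.mean() > 0.8

    def test_nmax_exceeds_grid(self):
        grid = GridSpec(5, 5)
        occ = pd.DataFrame({"lon": [], "lat": []})
        with pytest.warns(UserWarning, match="taking all"):
            bg = sample_background(occ, grid, n_max=100, seed=0)
        assert bg.n == 25
        assert len({(r, c) for r, c in zip(bg.rows, bg.cols)}) == 25

    def test_no_repeats_and_determinism(self):
        grid = GridSpec(30, 30)
        occ = pd.DataFrame({"lon": [5.0], "lat": [5.0]})
        a = sample_background(occ, grid, n_max=200, bias_bandwidth=3.0, seed=7)
        b = sample_background(occ, grid, n_max=200, bias_bandwidth=3.0, seed=7)
        assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)
        assert len({(r, c) for r, c in zip(a.rows, a.cols)}) == a.n


class TestHingeFeatures:
    def test_hinges_vanish_at_knot(self):
        vf = VariableFeatures("Bio1", vmin=0.0, vmax=10.0, knots=np.array([4.0]))
        row = vf.transform(np.array([4.0]))[0]
        # columns: linear, left hinge at 4, right hinge at 4
        assert row[1] == 0.0 and row[2] == 0.0

    def test_left_hinge_at_max_is_one(self):
        vf = VariableFeatures("Bio1", vmin=0.0, vmax=10.0, knots=np.array([3.0, 7.0]))
        row = vf.transform(np.array([10.0]))[0]
        assert row[1] == 1.0 and row[2] == 1.0  # both left hinges

    def test_design_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 5, 200)
        fs = build_hinge_features(x[:, None], ["Bio1"], n_knots_per_variable=5)
        design = fs.transform(x[:, None])
        vf = fs.variables[0]
        expected = [(np.clip(x, vf.vmin, vf.vmax) - vf.vmin) / (vf.vmax - vf.vmin)]
        for k in vf.knots:
            expected.append(np.maximum(0.0, (np.clip(x, vf.vmin, vf.vmax) - k) / (vf.vmax - k)))
        for k in vf.knots:
            expected.append(np.maximum(0.0, (k - np.clip(x, vf.vmin, vf.vmax)) / (k - vf.vmin)))
        np.testing.assert_allclose(design, np.stack(expected, axis=1), atol=1e-12)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 2)) * 10
        fs = build_hinge_features(x, ["Bio1", "Bio4"], n_knots_per_variable=8)
        design = fs.transform(x)
        assert design.min() >= 0.0 and design.max() <= 1.0

    def test_knots_strictly_increasing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        fs = build_hinge_features(x[:, None], ["Bio1"], n_knots_per_variable=10)
        knots = fs.variables[0].knots
        assert (np.diff(knots) > 0).all()

    def test_constant_variable_warns(self):
        x = np.ones((50, 1))
        with pytest.warns(UserWarning, match="constant"):
            fs = build_hinge_features(x, ["Bio1"], n_knots_per_variable=5)
        assert fs.n_features == 0


def _toy_fit(seed=0, n_pres=200, n_bg=1000, beta=1.5):
    rng = np.random.default_rng(seed)
    bg = rng.uniform(0, 10, n_bg)
    pres = np.clip(rng.normal(7, 1, n_pres), 0, 10)
    fs = build_hinge_features(np.concatenate([pres, bg])[:, None], ["Bio1"], 8)
    model = fit_maxent(fs.transform(pres[:, None]), fs.transform(bg[:, None]), fs, beta=beta)
    return model, fs, pres, bg


class TestFitMaxent:
    def test_huge_beta_gives_uniform(self):
        model, _, _, bg = _toy_fit(beta=1e6)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-8)
        np.testing.assert_allclose(model.entropy, np.log(bg.size), atol=1e-6)
        logistic = model.logistic_from_raw(model.bg_raw_sorted)
        np.testing.assert_allclose(logistic, 0.5, atol=1e-6)

    def test_objective_not_worse_than_zero(self):
        model, fs, pres, bg = _toy_fit()
        Fp, Fb = fs.transform(pres[:, None]), fs.transform(bg[:, None])
        m = Fp.shape[0]
        reg = model.beta * np.maximum(Fp.std(axis=0), 1e-4) / np.sqrt(m)

        def obj(lam):
            eta = Fb @ lam
            from scipy.special import logsumexp
            return logsumexp(eta) - Fp.mean(axis=0) @ lam + reg @ np.abs(lam)

        assert obj(model.weights) <= obj(np.zeros_like(model.weights)) + 1e-12

    def test_monotone_trace(self):
        model, *_ = _toy_fit()
        trace = model.trace
        assert trace.size > 1
        assert (np.diff(trace) <= 1e-9).all()

    def test_raw_sums_to_one(self):
        model, *_ = _toy_fit()
        assert abs(model.bg_raw_sorted.sum() - 1.0) < 1e-9

    def test_recovers_single_hinge_gibbs_density(self):
        """Presences from a known single-hinge Gibbs density: fitted raw
        rank-correlates with truth at ρ >= 0.95 (n=1,000)."""
        rng = np.random.default_rng(42)
        bg = rng.uniform(0, 10, 2000)
        hinge = np.maximum(0.0, (bg - 5.0) / 5.0)
        q_true = np.exp(3.0 * hinge)
        q_true /= q_true.sum()
        pres_idx = rng.choice(bg.size, size=1000, replace=True, p=q_true)
        pres = bg[pres_idx]
        fs = build_hinge_features(np.concatenate([pres, bg])[:, None], ["Bio1"], 20)
        model = fit_maxent(fs.transform(pres[:, None]), fs.transform(bg[:, None]), fs)
        raw = model.raw_from_values(bg[:, None])
        rho = stats.spearmanr(raw, q_true).statistic
        assert rho >= 0.95

    def test_rejects_bad_shapes(self):
        fs = FeatureSet([])
        with pytest.raises(ValueError):
            fit_maxent(np.zeros((0, 2)), np.zeros((5, 2)), fs)
        with pytest.raises(ValueError):
            fit_maxent(np.zeros((3, 2)), np.zeros((5, 3)), fs)


def _manual_model(bg_raw, entropy=None):
    bg_raw = np.sort(np.asarray(bg_raw, dtype=float))
    h = entropy if entropy is not None else float(-np.sum(bg_raw * np.log(bg_raw)))
    return SuitabilityModel(
        featureset=FeatureSet([]),
        weights=np.empty(0),
        beta=1.5,
        log_z=0.0,
        entropy=h,
        bg_raw_sorted=bg_raw,
        bg_raw_cumsum=np.cumsum(bg_raw),
    )


class TestPredict:
    def test_cumulative_toy_example(self):
        model = _manual_model([0.1, 0.1, 0.2, 0.25, 0.35])
        out = model.cumulative_from_raw(np.array([0.1, 0.1, 0.2, 0.25, 0.35]))
        np.testing.assert_allclose(out, [20.0, 20.0, 40.0, 65.0, 100.0], atol=1e-12)

    def test_uniform_model_constant_logistic(self, stack_small):
        values, _, _ = stack_small.to_matrix()
        fs = build_hinge_features(values, stack_small.codes, 5)
        model = fit_maxent(fs.transform(values[:5]), fs.transform(values), fs, beta=1e9)
        logistic = model.predict(stack_small, "logistic")
        vals = logistic[stack_small.grid.valid_mask]
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)
        cumulative = model.predict(stack_small, "cumulative")
        assert cumulative[stack_small.grid.valid_mask].max() == pytest.approx(100.0)

    def test_logistic_strictly_increasing_in_raw(self):
        model = _manual_model(np.linspace(0.01, 0.1, 10) / np.linspace(0.01, 0.1, 10).sum())
        raws = np.linspace(1e-6, 1e-2, 50)
        log = model.logistic_from_raw(raws)
        assert (np.diff(log) > 0).all()

    def test_missing_variable_rejected(self, stack_small):
        values, _, _ = stack_small.to_matrix()
        fs = build_hinge_features(values, stack_small.codes, 4)
        model = fit_maxent(fs.transform(values[:10]), fs.transform(values), fs)
        with pytest.raises(ValueError, match="missing"):
            model.predict(stack_small.subset(["Bio1", "Bio4"]))

    def test_serialisation_roundtrip(self, tmp_path):
        model, _, _, bg = _toy_fit()
        model.to_json(tmp_path / "m.json")
        back = SuitabilityModel.from_json(tmp_path / "m.json")
        x = np.linspace(0, 10, 50)[:, None]
        np.testing.assert_allclose(back.raw_from_values(x), model.raw_from_values(x), rtol=1e-12)


class TestCrossValidate:
    def test_fold_sizes_k2(self, stack_small):
        occ = pd.DataFrame(
            {
                "species": ["s"] * 4,
                "lon": [1.1, 3.1, 5.1, 7.1],
                "lat": [31.1, 32.1, 33.1, 34.1],
            }
        )
        cv = cross_validate(occ, stack_small, k=2, seed=0, n_background=100, n_knots=3)
        sizes = sorted(len(t) for _, t in cv.folds)
        assert sizes == [2, 2]
        for train, test in cv.folds:
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 4

    def test_k1_and_k_too_large_rejected(self, stack_small):
        occ = pd.DataFrame({"species": ["s"] * 3, "lon": [1.1, 3.1, 5.1], "lat": [31.1] * 3})
        with pytest.raises(ValueError):
            cross_validate(occ, stack_small, k=1)
        with pytest.raises(ValueError):
            cross_validate(occ, stack_small, k=5, n_background=100)

    def test_partition_deterministic(self, strong_world):
        from ipsexp.sdm.cv import _partition

        a = _partition(100, 10, seed=3)
        b = _partition(100, 10, seed=3)
        for (t1, s1), (t2, s2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(s1, s2)

    def test_mean_map_is_fold_mean(self, strong_world):
        cv = strong_world["cv"]
        recombined = np.mean([m.predict(strong_world["stack"], "logistic") for m in cv.models], axis=0)
        np.testing.assert_allclose(cv.mean_logistic, recombined, atol=1e-12)

    def test_projection_onto_identical_stack_bitwise(self, strong_world):
        cv = strong_world["cv"]
        model = cv.models[0]
        a = model.predict(strong_world["stack"], "logistic")
        b = model.predict(strong_world["stack"].copy(), "logistic")
        assert np.array_equal(a, b, equal_nan=True)

    def test_raw_map_sums_to_one_over_background(self, strong_world):
        cv = strong_world["cv"]
        bg = cv.background
        for model in cv.models:
            raw_map = model.predict(strong_world["stack"], "raw")
            assert abs(raw_map[bg.rows, bg.cols].sum() - 1.0) < 1e-9

    def test_suitability_recovery(self, strong_world):
        """Averaged logistic suitability tracks true occupancy (ρ >= 0.8)."""
        truth = strong_world["niche"].occupancy(strong_world["stack"])
        rho = stats.spearmanr(
            strong_world["cv"].mean_logistic.ravel(), truth.ravel()
        ).statistic
        assert rho >= 0.8
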