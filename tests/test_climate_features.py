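import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipsexp.grid import GridSpec
from ipsexp import synthgen
from ipsexp.climate_features import (
    biome_change_summary,
    jackknife_importance,
    mean_importance,
    potential_vs_change_regression,
    select_top_variables,
    variable_change,
)
from ipsexp.regions import TERRESTRIAL_BIOMES
from ipsexp.synthgen import NicheSpec, ScenarioDelta


def _species_data(niche, stack, n=150, n_bg=800, seed=0):
    occ = synthgen.sample_occurrences(niche, stack, n, seed=seed)
    grid = stack.grid
    r, c = grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    rng = np.random.default_rng(seed + 1)
    rows, cols = np.nonzero(grid.valid_mask)
    pick = rng.choice(rows.size, size=n_bg, replace=False)
    codes = stack.codes
    return stack.values_at(r, c, codes), stack.values_at(rows[pick], cols[pick], codes), codes


@pytest.fixture(scope="module")
def driver_world():
    grid = GridSpec(50, 75, origin_lat=30.0)
    # independent fields so Bio1 is not mirrored by Bio5/Bio6
    stack = synthgen.generate_climate(grid, seed=21, consistent=False)
    return grid, stack


class TestJackknifeImportance:
    def test_single_driver_dominates(self, driver_world):
        grid, stack = driver_world
        b1 = stack.layers["Bio1"][grid.valid_mask]
        niche = NicheSpec(
            "sp", "herb", optimum={"Bio1": float(np.quantile(b1, 0.5))}, breadth={"Bio1": 0.8}
        )
        pres, bg, codes = _species_data(niche, stack)
        imp = jackknife_importance(pres, bg, codes, n_knots=5, with_only=False)
        assert imp.loc["Bio1", "percent"] > 90.0

    def test_percents_sum_to_100(self, driver_world):
        grid, stack = driver_world
        b1 = stack.layers["Bio1"][grid.valid_mask]
        niche = NicheSpec(
            "sp", "herb", optimum={"Bio1": float(np.quantile(b1, 0.4))}, breadth={"Bio1": 1.5}
        )
        pres, bg, codes = _species_data(niche, stack, seed=2)
        imp = jackknife_importance(pres, bg, codes, n_knots=4, with_only=False)
        assert imp["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp["percent"] >= 0).all()

    def test_duplicate_drivers_near_equal(self):
        """Two exchangeable copies of the driver split the importance."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 3000)
        bg = np.stack([x, x + rng.normal(0, 1e-6, x.size)], axis=1)  # Bio1 ~ Bio2
        w = np.exp(-0.5 * ((x - 7) / 0.8) ** 2)
        idx = rng.choice(x.size, size=400, replace=False, p=w / w.sum())
        pres = bg[idx]
        imp = jackknife_importance(pres, bg, ["Bio1", "Bio2"], n_knots=6, with_only=False)
        # dropping either variable barely hurts: contributions are near-equal
        assert abs(imp.loc["Bio1", "percent"] - imp.loc["Bio2", "percent"]) < 20.0

    def test_single_variable_trivial(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(0, 10, 500)[:, None]
        pres = np.clip(rng.normal(7, 1, 100), 0, 10)[:, None]
        imp = jackknife_importance(pres, bg, ["Bio1"], n_knots=5)
        assert imp.loc["Bio1", "percent"] == pytest.approx(100.0)

    def test_affine_rescaling_invariance(self, driver_world):
        """Quantile-based knots make importance invariant to affine rescaling."""
        grid, stack = driver_world
        b1 = stack.layers["Bio1"][grid.valid_mask]
        niche = NicheSpec(
            "sp", "herb", optimum={"Bio1": float(np.quantile(b1, 0.5))}, breadth={"Bio1": 1.0}
        )
        pres, bg, codes = _species_data(niche, stack, seed=5)
        imp1 = jackknife_importance(pres, bg, codes, n_knots=4, with_only=False)
        j = codes.index("Bio1")
        pres2, bg2 = pres.copy(), bg.copy()
        pres2[:, j] = 3.0 * pres2[:, j] + 100.0
        bg2[:, j] = 3.0 * bg2[:, j] + 100.0
        imp2 = jackknife_importance(pres2, bg2, codes, n_knots=4, with_only=False)
        np.testing.assert_allclose(imp1["percent"], imp2["percent"], atol=0.5)


class TestSelectTopVariables:
    def _imp(self, mapping):
        return pd.DataFrame({"mean_percent": pd.Series(mapping)})

    def test_concentrated_selection(self):
        imp = self._imp({"Bio1": 45.0, "Bio4": 40.0, "Bio2": 10.0, "Bio12": 5.0})
        assert select_top_variables(imp, k=2) == ["Bio1", "Bio4"]

    def test_k_equals_n_identity_ordering(self):
        imp = self._imp({"Bio1": 50.0, "Bio2": 30.0, "Bio4": 20.0})
        assert select_top_variables(imp, k=3) == ["Bio1", "Bio2", "Bio4"]

    def test_tie_break_canonical_order(self):
        imp = self._imp({"Bio4": 50.0, "Bio1": 50.0})
        assert select_top_variables(imp, k=1) == ["Bio1"]

    def test_species_permutation_invariance(self):
        a = pd.DataFrame({"percent": pd.Series({"Bio1": 80.0, "Bio4": 20.0})})
        b = pd.DataFrame({"percent": pd.Series({"Bio1": 20.0, "Bio4": 80.0})})
        m1 = mean_importance({"s1": a, "s2": b})
        m2 = mean_importance({"s2": b, "s1": a})
        assert select_top_variables(m1) == select_top_variables(m2)


class TestVariableChange:
    def test_identity_scenario_zero(self, stack_small):
        regions = synthgen.generate_ecoregions(stack_small.grid, 6, TERRESTRIAL_BIOMES, seed=2)
        out = variable_change(stack_small, stack_small, regions, "Bio1")
        np.testing.assert_allclose(out["cv"], 0.0, atol=1e-12)

    def test_uniform_shift(self, stack_small):
        regions = synthgen.generate_ecoregions(stack_small.grid, 6, TERRESTRIAL_BIOMES, seed=2)
        future = synthgen.apply_scenario(stack_small, ScenarioDelta("RCP4.5", {"Bio1": 2.0}))
        out = variable_change(stack_small, future, regions, "Bio1")
        np.testing.assert_allclose(out["cv"], 2.0, atol=1e-9)

    def test_matches_masked_mean_oracle(self, stack_small):
        regions = synthgen.generate_ecoregions(stack_small.grid, 12, TERRESTRIAL_BIOMES, seed=3)
        rng = np.random.default_rng(6)
        delta = rng.normal(size=stack_small.grid.shape)
        future = synthgen.apply_scenario(stack_small, ScenarioDelta("RCP4.5", {"Bio1": delta}))
        out = variable_change(stack_small, future, regions, "Bio1").set_index("ecoregion_id")
        for rid in regions.region_ids:
            mask = regions.labels == rid
            expected = future.layers["Bio1"][mask].mean() - stack_small.layers["Bio1"][mask].mean()
            assert out.loc[rid, "cv"] == pytest.approx(expected, abs=1e-9)


def _potential_table(cvs, biome="TBMF", noise=0.0, slope=3.0, seed=0):
    rng = np.random.default_rng(seed)
    n = len(cvs)
    return pd.DataFrame(
        {
            "ecoregion_id": np.arange(n),
            "biome": [biome] * n,
            "realm": ["terrestrial"] * n,
            "potential": slope * np.asarray(cvs) + noise * rng.normal(size=n),
            "included": [True] * n,
        }
    )


def _cv_frame(cvs):
    return pd.DataFrame(
        {"ecoregion_id": np.arange(len(cvs)), "cv": cvs, "variable": "Bio1"}
    )


class TestPotentialVsChangeRegression:
    def test_noiseless_r2_one(self):
        cvs = np.linspace(0.5, 3.0, 10)
        out = potential_vs_change_regression(_potential_table(cvs), _cv_frame(cvs))
        assert out.iloc[0]["r2"] == pytest.approx(1.0)
        assert out.iloc[0]["flag"] == "ok"

    def test_four_point_closed_form(self):
        pot = _potential_table([0.0] * 4)
        pot["potential"] = [2.0, 3.0, 5.0, 6.0]
        cvf = _cv_frame([1.0, 2.0, 3.0, 4.0])
        out = potential_vs_change_regression(pot, cvf)
        assert out.iloc[0]["r2"] == pytest.approx(0.98)
        assert out.iloc[0]["slope"] == pytest.approx(1.4)
        assert out.iloc[0]["p"] == pytest.approx(0.01005, abs=2e-5)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for i in range(200):
            cvs = rng.normal(size=100)
            pot = _potential_table(cvs, slope=0.0, noise=1.0, seed=i)
            ps.append(potential_vs_change_regression(pot, _cv_frame(cvs)).iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_too_few_flagged(self):
        cvs = [1.0, 2.0]
        out = potential_vs_change_regression(_potential_table(cvs), _cv_frame(cvs))
        assert out.iloc[0]["flag"] == "too_few"
        assert np.isnan(out.iloc[0]["r2"])

    def test_zero_variance_flagged(self):
        cvs = [1.0, 1.0, 1.0, 1.0]
        out = potential_vs_change_regression(_potential_table(cvs), _cv_frame(cvs))
        assert out.iloc[0]["flag"] == "zero_variance"

    def test_planted_slope_coverage(self):
        """|slope_hat − β| <= 2 SE in >= 93% of 200 simulations."""
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=30)
            y = 3.0 * x + rng.normal(size=30)
            res = stats.linregress(x, y)
            hits += abs(res.slope - 3.0) <= 2 * res.stderr
        assert hits / 200 >= 0.93


class TestBiomeChangeSummary:
    def test_single_included_sd_undefined(self):
        pot = _potential_table([1.0, 2.0], biome="TD")
        pot.loc[1, "included"] = False
        out = biome_change_summary(_cv_frame([1.0, 2.0]), pot)
        assert out.iloc[0]["n"] == 1
        assert out.iloc[0]["mean"] == pytest.approx(1.0)
        assert np.isnan(out.iloc[0]["sd"])

    def test_identical_cvs_sd_zero(self):
        pot = _potential_table([2.0, 2.0, 2.0])
        out = biome_change_summary(_cv_frame([2.0, 2.0, 2.0]), pot)
        assert out.iloc[0]["sd"] == pytest.approx(0.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        cvs = rng.normal(size=20)
        pot = _potential_table(cvs)
        out = biome_change_summary(_cv_frame(cvs), pot)
        assert out.iloc[0]["mean"] == pytest.approx(cvs.mean())
        assert out.iloc[0]["sd"] == pytest.approx(cvs.std(ddof=1))
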