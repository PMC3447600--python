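import numpy as np
import pandas as pd
import pytest

from ecoca.engine import (
    ConstraintMask,
    ScenarioConfig,
    build_constraints,
    neighborhood_share,
    neighborhood_share_map,
    run_scenario,
    stochastic_factor,
    synthesis_probability,
)
from ecoca.grid import DEFAULT_SCHEME, LandUseGrid
from ecoca.markov import MacroTargets
from ecoca.suitability import theil_normalize


def _grid(values):
    return LandUseGrid(np.asarray(values, dtype=np.int64))


class TestNeighborhoodShare:
    def test_interior_all_like(self):
        g = _grid(np.full((5, 5), 3))
        assert neighborhood_share(g, (2, 2), 3) == 1.0

    def test_interior_hand_count(self):
        v = np.ones((3, 3), dtype=np.int64)
        v[0, 0] = v[0, 1] = v[1, 0] = 2
        g = _grid(v)
        assert neighborhood_share(g, (1, 1), 2) == pytest.approx(3 / 8)

    def test_corner_uses_in_bounds_neighbors(self):
        v = np.ones((4, 4), dtype=np.int64)
        v[0, 1] = v[1, 0] = v[1, 1] = 3
        g = _grid(v)
        assert neighborhood_share(g, (0, 0), 3) == 1.0

    def test_map_version_agrees_with_scalar(self, rng):
        v = rng.choice([1, 2, 3, 4], size=(12, 12)).astype(np.int64)
        g = _grid(v)
        omega = neighborhood_share_map(v, 2)
        for r in range(12):
            for c in range(12):
                assert omega[r, c] == pytest.approx(neighborhood_share(g, (r, c), 2))

    def test_center_excluded(self):
        v = np.full((3, 3), 1, dtype=np.int64)
        v[1, 1] = 2
        assert neighborhood_share(_grid(v), (1, 1), 2) == 0.0


class TestStochasticFactor:
    @pytest.mark.parametrize("alpha", range(1, 11))
    def test_gamma_e_inverse_gives_two(self, alpha):
        assert stochastic_factor(np.exp(-1.0), alpha) == pytest.approx(2.0)

    def test_gamma_near_one_limit(self):
        assert stochastic_factor(1 - 1e-12, 3) == pytest.approx(1.0, abs=1e-6)

    def test_worked_value(self):
        assert stochastic_factor(np.exp(-2.0), 3) == pytest.approx(9.0)

    @pytest.mark.parametrize("gamma", [0.0, 1.0, -0.5, 1.5])
    def test_domain_enforced(self, gamma):
        with pytest.raises(ValueError):
            stochastic_factor(gamma, 2)

    def test_alpha_range_enforced(self):
        with pytest.raises(ValueError):
            stochastic_factor(0.5, 0)
        with pytest.raises(ValueError):
            stochastic_factor(0.5, 11)

    def test_always_at_least_one(self, rng):
        g = rng.uniform(1e-9, 1 - 1e-9, 1000)
        assert np.all(stochastic_factor(g, 4) >= 1.0)


class TestBuildConstraints:
    def test_natural_development_only_basic_farmland(self, small_bundle):
        con = build_constraints("natural_development", small_bundle.masks)
        bf = small_bundle.masks["basic_farmland"]
        assert np.all(con.base[bf] == 0)
        water_only = small_bundle.masks["water"] & ~bf
        assert np.all(con.base[water_only] == 1)

    def test_object_orientation_union(self, small_bundle):
        con = build_constraints("object_orientation", small_bundle.masks)
        zero = small_bundle.masks["basic_farmland"] | small_bundle.masks["water"]
        assert np.count_nonzero(con.base == 0) == np.count_nonzero(zero)
        assert np.all(con.base[zero] == 0)

    def test_ecosystem_priority_protects_all_ecological(self, small_bundle, scheme):
        con = build_constraints("ecosystem_priority", small_bundle.masks, small_bundle.map_t0)
        eco = small_bundle.map_t0.values == scheme.code("ecological")
        assert np.all(con.base[eco] == 0)
        steep = small_bundle.masks["steep_slope"]
        assert np.all(con.for_target("construction")[steep] == 0)
        # steepness alone does not block non-construction conversions
        free_steep = steep & ~eco & (con.base == 1)
        if free_steep.any():
            assert np.all(con.for_target("cultivated")[free_steep] == 1)

    def test_missing_mask_rejected(self):
        with pytest.raises(KeyError, match="requires mask"):
            build_constraints("natural_development", {})

    def test_unknown_scenario_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_constraints("utopia", small_bundle.masks)


class TestSynthesisProbability:
    def test_constraint_absorbs(self):
        assert synthesis_probability(0.9, 1.0, 0.0, 5.0) == 0.0

    def test_empty_neighborhood_absorbs(self):
        assert synthesis_probability(0.9, 0.0, 1.0, 5.0) == 0.0

    def test_product_arithmetic(self):
        assert synthesis_probability(0.5, 0.5, 1.0, 2.0) == pytest.approx(0.5)


def _mini_setup(scheme, seed=0):
    """60×60 clustered map + smooth surfaces for fast engine runs."""
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    fields = {
        name: ndimage.uniform_filter(rng.uniform(0, 1, (60, 60)), 7, mode="nearest")
        for name in ("cultivated", "ecological", "construction", "other")
    }
    stack = np.stack([fields[n] for n in scheme.names])
    values = np.asarray(list(scheme.codes))[np.argmax(stack, axis=0)].astype(np.int64)
    grid = LandUseGrid(values)
    surfaces = theil_normalize(
        {n: rng.uniform(0.05, 0.95, (60, 60)) for n in ("cultivated", "ecological", "construction")}
    )
    return grid, surfaces


def _targets_from_counts(counts, cell_area, shift=None):
    areas = pd.Series({k: v * cell_area for k, v in counts.items()})
    if shift:
        for k, dv in shift.items():
            areas[k] += dv * cell_area
    return MacroTargets("t+1", areas, tolerance=areas.clip(lower=1.0) * 0.01 + 1e-9)


class TestRunScenario:
    def test_targets_equal_current_is_fixed_point(self, scheme):
        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        targets = _targets_from_counts(grid.class_counts(scheme), grid.cell_area_km2)
        cfg = ScenarioConfig("natural_development", seed=1)
        res = run_scenario(grid, surfaces, con, targets, cfg)
        assert res.iterations == 0
        assert res.all_converged
        np.testing.assert_array_equal(res.final_grid.values, grid.values)

    def test_demand_met_within_band(self, scheme):
        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        counts = grid.class_counts(scheme)
        shift = {"construction": 300, "ecological": -200, "cultivated": -100}
        targets = _targets_from_counts(counts, grid.cell_area_km2, shift)
        cfg = ScenarioConfig("natural_development", seed=3)
        res = run_scenario(grid, surfaces, con, targets, cfg)
        assert res.all_converged
        for name in scheme.names:
            band = max(1, round(0.01 * res.targets_cells[name]))
            assert abs(res.gaps[name]) <= band

    def test_conservation_every_iteration(self, scheme):
        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(
            counts, grid.cell_area_km2, {"construction": 250, "ecological": -250}
        )
        res = run_scenario(grid, surfaces, con, targets, ScenarioConfig("natural_development", seed=5))
        totals = res.trajectory.sum(axis=1)
        assert totals.nunique() == 1
        assert totals.iloc[0] == grid.values.size

    def test_constraint_inviolability_many_seeds(self, scheme, rng):
        grid, surfaces = _mini_setup(scheme)
        frozen = rng.uniform(size=grid.shape) < 0.3
        con = ConstraintMask(np.where(frozen, 0.0, 1.0))
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(
            counts, grid.cell_area_km2, {"construction": 200, "cultivated": -100, "ecological": -100}
        )
        for seed in range(25):
            cfg = ScenarioConfig("natural_development", seed=seed, max_iterations=40)
            res = run_scenario(grid, surfaces, con, targets, cfg)
            np.testing.assert_array_equal(res.final_grid.values[frozen], grid.values[frozen])

    def test_bit_reproducible_under_seed(self, scheme):
        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(counts, grid.cell_area_km2, {"construction": 200, "ecological": -200})
        cfg = ScenarioConfig("natural_development", seed=11)
        a = run_scenario(grid, surfaces, con, targets, cfg)
        b = run_scenario(grid, surfaces, con, targets, cfg)
        np.testing.assert_array_equal(a.final_grid.values, b.final_grid.values)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)

    def test_deterministic_with_unit_stochastic_factor(self, scheme):
        # with R ≡ 1 (γ → 1⁻) and a tiny threshold, a step is seed-independent
        from ecoca.engine import iterate_step
        from ecoca.markov import default_band_width

        class UnitGamma:
            def uniform(self, low, high, size=None):
                return np.full(size, 1 - 1e-12)

        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(counts, grid.cell_area_km2, {"construction": 150, "ecological": -150})
        tc = targets.to_cells(grid.cell_area_km2, grid.values.size)
        band = default_band_width(tc)
        outs = []
        for _ in range(2):
            state = grid.values.copy()
            cfg = ScenarioConfig("natural_development", seed=0, p_threshold=1e-9)
            for _ in range(5):
                iterate_step(state, surfaces, con, tc, band, cfg, UnitGamma(), scheme)
            outs.append(state)
        np.testing.assert_array_equal(outs[0], outs[1])
        assert np.any(outs[0] != grid.values)

    def test_construction_absorbing(self, scheme):
        grid, surfaces = _mini_setup(scheme)
        con = ConstraintMask(np.ones(grid.shape))
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(
            counts, grid.cell_area_km2, {"construction": -300, "ecological": 300}
        )
        res = run_scenario(grid, surfaces, con, targets, ScenarioConfig("natural_development", seed=2))
        constr = scheme.code("construction")
        was = grid.values == constr
        assert np.all(res.final_grid.values[was] == constr)
        # demand below current construction cannot be met: reported, not raised
        assert not res.converged["construction"]

    def test_ecological_never_shrinks_under_ecosystem_priority(self, small_bundle, scheme):
        con = build_constraints("ecosystem_priority", small_bundle.masks, small_bundle.map_t0)
        grid = small_bundle.map_t0
        rng = np.random.default_rng(0)
        surfaces = theil_normalize(
            {n: rng.uniform(0.05, 0.95, grid.shape) for n in ("cultivated", "ecological", "construction")}
        )
        counts = grid.class_counts(scheme)
        targets = _targets_from_counts(
            counts, grid.cell_area_km2, {"construction": 400, "cultivated": -500, "ecological": 100}
        )
        res = run_scenario(grid, surfaces, con, targets, ScenarioConfig("ecosystem_priority", seed=4))
        eco = scheme.code("ecological")
        n0 = np.count_nonzero(grid.values == eco)
        n1 = np.count_nonzero(res.final_grid.values == eco)
        assert n1 >= n0


class TestScenarioConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"p_threshold": 0.0},
            {"p_threshold": 1.0},
            {"alpha": 0},
            {"alpha": 11},
            {"alpha": 2.5},
            {"threshold_direction": "up"},
            {"targets_source": "oracle"},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ScenarioConfig("natural_development", **kw)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("business_as_usual")
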