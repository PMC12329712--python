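"""Generator contracts: trajectories, conservation, autocorrelation,
species sampling fidelity, reference-table completeness."""

import dataclasses

import numpy as np
import pytest

from lusa.grids import GridGeometry
from lusa.landuse import RAW_CATEGORIES, category_area, validate_fractions
from lusa.synthetic import (
    DegenerateSpeciesError,
    InfeasibleTrajectoryError,
    ScenarioConfig,
    SyntheticSpecies,
    env_stack,
    generate_landscape,
    generate_scenario,
    generate_species,
    sample_presences,
    ssp1_like,
    ssp2_like,
    ssp3_like,
    true_suitability,
)


def national_total_loop(grid, category):
    """Per-cell loop oracle for national category area."""
    total = 0.0
    frac = grid.fractions[category]
    for r in range(frac.shape[0]):
        for c in range(frac.shape[1]):
            total += frac[r, c] * grid.geometry.cell_area
    return total


class TestGenerateScenario:
    def test_endpoint_trajectories_within_one_percent(self, cfg, raw_grids):
        base, end = raw_grids[0], raw_grids[-1]
        for cat, traj in cfg.category_trajectories.items():
            a0 = category_area(base, cat)
            a1 = category_area(end, cat)
            assert a1 == pytest.approx((1.0 + traj) * a0, rel=0.01)

    def test_fractions_valid_every_timestep(self, raw_grids):
        for grid in raw_grids:
            assert validate_fractions(grid).ok

    def test_totals_monotone(self, cfg, raw_grids):
        for cat, traj in cfg.category_trajectories.items():
            series = np.array([category_area(g, cat) for g in raw_grids])
            diffs = np.diff(series)
            if traj > 0:
                assert (diffs > -1e-6 * series[0]).all()
            elif traj < 0:
                assert (diffs < 1e-6 * series[0]).all()

    def test_total_land_area_conserved_loop_oracle(self, raw_grids):
        totals = [
            sum(national_total_loop(g, cat) for cat in RAW_CATEGORIES)
            for g in raw_grids
        ]
        assert np.allclose(totals, totals[0], rtol=1e-12)

    def test_zero_trajectories_freeze_the_map(self):
        cfg = ScenarioConfig(
            scenario_id="frozen",
            grid_shape=(12, 12),
            category_trajectories={},
            seed=5,
        )
        grids = generate_scenario(cfg)
        for grid in grids[1:]:
            for cat in RAW_CATEGORIES:
                np.testing.assert_allclose(
                    grid.fractions[cat], grids[0].fractions[cat], atol=1e-9
                )

    def test_deterministic_given_seed(self, cfg):
        a = generate_scenario(cfg)
        b = generate_scenario(cfg)
        for ga, gb in zip(a, b):
            for cat in RAW_CATEGORIES:
                np.testing.assert_array_equal(ga.fractions[cat], gb.fractions[cat])

    def test_infeasible_trajectory_rejected(self):
        with pytest.raises(InfeasibleTrajectoryError):
            ScenarioConfig(category_trajectories={"forest": -1.2})

    def test_unbalanced_trajectories_without_balance_category_rejected(self):
        cfg = ScenarioConfig(
            grid_shape=(10, 10),
            category_trajectories={"forest": 0.5},
            balance_category=None,
            seed=1,
        )
        with pytest.raises(InfeasibleTrajectoryError, match="conserve total land area"):
            generate_scenario(cfg)


class TestGenerateLandscape:
    def test_categorical_maps_partition_grid(self, cfg, landscape):
        for m in (landscape.biome, landscape.climate, landscape.soil, landscape.state):
            assert m.values.shape == cfg.grid_shape
            assert m.values.min() >= 0
            assert m.values.max() < m.n_classes

    def test_deterministic(self, cfg, landscape):
        again = generate_landscape(cfg)
        for name, layer in landscape.static_layers.items():
            np.testing.assert_array_equal(layer, again.static_layers[name])
        np.testing.assert_array_equal(landscape.biome.values, again.biome.values)

    def test_elevation_spatially_autocorrelated(self, landscape):
        """Neighbour-pair correlation computed by an explicit loop oracle."""
        elev = landscape.static_layers["elevation"]
        pairs = []
        for r in range(elev.shape[0]):
            for c in range(elev.shape[1] - 1):
                pairs.append((elev[r, c], elev[r, c + 1]))
        for r in range(elev.shape[0] - 1):
            for c in range(elev.shape[1]):
                pairs.append((elev[r, c], elev[r + 1, c]))
        a, b = np.array(pairs).T
        assert np.corrcoef(a, b)[0, 1] > 0.5


class TestGenerateSpecies:
    def test_presences_inside_range_mask(self, cfg, base_env):
        species, records = generate_species(base_env, cfg.n_species, cfg)
        for sp in species:
            rec = records[records["species_id"] == sp.species_id]
            row, col = base_env.geometry.cell_of(rec["x"].to_numpy(), rec["y"].to_numpy())
            assert sp.true_range_mask[row, col].all()

    def test_mean_record_count_near_configured_mean(self, cfg, base_env):
        species, records = generate_species(base_env, 10, cfg)
        counts = records.groupby("species_id").size()
        assert abs(counts.mean() - 66.0) / 66.0 < 0.20

    def test_deterministic(self, cfg, base_env):
        s1, r1 = generate_species(base_env, 3, cfg)
        s2, r2 = generate_species(base_env, 3, cfg)
        assert r1.equals(r2)
        for a, b in zip(s1, s2):
            assert a.true_coefficients == b.true_coefficients

    def test_presence_frequency_matches_suitability(self, cfg, base_env, rng):
        """Per-cell presence frequencies against a binomial/multinomial
        99% interval at large n."""
        species, _ = generate_species(base_env, 1, cfg)
        sp = species[0]
        n = 40_000
        rec = sample_presences(sp, base_env, n, rng)
        row, col = base_env.geometry.cell_of(rec["x"].to_numpy(), rec["y"].to_numpy())
        counts = np.zeros(base_env.geometry.shape)
        np.add.at(counts, (row, col), 1)
        p = true_suitability(sp, base_env)
        mask = sp.true_range_mask
        probs = np.where(mask, p, 0.0)
        probs = probs / probs.sum()
        from scipy.stats import binom

        lo = binom.ppf(0.005, n, probs[mask])
        hi = binom.ppf(0.995, n, probs[mask])
        inside = (counts[mask] >= lo) & (counts[mask] <= hi)
        assert inside.mean() > 0.95

    def test_degenerate_species_rejected(self):
        with pytest.raises(DegenerateSpeciesError):
            SyntheticSpecies(
                species_id="bad",
                true_coefficients={"intercept": 0.0},
                true_range_mask=np.zeros((5, 5), dtype=bool),
                n_presences=10,
            )


class TestReferenceTables:
    def test_complete_key_coverage(self, canonical_grids, landscape, refs):
        carbon_refs = refs[0]
        grid = canonical_grids[0]
        for cat in grid.categories:
            for b in landscape.biome.labels:
                assert carbon_refs.get_f(cat, b) > 0
                for cl in landscape.climate.labels:
                    assert carbon_refs.get_biomass(cat, b, cl) >= 0
        for cl in landscape.climate.labels:
            for so in landscape.soil.labels:
                assert carbon_refs.get_socref(cl, so) >= 0

    def test_natural_vegetation_factor_is_one(self, landscape, refs):
        for b in landscape.biome.labels:
            assert refs[0].get_f("forest", b) == 1.0
            assert refs[0].get_f("grassland", b) == 1.0

    def test_price_index_starts_at_one(self, cfg, refs):
        price_table = refs[1]
        for commodity in ("soybean", "coffee", "sugarcane", "cattle"):
            assert price_table.get_index(commodity, cfg.start_year) == 1.0


def test_scenario_presets_have_distinct_trajectories():
    t1 = ssp1_like().category_trajectories
    t2 = ssp2_like().category_trajectories
    t3 = ssp3_like().category_trajectories
    assert t1["forest"] > 0 > t2["forest"] > t3["forest"]
    assert t1["pasture"] < 0 < t2["pasture"] < t3["pasture"]


def test_env_stack_landuse_layers_in_unit_interval(base_env):
    for name in ("forest", "cropland", "forest_plantation", "grassland_pasture"):
        layer = base_env.layers[name]
        assert layer.min() >= 0 and layer.max() <= 1 + 1e-9
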