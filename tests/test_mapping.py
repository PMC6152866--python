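"""Raster prediction, domain/range masks, and richness stacking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from shapely.geometry import box

from occumap import covariate_prep as cp
from occumap import mapping
from occumap import occu_model as oc
from occumap import rasters, synthetic_data as sd
from occumap import survey_io as sio

from conftest import make_sites, simulate_dataset


@pytest.fixture(scope="module")
def fitted_on_landscape():
    stack = sd.gen_landscape(30, 30, ["rugged", "temp"], seed=3, cell_size=100.0)
    sites_raw = sd.gen_sites(stack, 150, seed=4)
    truth = sd.TrueParameters(
        beta={"(Intercept)": -0.2, "rugged": 1.0}, gamma_method={"m": -0.3}, species_id="sp"
    )
    design = sd.SurveyDesign(methods=["m"], occasions_per_method={"m": 4})
    rec = sd.simulate_surveys(sites_raw, truth, design, seed=5)
    hist = sio.build_history(rec, "sp", {"m": "daily"})
    std, scaling = cp.standardize(sites_raw)
    fitted = oc.fit(
        oc.ModelSpec(psi_terms=(("rugged", 1),)), hist, std, n_starts=2, seed=0,
        scaling=scaling,
    )
    return stack, sites_raw, fitted


class TestPredictRaster:
    def test_intercept_only_uniform_half(self, fitted_on_landscape):
        stack, sites_raw, fitted = fitted_on_landscape
        const = oc.FittedModel(
            **{**fitted.__dict__, "spec": oc.ModelSpec(), "params": np.array([0.0, 0.0]),
               "param_names": ["psi:(Intercept)", "p:m"]}
        )
        surface = mapping.predict_raster(const, stack)
        np.testing.assert_allclose(surface.grid, 0.5)

    def test_sites_mean_raster_gives_intercept_probability(self, fitted_on_landscape):
        stack, sites_raw, fitted = fitted_on_landscape
        flat = rasters.GridStack(
            {"rugged": np.full((5, 5), sites_raw["rugged"].mean()),
             "temp": np.zeros((5, 5))},
            cell_size=100.0,
        )
        surface = mapping.predict_raster(fitted, flat)
        np.testing.assert_allclose(surface.grid, expit(fitted.params[0]), atol=1e-12)

    def test_single_cell_matches_predict_probabilities(self, fitted_on_landscape):
        stack, sites_raw, fitted = fitted_on_landscape
        cell = rasters.GridStack(
            {"rugged": np.array([[1.3]]), "temp": np.array([[0.0]])}, cell_size=100.0
        )
        surface = mapping.predict_raster(fitted, cell)
        table = pd.DataFrame({"rugged": [1.3], "temp": [0.0]})
        psi, _ = oc.predict_probabilities(fitted, table)
        assert surface.grid[0, 0] == pytest.approx(psi[0])

    def test_sites_own_cells_match_site_predictions(self, fitted_on_landscape):
        stack, sites_raw, fitted = fitted_on_landscape
        surface = mapping.predict_raster(fitted, stack)
        row, col = stack.index_of(sites_raw["x"].to_numpy(), sites_raw["y"].to_numpy())
        psi, _ = oc.predict_probabilities(fitted, sites_raw)
        np.testing.assert_allclose(surface.grid[row, col], psi, atol=1e-10)

    def test_missing_layer_named(self, fitted_on_landscape):
        _, _, fitted = fitted_on_landscape
        stack = rasters.GridStack({"temp": np.zeros((2, 2))})
        with pytest.raises(KeyError, match="rugged"):
            mapping.predict_raster(fitted, stack)

    def test_missing_covariate_cell_is_missing(self, fitted_on_landscape):
        stack, _, fitted = fitted_on_landscape
        stack2 = stack.copy()
        stack2.layers["rugged"][0, 0] = np.nan
        surface = mapping.predict_raster(fitted, stack2)
        assert np.isnan(surface.grid[0, 0])
        assert np.isfinite(surface.grid[1, 1])


class TestDomainMask:
    def test_cell_above_sampled_maximum_masked(self):
        # emulate the sampled maximum-temperature range 32.4-39.2
        stack = rasters.GridStack({"max_temp": np.array([[35.0, 40.1]])})
        sampled = pd.DataFrame(
            {"site_id": ["a", "b"], "x": 0.0, "y": 0.0, "max_temp": [32.4, 39.2]}
        )
        dm = mapping.domain_mask(stack, sampled, ["max_temp"])
        assert dm.mask[0, 0] and not dm.mask[0, 1]
        assert dm.ranges["max_temp"] == (32.4, 39.2)

    def test_boundary_value_passes_closed_interval(self):
        stack = rasters.GridStack({"c": np.array([[39.2]])})
        sampled = pd.DataFrame({"site_id": ["a"], "x": 0.0, "y": 0.0, "c": [39.2]})
        assert mapping.domain_mask(stack, sampled, ["c"]).mask[0, 0]

    def test_all_within_range_all_true(self):
        stack = sd.gen_landscape(10, 10, ["c"], seed=0)
        vals = stack.layers["c"].ravel()
        sampled = pd.DataFrame(
            {"site_id": ["a", "b"], "x": 0.0, "y": 0.0, "c": [vals.min(), vals.max()]}
        )
        assert mapping.domain_mask(stack, sampled, ["c"]).mask.all()

    def test_empty_site_table_rejected(self):
        stack = rasters.GridStack({"c": np.zeros((2, 2))})
        with pytest.raises(ValueError, match="empty site table"):
            mapping.domain_mask(stack, pd.DataFrame(columns=["site_id", "x", "y", "c"]))

    def test_masking_only_removes(self, fitted_on_landscape):
        stack, sites_raw, fitted = fitted_on_landscape
        surface = mapping.predict_raster(fitted, stack)
        dm = mapping.domain_mask(stack, sites_raw, ["rugged"])
        masked = surface.apply_mask(dm.mask, "domain")
        newly_finite = np.isfinite(masked.grid) & ~np.isfinite(surface.grid)
        assert not newly_finite.any()


class TestRangeMask:
    def _stack(self):
        return rasters.GridStack({"c": np.zeros((20, 20))}, cell_size=1000.0)

    def test_buffer_includes_nearby_excludes_far(self):
        stack = self._stack()
        region = np.zeros((20, 20), dtype=bool)
        region[10, 10] = True
        mask = mapping.range_mask(region, 5000.0, stack)
        assert mask[10, 13]   # 3 km away: inside the 5 km buffer
        assert not mask[10, 17]  # 7 km away: outside

    def test_zero_buffer_is_region_itself(self):
        stack = self._stack()
        region = np.zeros((20, 20), dtype=bool)
        region[3:5, 3:5] = True
        np.testing.assert_array_equal(mapping.range_mask(region, 0.0, stack), region)

    def test_polygon_region(self):
        stack = self._stack()
        poly = box(5000.0, 5000.0, 10000.0, 10000.0)
        mask = mapping.range_mask(poly, 0.0, stack)
        xx, yy = stack.cell_centers()
        inside = (xx > 5000) & (xx < 10000) & (yy > 5000) & (yy < 10000)
        np.testing.assert_array_equal(mask, inside)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            mapping.range_mask(np.zeros((3, 3), dtype=bool), 0.0, self._stack())


class TestStackRichness:
    def _surface(self, grid, species="sp"):
        stack = rasters.GridStack({"c": np.zeros_like(np.asarray(grid, dtype=float))})
        return mapping.OccupancySurface(np.asarray(grid, dtype=float), species, stack)

    def test_cellwise_sum(self):
        surfaces = [self._surface([[v]]) for v in (0.2, 0.3, 0.5)]
        richness, coverage = mapping.stack_richness(surfaces)
        assert richness[0, 0] == pytest.approx(1.0)
        assert coverage[0, 0] == 3

    def test_single_surface_identity(self):
        s = self._surface([[0.4, 0.7]])
        richness, _ = mapping.stack_richness([s])
        np.testing.assert_allclose(richness, s.grid)

    def test_bounded_by_species_count(self):
        rng = np.random.default_rng(0)
        surfaces = [self._surface(rng.uniform(size=(4, 4))) for _ in range(5)]
        richness, coverage = mapping.stack_richness(surfaces)
        assert (richness <= coverage).all()

    def test_missing_in_all_stays_missing(self):
        a = self._surface([[np.nan, 0.2]])
        b = self._surface([[np.nan, np.nan]])
        richness, coverage = mapping.stack_richness([a, b])
        assert np.isnan(richness[0, 0])
        assert richness[0, 1] == pytest.approx(0.2)
        assert coverage[0, 1] == 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            mapping.stack_richness([self._surface([[0.1]]), self._surface([[0.1, 0.2]])])


def test_sites_in_mask_subsets_by_cell(fitted_on_landscape):
    stack, sites_raw, _ = fitted_on_landscape
    mask = np.zeros(stack.shape, dtype=bool)
    mask[:15, :] = True
    sub = mapping.sites_in_mask(sites_raw, mask, stack)
    row, _ = stack.index_of(sub["x"].to_numpy(), sub["y"].to_numpy())
    assert (row < 15).all()
    assert len(sub) < len(sites_raw)
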