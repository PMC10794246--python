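"""Grid model: regridding, population weighting, fractions, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmburden as pb
from pmburden.grids import NO_COUNTRY


def field(grid, values, species="PM25", scenario="BASE"):
    return pb.ConcentrationField(grid, species, scenario, np.asarray(values, float))


class TestGridSpec:
    def test_equality_is_field_wise(self):
        a = pb.GridSpec(3, 4, 5.0, (0.0, 0.0))
        assert a == pb.GridSpec(3, 4, 5.0, (0.0, 0.0))
        assert a != pb.GridSpec(3, 4, 5.0, (1.0, 0.0))
        assert a != pb.GridSpec(3, 4, 20.0, (0.0, 0.0))

    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=0, n_cols=3, cell_size=5.0),
        dict(n_rows=3, n_cols=3, cell_size=0.0),
        dict(n_rows=3, n_cols=3, cell_size=-1.0),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pb.GridSpec(**kwargs)

    def test_coordinates_are_cell_centers(self):
        g = pb.GridSpec(2, 3, 10.0, (100.0, 200.0))
        assert np.allclose(g.x, [100.0, 110.0, 120.0])
        assert np.allclose(g.y, [200.0, 210.0])


class TestRegrid:
    def test_constant_field_survives_both_methods(self):
        src = pb.GridSpec(4, 4, 20.0)
        tgt = pb.GridSpec(13, 13, 5.0, (-5.0, -5.0))
        f = field(src, np.full((4, 4), 10.0))
        for method in ("bilinear", "nearest"):
            out = pb.regrid_field(f, tgt, method)
            assert np.allclose(out.values, 10.0)
            assert out.species == "PM25" and out.scenario == "BASE"

    def test_bilinear_midpoint_of_two_cells(self):
        # Source cells at x = 0 and 20 valued 10 and 20; midpoint → 15.
        src = pb.GridSpec(1, 2, 20.0)
        tgt = pb.GridSpec(1, 1, 1.0, (10.0, 0.0))
        out = pb.regrid_field(field(src, [[10.0, 20.0]]), tgt, "bilinear")
        assert out.values[0, 0] == pytest.approx(15.0)

    def test_nearest_only_emits_source_values(self):
        rng = np.random.default_rng(0)
        src = pb.GridSpec(5, 5, 20.0)
        vals = rng.uniform(0, 30, (5, 5))
        tgt = pb.GridSpec(17, 17, 5.0, (-5.0, -5.0))
        out = pb.regrid_field(field(src, vals), tgt, "nearest")
        assert set(np.round(out.values.ravel(), 12)) <= set(np.round(vals.ravel(), 12))

    def test_bilinear_reproduces_affine_fields_at_centers(self):
        # An affine surface c = a + bx + cy is interpolated exactly.
        src = pb.GridSpec(3, 3, 20.0)
        yy, xx = np.meshgrid(src.y, src.x, indexing="ij")
        vals = 2.0 + 0.3 * xx + 0.1 * yy
        tgt = pb.GridSpec(5, 5, 8.0, (2.0, 3.0))
        out = pb.regrid_field(field(src, vals), tgt, "bilinear")
        tyy, txx = np.meshgrid(tgt.y, tgt.x, indexing="ij")
        assert np.allclose(out.values, 2.0 + 0.3 * txx + 0.1 * tyy)

    def test_output_bounded_by_source_range(self):
        rng = np.random.default_rng(1)
        src = pb.GridSpec(6, 6, 20.0)
        vals = rng.uniform(0, 25, (6, 6))
        tgt = pb.GridSpec(21, 21, 5.0, (-7.5, -7.5))
        for method in ("bilinear", "nearest"):
            out = pb.regrid_field(field(src, vals), tgt, method)
            assert out.values.min() >= vals.min() - 1e-12
            assert out.values.max() <= vals.max() + 1e-12

    def test_target_beyond_source_extent_raises(self):
        src = pb.GridSpec(4, 4, 20.0)
        tgt = pb.GridSpec(4, 4, 30.0, (0.0, 0.0))
        with pytest.raises(pb.GridExtentError):
            pb.regrid_field(field(src, np.ones((4, 4))), tgt)


class TestPopulationWeightedMean:
    def _inputs(self, conc_vals, pop_totals):
        grid = pb.GridSpec(1, len(conc_vals), 5.0)
        conc = field(grid, [conc_vals])
        pop_values = np.zeros((12, 1, len(conc_vals)))
        pop_values[0, 0, :] = pop_totals
        pop = pb.PopulationGrid(grid, pop_values)
        mask = pb.CountryMask(grid, np.array([["AA"] * len(conc_vals)]))
        return conc, pop, mask

    def test_uniform_concentration_is_population_independent(self):
        conc, pop, mask = self._inputs([10.0, 10.0, 10.0], [1.0, 5.0, 100.0])
        assert pb.population_weighted_mean(conc, pop, mask, "AA") == pytest.approx(10.0)

    def test_two_cell_weighted_mean(self):
        conc, pop, mask = self._inputs([10.0, 20.0], [1.0, 3.0])
        assert pb.population_weighted_mean(conc, pop, mask, "AA") == pytest.approx(17.5)

    def test_degenerate_weights_pick_single_cell(self):
        conc, pop, mask = self._inputs([10.0, 20.0], [0.0, 7.0])
        assert pb.population_weighted_mean(conc, pop, mask, "AA") == pytest.approx(20.0)

    def test_zero_population_is_an_error_not_zero(self):
        conc, pop, mask = self._inputs([10.0, 20.0], [0.0, 0.0])
        with pytest.raises(pb.WeightingError):
            pb.population_weighted_mean(conc, pop, mask, "AA")

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_uniform_population_scaling(self, k):
        conc, pop, mask = self._inputs([3.0, 11.0, 29.0], [2.0, 5.0, 1.0])
        ref = pb.population_weighted_mean(conc, pop, mask, "AA")
        scaled = pb.PopulationGrid(pop.grid, pop.values * k)
        assert pb.population_weighted_mean(conc, scaled, mask, "AA") == \
            pytest.approx(ref, rel=1e-12)


class TestAcaFraction:
    def test_zero_aca_gives_zero_fraction(self):
        grid = pb.GridSpec(2, 2, 5.0)
        frac = pb.aca_fraction(field(grid, np.zeros((2, 2)), "ACA"),
                               field(grid, np.full((2, 2), 8.0)))
        assert np.all(frac == 0.0)

    def test_direct_division(self):
        grid = pb.GridSpec(1, 1, 5.0)
        frac = pb.aca_fraction(field(grid, [[2.0]], "ACA"), field(grid, [[10.0]]))
        assert frac[0, 0] == pytest.approx(0.2)

    def test_pathological_excess_is_clamped(self):
        grid = pb.GridSpec(1, 1, 5.0)
        frac = pb.aca_fraction(field(grid, [[12.0]], "ACA"), field(grid, [[10.0]]))
        assert frac[0, 0] == 1.0

    def test_zero_pm_cells_yield_zero(self):
        grid = pb.GridSpec(1, 2, 5.0)
        frac = pb.aca_fraction(field(grid, [[0.0, 1.0]], "ACA"),
                               field(grid, [[0.0, 4.0]]))
        assert frac[0, 0] == 0.0 and frac[0, 1] == pytest.approx(0.25)

    def test_scenario_mismatch_raises(self):
        grid = pb.GridSpec(1, 1, 5.0)
        with pytest.raises(pb.GridAlignmentError):
            pb.aca_fraction(field(grid, [[1.0]], "ACA", "RES100"),
                            field(grid, [[4.0]], "PM25", "BASE"))

    def test_round_trips_constructed_fraction(self):
        rng = np.random.default_rng(2)
        grid = pb.GridSpec(4, 4, 5.0)
        pm_vals = rng.uniform(0.5, 20.0, (4, 4))
        f = rng.uniform(0.0, 1.0, (4, 4))
        frac = pb.aca_fraction(field(grid, f * pm_vals, "ACA"), field(grid, pm_vals))
        assert np.allclose(frac, f, atol=1e-12)


class TestCountryAggregate:
    def test_single_country_sum_is_domain_total(self):
        grid = pb.GridSpec(2, 2, 5.0)
        mask = pb.CountryMask(grid, np.full((2, 2), "AA", dtype="U8"))
        out = pb.country_aggregate(np.arange(4.0).reshape(2, 2), mask, "sum")
        assert out["AA"] == pytest.approx(6.0)

    def test_two_country_partition(self):
        grid = pb.GridSpec(1, 3, 5.0)
        mask = pb.CountryMask(grid, np.array([["AA", "AA", "BB"]]))
        out = pb.country_aggregate(np.array([[1.0, 2.0, 3.0]]), mask, "sum")
        assert out["AA"] == 3.0 and out["BB"] == 3.0

    def test_empty_country_absent_not_zero(self):
        grid = pb.GridSpec(1, 2, 5.0)
        mask = pb.CountryMask(grid, np.array([["AA", "AA"]]), registry=("AA", "BB"))
        out = pb.country_aggregate(np.ones((1, 2)), mask, "sum")
        assert "BB" not in out.index

    def test_pop_weighted_requires_population(self):
        grid = pb.GridSpec(1, 2, 5.0)
        mask = pb.CountryMask(grid, np.array([["AA", "AA"]]))
        with pytest.raises(TypeError):
            pb.country_aggregate(np.ones((1, 2)), mask, "pop_weighted_mean")

    def test_sum_partitions_grid_total(self, small_study):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, small_study.mask.grid.shape)
        per_country = pb.country_aggregate(vals, small_study.mask, "sum")
        out_of_mask = vals[small_study.mask.values == NO_COUNTRY].sum()
        assert per_country.sum() + out_of_mask == pytest.approx(
            vals.sum(), rel=1e-9)
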