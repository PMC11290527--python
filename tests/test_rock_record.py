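import numpy as np
import pandas as pd
import pytest

from stratodyn.data_model_io import TimeGrid, ValidationError
from stratodyn.rock_record import (
    compute_area_series,
    compute_volume_flux,
    leave_region_out,
    lithofacies_percentages,
    normalize_to_unit_max,
)


def make_units(rows):
    """Units from (unit_id, region, group, depth, marine, thickness_m, area, base, top)."""
    return pd.DataFrame(
        rows,
        columns=["unit_id", "region", "group", "depth", "marine",
                 "mean_thickness", "area", "base_age", "top_age"],
    )


GRID = TimeGrid(oldest=580.0, youngest=560.0)


def random_units(rng, n, grid=GRID, region=None):
    groups = ["siliciclastic", "limestone", "dolostone", "phosphorite",
              "evaporitic_semirestricted"]
    depths = ["shallow_inner_shelf", "mid_outer_shelf_upper_slope", "lower_slope_basinal"]
    rows = []
    for i in range(n):
        base = rng.uniform(grid.youngest + 0.5, grid.oldest)
        top = rng.uniform(grid.youngest, base - 0.01)
        g = groups[rng.integers(len(groups))]
        d = depths[rng.integers(3)] if g in ("siliciclastic", "limestone", "dolostone") \
            else "not_applicable"
        rows.append(
            (f"u{i}", region or f"r{rng.integers(4)}", g, d,
             g != "evaporitic_semirestricted",
             rng.uniform(1, 800), rng.uniform(100, 1e5), base, top)
        )
    return make_units(rows)


class TestVolumeFlux:
    def test_uniform_unit_arithmetic(self):
        """area 10,000 km² × 200 m over 10 Ma → 2,000 km³; 10 km³ per full 50-ka bin."""
        units = make_units([("u1", "A", "limestone", "shallow_inner_shelf", True,
                             200.0, 10000.0, 580.0, 570.0)])
        flux = compute_volume_flux(units, GRID)
        assert flux.total.sum() == pytest.approx(2000.0, rel=1e-12)
        covered = flux.bin_younger >= 570.0
        np.testing.assert_allclose(flux.total[covered], 10.0, rtol=1e-9)
        assert (flux.total[~covered] == 0).all()

    def test_partial_overlap_is_proportional(self, rng):
        """Allocation matches a fine-step numerical integration of coverage."""
        units = random_units(rng, 25)
        flux = compute_volume_flux(units, GRID)
        bo, by = GRID.flux_bins()
        # oracle: deposit rate × 1-ka micro-slices into the bin holding each midpoint
        oracle = np.zeros(bo.size)
        for _, u in units.iterrows():
            rate = u.area * u.mean_thickness / 1000.0 / (u.base_age - u.top_age)
            edges = np.arange(u.base_age, u.top_age, -0.001)
            mids = (edges[:-1] + edges[1:]) / 2.0
            widths = edges[:-1] - edges[1:]
            idx = np.searchsorted(-bo, -mids, side="right") - 1
            ok = (idx >= 0) & (mids > by[np.clip(idx, 0, by.size - 1)])
            np.add.at(oracle, idx[ok], rate * widths[ok])
            # trailing remainder slice of the unit
            if edges[-1] > u.top_age:
                m = (edges[-1] + u.top_age) / 2.0
                j = np.searchsorted(-bo, -m, side="right") - 1
                if 0 <= j < bo.size and m > by[j]:
                    oracle[j] += rate * (edges[-1] - u.top_age)
        # micro-slice misassignment at bin boundaries bounds the discrepancy
        rates = units.area * units.mean_thickness / 1000.0 / (units.base_age - units.top_age)
        np.testing.assert_allclose(flux.total, oracle, rtol=5e-3,
                                   atol=0.002 * rates.max())

    def test_sub_bin_unit_gets_proportional_share(self):
        units = make_units([("u1", "A", "limestone", "shallow_inner_shelf", True,
                             100.0, 1000.0, 570.025, 570.0)])
        grid = TimeGrid(oldest=571.0, youngest=569.0)
        flux = compute_volume_flux(units, grid)
        bo, _ = grid.flux_bins()
        j = int(np.argwhere(bo == 570.05)[0, 0])
        # unit occupies half of bin [570.05, 570.00): all 100 km³ land there,
        # i.e. half the share a full-overlap 50-ka slice at the same
        # deposition rate would spread over two bins
        assert flux.total[j] == pytest.approx(100.0, rel=1e-12)
        assert flux.total.sum() == pytest.approx(100.0, rel=1e-12)
        rate = 1000.0 * 0.1 / 0.025  # km³ per Ma
        assert flux.total[j] == pytest.approx(rate * 0.05 / 2.0, rel=1e-12)

    def test_zero_thickness_zero_flux(self):
        units = make_units([("u1", "A", "limestone", "shallow_inner_shelf", True,
                             0.0, 10000.0, 580.0, 570.0)])
        assert compute_volume_flux(units, GRID).total.sum() == 0.0

    def test_zero_duration_errors_with_unit_id(self):
        units = make_units([("bad_unit", "A", "limestone", "shallow_inner_shelf", True,
                             10.0, 100.0, 570.0, 570.0)])
        with pytest.raises(ValidationError, match="bad_unit"):
            compute_volume_flux(units, GRID)

    def test_conservation_per_unit(self, rng):
        """Binned volume of each unit sums to area × thickness (rel 1e-9)."""
        units = random_units(rng, 60)
        flux = compute_volume_flux(units, GRID)
        for i in range(len(units)):
            one = compute_volume_flux(units.iloc[[i]], GRID)
            expected = units.iloc[i].area * units.iloc[i].mean_thickness / 1000.0
            assert one.total.sum() == pytest.approx(expected, rel=1e-9)
        # partitions sum to the total bin-wise
        np.testing.assert_allclose(flux.by_class.sum(axis=1), flux.total, rtol=1e-9)
        np.testing.assert_allclose(flux.by_region.sum(axis=1), flux.total, rtol=1e-9)

    def test_linearity_over_disjoint_unit_sets(self, rng):
        units = random_units(rng, 30)
        a, b = units.iloc[:13], units.iloc[13:]
        total = compute_volume_flux(units, GRID).total
        np.testing.assert_allclose(
            total,
            compute_volume_flux(a, GRID).total + compute_volume_flux(b, GRID).total,
            rtol=1e-12, atol=1e-12,
        )


class TestLithofaciesPercentages:
    def _flux(self, rows):
        return compute_volume_flux(make_units(rows), TimeGrid(oldest=571, youngest=570))

    def test_percentages_normalize_to_100(self):
        flux = self._flux([
            ("u1", "A", "siliciclastic", "shallow_inner_shelf", True, 30.0, 1000.0, 571.0, 570.0),
            ("u2", "A", "limestone", "shallow_inner_shelf", True, 50.0, 1000.0, 571.0, 570.0),
            ("u3", "A", "siliciclastic", "lower_slope_basinal", True, 20.0, 1000.0, 571.0, 570.0),
        ])
        pct = lithofacies_percentages(flux)
        row = pct.iloc[0]
        assert row["siliciclastic:shallow_inner_shelf"] == pytest.approx(30.0)
        assert row["limestone:shallow_inner_shelf"] == pytest.approx(50.0)
        assert row["siliciclastic:lower_slope_basinal"] == pytest.approx(20.0)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0)

    def test_evaporite_excluded_from_both_sides(self):
        flux = self._flux([
            ("u1", "A", "evaporitic_semirestricted", "not_applicable", False,
             10.0, 1000.0, 571.0, 570.0),
            ("u2", "A", "limestone", "shallow_inner_shelf", True, 40.0, 1000.0, 571.0, 570.0),
        ])
        pct = lithofacies_percentages(flux)
        assert "evaporitic_semirestricted" not in pct.columns
        np.testing.assert_allclose(pct["limestone:shallow_inner_shelf"], 100.0)

    def test_zero_bin_is_missing_not_zero(self):
        flux = self._flux([
            ("u1", "A", "limestone", "shallow_inner_shelf", True, 40.0, 1000.0,
             571.0, 570.5),
        ])
        pct = lithofacies_percentages(flux)
        empty = flux.total == 0
        assert pct[empty].isna().all().all()


class TestAreaSeries:
    UNITS = make_units([
        ("u1", "B", "limestone", "shallow_inner_shelf", True, 10.0, 300.0, 571.0, 570.5),
        ("u2", "A", "siliciclastic", "shallow_inner_shelf", True, 10.0, 100.0, 570.6, 570.4),
    ])
    AREAS = {"A": 100.0, "B": 300.0}

    def test_presence_absence_area_and_fraction(self):
        grid = TimeGrid(oldest=571.0, youngest=570.0)
        series = compute_area_series(self.UNITS, self.AREAS, grid)
        bo = series.bin_older
        only_b = bo == 571.0  # bin [571.0, 570.95): only region B deposits
        both = bo == 570.6    # covered in both regions
        neither = bo == 570.2
        assert series.area[only_b] == pytest.approx(300.0)
        assert series.nondeposition_fraction[only_b] == pytest.approx(0.25)
        assert series.nondeposition_fraction[both] == pytest.approx(0.0)
        assert series.nondeposition_fraction[neither] == pytest.approx(1.0)

    def test_unknown_region_errors(self):
        grid = TimeGrid(oldest=571.0, youngest=570.0)
        with pytest.raises(ValidationError, match="unknown region"):
            compute_area_series(self.UNITS, {"A": 100.0}, grid)

    def test_nonmarine_units_do_not_count(self):
        units = make_units([
            ("u1", "A", "fluvial_subaerial", "not_applicable", False,
             10.0, 100.0, 571.0, 570.0),
        ])
        grid = TimeGrid(oldest=571.0, youngest=570.0)
        series = compute_area_series(units, {"A": 100.0}, grid)
        assert (series.nondeposition_fraction == 1.0).all()


class TestLeaveRegionOut:
    def test_removal_count_and_equivalence(self, rng):
        units = random_units(rng, 12, region=None)
        region = units["region"].iloc[0]
        n_in_region = (units["region"] == region).sum()
        kept, _ = leave_region_out(units, None, region)
        assert len(kept) == len(units) - n_in_region
        flux_removed = compute_volume_flux(kept, GRID).total
        complement = units[units["region"] != region]
        np.testing.assert_array_equal(
            flux_removed, compute_volume_flux(complement, GRID).total
        )

    def test_unknown_region_errors(self, rng):
        units = random_units(rng, 5)
        with pytest.raises(KeyError):
            leave_region_out(units, None, "atlantis")

    def test_occurrences_filtered_too(self, rng):
        units = random_units(rng, 5, region="keep")
        occ = pd.DataFrame({"region": ["keep", "drop"], "genus": ["a", "b"]})
        _, occ_out = leave_region_out(units, occ, "drop")
        assert list(occ_out["genus"]) == ["a"]


class TestNormalizeToUnitMax:
    def test_basic_scaling(self):
        np.testing.assert_allclose(normalize_to_unit_max([2.0, 4.0]), [0.5, 1.0])
        np.testing.assert_allclose(normalize_to_unit_max([3.0, 3.0, 3.0]), 1.0)

    def test_missing_values_stay_missing(self):
        out = normalize_to_unit_max([2.0, np.nan, 4.0])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.5, 1.0])

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_unit_max([0.0, 0.0])
        with pytest.raises(ValueError):
            normalize_to_unit_max([])
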