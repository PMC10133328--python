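"""ES capacity/flow operations against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from vallescape.es import (
    HabitatLayerSet,
    aquaculture_capacity,
    attractiveness_index,
    climate_regulation,
    huntable_density_surface,
    lifecycle_flow,
    record_mean_flow,
    water_purification,
    wildfood_capacity,
)
from vallescape.rates import RateTable


def layers(pixel_size=25.0, **masks):
    return HabitatLayerSet({k: np.asarray(v, dtype=bool) for k, v in masks.items()}, pixel_size)


class TestClimateRegulation:
    def test_no_vegetated_habitat_is_zero(self):
        hab = layers(reed_stand=np.zeros((4, 4)))
        cap, flow = climate_regulation(hab, RateTable(), 10_000.0)
        assert cap == flow == 0.0

    def test_linearity_single_habitat(self):
        # 16 pixels of 25 m = 10,000 m^2 at 100 gC/m2/y over 100,000 m^2
        hab = layers(reed_stand=np.ones((4, 4)))
        rates = RateTable(carbon_rates_gC_m2_y={"reed_stand": 100.0})
        cap, flow = climate_regulation(hab, rates, 100_000.0)
        assert cap == pytest.approx(10.0)
        assert cap == flow  # capacity and flow equivalent for this service

    def test_matches_pixelwise_oracle(self, rng):
        masks = {
            "reed_stand": rng.random((10, 10)) < 0.3,
            "vegetated_saltmarsh": rng.random((10, 10)) < 0.4,
            "seagrass_meadow": rng.random((10, 10)) < 0.2,
        }
        rates = RateTable()
        hab = layers(**masks)
        area = 10 * 10 * 625.0
        cap, _ = climate_regulation(hab, rates, area)
        expected = 0.0
        for name, mask in masks.items():
            rate = rates.carbon_rates_gC_m2_y[name]
            if name == "seagrass_meadow":
                rate += rates.seagrass_epiphyte_increment_gC_m2_y
            for v in mask.ravel():  # explicit pixelwise multiply-accumulate
                if v:
                    expected += 625.0 * rate
        assert cap == pytest.approx(expected / area)

    def test_doubling_areas_doubles_total(self, rng):
        mask = rng.random((6, 6)) < 0.5
        hab1 = layers(vegetated_saltmarsh=mask)
        hab2 = layers(vegetated_saltmarsh=np.concatenate([mask, mask]))
        area = 36 * 625.0
        cap1, _ = climate_regulation(hab1, RateTable(), area)
        cap2, _ = climate_regulation(hab2, RateTable(), area)
        assert cap2 == pytest.approx(2 * cap1)

    def test_missing_rate_for_present_habitat_rejected(self):
        hab = layers(vegetated_saltmarsh=np.ones((2, 2)))
        rates = RateTable(carbon_rates_gC_m2_y={"reed_stand": 100.0})
        with pytest.raises(KeyError, match="vegetated_saltmarsh"):
            climate_regulation(hab, rates, 1e4)


class TestWaterPurification:
    def test_zero_fraction(self):
        res = water_purification(1e4, 10.0, 0.0)
        assert res.capacity_pct == res.flow_pct == 0.0

    def test_linearity(self):
        res = water_purification(1e4, 10.0, 0.5)
        assert res.capacity_pct == 50.0
        assert res.removed_gN_y == pytest.approx(5e4)

    def test_matches_product_oracle(self, rng):
        area, load, frac = rng.uniform(1e3, 1e6), rng.uniform(0, 50), rng.uniform(0, 1)
        res = water_purification(area, load, frac)
        assert res.capacity_pct == pytest.approx(frac * 100)
        assert res.removed_gN_y == pytest.approx(frac * load * area)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            water_purification(1e4, 10.0, 1.5)
        with pytest.raises(ValueError):
            water_purification(1e4, -1.0, 0.5)


class TestAttractiveness:
    def test_all_zero_layers_give_zero_index(self):
        index, mean = attractiveness_index([np.zeros((5, 5))], [1.0])
        assert not index.any() and mean == 0.0

    def test_single_binary_layer_is_identity(self, rng):
        layer = (rng.random((6, 6)) < 0.5).astype(float)
        index, _ = attractiveness_index([layer], [1.0])
        assert np.array_equal(index, layer)

    def test_matches_weighted_sum_rescale_oracle(self, rng):
        ls = [rng.random((7, 7)) for _ in range(3)]
        w = [0.5, 0.3, 0.2]
        index, mean = attractiveness_index(ls, w)
        raw = 0.5 * ls[0] + 0.3 * ls[1] + 0.2 * ls[2]
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(index, expected)
        assert mean == pytest.approx(expected.mean())
        assert index.min() == 0.0 and index.max() == 1.0

    def test_shared_bounds_keep_scale_across_units(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4)) + 2.0
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        ia, _ = attractiveness_index([a], [1.0], rescale_bounds=(lo, hi))
        ib, _ = attractiveness_index([b], [1.0], rescale_bounds=(lo, hi))
        assert ia.max() < 1.0 and ib.max() == pytest.approx(1.0)

    def test_violations_rejected(self):
        with pytest.raises(ValueError):
            attractiveness_index([np.zeros((2, 2))], [0.5, 0.5])
        with pytest.raises(ValueError):
            attractiveness_index([np.zeros((2, 2)), np.zeros((3, 3))], [0.5, 0.5])
        with pytest.raises(ValueError):
            attractiveness_index([], [])


def make_records(values_by_unit, field="fry_sown", years=None):
    rows = []
    for uid, vals in values_by_unit.items():
        for i, v in enumerate(vals):
            year = (years or range(2010, 2010 + len(vals)))[i]
            rows.append({"legend_id": uid, "year": year, field: v})
    return pd.DataFrame(rows)


class TestFlows:
    def test_lifecycle_extremes(self):
        records = pd.DataFrame(
            {
                "legend_id": [1, 1, 2, 2],
                "year": [2010, 2011] * 2,
                "fry_sown": [10.0, 10.0, 0.0, 0.0],
                "waterbirds_censused": [5.0, 5.0, 0.0, 0.0],
            }
        )
        combined = lifecycle_flow(records)
        assert combined[1] == pytest.approx(2.0)  # maximal in both components
        assert combined[2] == pytest.approx(0.0)

    def test_lifecycle_matches_normalize_then_add(self, rng):
        records = pd.DataFrame(
            {
                "legend_id": np.repeat(np.arange(5), 3),
                "year": np.tile([2010, 2011, 2012], 5),
                "fry_sown": rng.random(15) * 50,
                "waterbirds_censused": rng.random(15) * 20,
            }
        )
        combined = lifecycle_flow(records)
        fry = records.groupby("legend_id")["fry_sown"].mean()
        birds = records.groupby("legend_id")["waterbirds_censused"].mean()
        expected = (fry - fry.min()) / (fry.max() - fry.min()) + (birds - birds.min()) / (
            birds.max() - birds.min()
        )
        assert np.allclose(combined, expected)

    def test_lifecycle_needs_two_units(self):
        records = make_records({1: [1.0, 2.0]})
        records["waterbirds_censused"] = 1.0
        with pytest.raises(ValueError, match=">= 2 units"):
            lifecycle_flow(records)

    def test_record_mean_constant_series(self):
        records = make_records({1: [7.0, 7.0, 7.0]})
        assert record_mean_flow(records, "fry_sown")[1] == 7.0

    def test_record_mean_excludes_missing_years(self):
        records = make_records({1: [10.0, 20.0, np.nan, 30.0]})
        assert record_mean_flow(records, "fry_sown")[1] == pytest.approx(20.0)

    def test_record_mean_matches_sum_count_oracle(self, rng):
        vals = rng.random(8) * 100
        records = make_records({1: list(vals)})
        assert record_mean_flow(records, "fry_sown")[1] == pytest.approx(vals.sum() / len(vals))

    def test_window_filtering_and_errors(self):
        records = make_records({1: [1.0, 2.0, 3.0]}, years=[2010, 2011, 2012])
        assert record_mean_flow(records, "fry_sown", (2011, 2012))[1] == pytest.approx(2.5)
        with pytest.raises(ValueError, match="window"):
            record_mean_flow(records, "fry_sown", (2020, 2021))
        with pytest.raises(KeyError):
            record_mean_flow(records, "nonexistent_field")


class TestHuntableDensity:
    def test_single_point_constant_surface(self):
        surface = huntable_density_surface([(100.0, 100.0, 4.2)], (10, 10), 25.0)
        assert np.allclose(surface, 4.2)

    def test_exact_at_census_pixels(self):
        pts = [(0.0, 0.0, 1.0), (225.0, 225.0, 9.0)]
        surface = huntable_density_surface(pts, (10, 10), 25.0)
        assert surface[0, 0] == pytest.approx(1.0)
        assert surface[9, 9] == pytest.approx(9.0)

    def test_matches_direct_idw_formula(self):
        pts = [(0.0, 0.0, 1.0), (475.0, 0.0, 2.0), (0.0, 475.0, 3.0), (475.0, 475.0, 4.0)]
        surface = huntable_density_surface(pts, (20, 20), 25.0, power=2.0)
        # direct formula at an off-point pixel
        r, c = 7, 11
        num = den = 0.0
        for x, y, v in pts:
            d = math.hypot((r - y / 25.0) * 25.0, (c - x / 25.0) * 25.0)
            num += v / d**2
            den += 1 / d**2
        assert surface[r, c] == pytest.approx(num / den)

    def test_coincident_conflicting_points_averaged_with_warning(self):
        with pytest.warns(UserWarning, match="coincident"):
            surface = huntable_density_surface(
                [(0.0, 0.0, 2.0), (0.0, 0.0, 4.0)], (5, 5), 25.0
            )
        assert surface[0, 0] == pytest.approx(3.0)

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            huntable_density_surface([], (5, 5), 25.0)


class TestWildFoodAndAquaculture:
    def test_empty_inputs_give_zero(self):
        res = wildfood_capacity(np.zeros((5, 5), dtype=bool), 0.0, RateTable(), 1e6, 25.0)
        assert res.total_kg_ha_y == 0.0

    def test_salicornia_linearity(self):
        # 16 px * 625 m^2 = 10^4 m^2 at 0.2 kg/m2/y over 100 ha
        mask = np.ones((4, 4), dtype=bool)
        res = wildfood_capacity(mask, 0.0, RateTable(), 1e6, 25.0)
        assert res.total_kg_ha_y == pytest.approx(20.0)

    def test_matches_direct_arithmetic(self, rng):
        mask = rng.random((8, 8)) < 0.4
        rates = RateTable()
        res = wildfood_capacity(mask, 5e4, rates, 2e6, 25.0)
        sal = mask.sum() * 625.0 * rates.salicornia_biomass_kg_m2_y / 200.0
        honey = 5e4 * rates.honey_yield_g_m2_y / 1000.0 / 200.0
        assert res.salicornia_kg_ha_y == pytest.approx(sal)
        assert res.honey_kg_ha_y == pytest.approx(honey)
        assert res.total_kg_ha_y == pytest.approx(sal + honey)

    def test_aquaculture_constant_surface(self):
        surface = np.full((5, 5), 42.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert aquaculture_capacity(surface, mask) == 42.0

    def test_aquaculture_masked_out_surface(self, rng):
        surface = rng.random((5, 5)) * 100
        mask = surface < 0  # nothing brackish where surface lives
        mask[0, 0] = True
        surface[0, 0] = 0.0
        assert aquaculture_capacity(surface, mask) == 0.0

    def test_aquaculture_matches_masked_mean(self, rng):
        surface = rng.random((9, 9)) * 50
        mask = rng.random((9, 9)) < 0.5
        expected = surface[mask].mean()
        assert aquaculture_capacity(surface, mask) == pytest.approx(expected)

    def test_aquaculture_empty_mask_flagged_missing(self):
        assert math.isnan(aquaculture_capacity(np.ones((3, 3)), np.zeros((3, 3), dtype=bool)))
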