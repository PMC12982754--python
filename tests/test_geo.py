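"""Distance kernel and exposure-matrix construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exposcreen import geo

R = geo.EARTH_RADIUS_MILES


def zips_frame(rows):
    return pd.DataFrame(rows, columns=["zip_id", "lat", "lon", "population"])


def releases_frame(rows):
    return pd.DataFrame(rows, columns=["facility_id", "lat", "lon", "chemical_id", "amount"])


class TestGreatCircleDistance:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((40.0, -75.0), (40.0, -75.0), 0.0),
            ((0.0, 0.0), (1.0, 0.0), R * math.pi / 180.0),  # one degree of arc
            ((0.0, 0.0), (0.0, 180.0), R * math.pi),  # antipodal
        ],
    )
    def test_closed_forms(self, p1, p2, expected):
        assert geo.great_circle_distance(*p1, *p2) == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_coordinate_names_field(self):
        with pytest.raises(ValueError, match="latitude"):
            geo.great_circle_distance(91.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="longitude"):
            geo.great_circle_distance(0.0, 0.0, 0.0, 181.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.tuples(
            *[st.floats(-89.0, 89.0) for _ in range(3)],
            *[st.floats(-179.0, 179.0) for _ in range(3)],
        )
    )
    def test_symmetry_and_triangle_inequality(self, coords):
        la1, la2, la3, lo1, lo2, lo3 = coords
        d12 = geo.great_circle_distance(la1, lo1, la2, lo2)
        d21 = geo.great_circle_distance(la2, lo2, la1, lo1)
        d13 = geo.great_circle_distance(la1, lo1, la3, lo3)
        d23 = geo.great_circle_distance(la2, lo2, la3, lo3)
        assert d12 == pytest.approx(d21, abs=1e-9)
        assert d12 <= d13 + d23 + 1e-6


class TestHalfNormalSigma:
    def test_default_kernel_width_derivation(self):
        assert round(geo.half_normal_sigma(8.6), 4) == 10.7785

    def test_inverse_of_half_normal_mean(self):
        assert geo.half_normal_sigma(math.sqrt(2.0 / math.pi)) == pytest.approx(1.0)

    def test_linearity(self):
        assert geo.half_normal_sigma(17.2) == pytest.approx(2 * geo.half_normal_sigma(8.6))

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            geo.half_normal_sigma(bad)


class TestAirExposure:
    def test_single_facility_at_centroid_returns_amount(self):
        zips = zips_frame([("Z1", 40.0, -85.0, 10_000)])
        rel = releases_frame([("F1", 40.0, -85.0, "benzene", 500.0)])
        m = geo.build_air_exposure(zips, rel)
        assert m.to_frame().loc["Z1", "benzene"] == pytest.approx(500.0)

    def test_empty_catchment_is_explicit_zero(self):
        zips = zips_frame([("Z1", 40.0, -85.0, 10_000), ("Z2", 20.0, -85.0, 10_000)])
        rel = releases_frame([("F1", 40.0, -85.0, "benzene", 500.0)])
        m = geo.build_air_exposure(zips, rel)
        assert m.to_frame().loc["Z2", "benzene"] == 0.0

    def test_equal_weight_facilities_average(self):
        # two facilities symmetric about the centroid, equal populations
        zips = zips_frame([("Z1", 0.0, 0.0, 10_000)])
        rel = releases_frame(
            [
                ("F1", 0.1, 0.0, "benzene", 100.0),
                ("F2", -0.1, 0.0, "benzene", 300.0),
            ]
        )
        rel["population"] = 5000
        m = geo.build_air_exposure(zips, rel)
        assert m.to_frame().loc["Z1", "benzene"] == pytest.approx(200.0)

    def test_strict_radius_boundary(self):
        # ~1 degree latitude = 69.09 miles; place facilities just inside and
        # outside 30 miles (0.4342 deg ~ 30.0 mi)
        inside_lat = 29.9 / (R * math.pi / 180.0)
        outside_lat = 30.1 / (R * math.pi / 180.0)
        zips = zips_frame([("Z1", 0.0, 0.0, 10_000)])
        rel_in = releases_frame([("F1", inside_lat, 0.0, "benzene", 77.0)])
        rel_out = releases_frame([("F1", outside_lat, 0.0, "benzene", 77.0)])
        assert geo.build_air_exposure(zips, rel_in).values[0, 0] == pytest.approx(77.0)
        assert geo.build_air_exposure(zips, rel_out).values[0, 0] == 0.0

    def test_homogeneity_in_release_amounts(self, small_zips):
        rng = np.random.default_rng(3)
        rel = releases_frame(
            [
                (f"F{i}", 40.0 + rng.uniform(-0.3, 0.3), -85.0 + rng.uniform(-0.3, 0.3),
                 f"chem{i % 3}", rng.uniform(1, 100))
                for i in range(12)
            ]
        )
        m1 = geo.build_air_exposure(small_zips, rel)
        rel2 = rel.assign(amount=2.0 * rel["amount"])
        m2 = geo.build_air_exposure(small_zips, rel2)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values, rtol=1e-12)

    def test_weighted_mean_bounded_by_amounts(self, small_zips):
        rng = np.random.default_rng(4)
        rel = releases_frame(
            [
                (f"F{i}", 40.0 + rng.uniform(-0.2, 0.2), -85.0 + rng.uniform(-0.2, 0.2),
                 "chem0", rng.uniform(10, 90))
                for i in range(8)
            ]
        )
        m = geo.build_air_exposure(small_zips, rel)
        vals = m.values[m.values > 0]
        assert np.all(vals >= rel["amount"].min() - 1e-9)
        assert np.all(vals <= rel["amount"].max() + 1e-9)

    def test_permutation_invariance(self, small_zips):
        rng = np.random.default_rng(5)
        rel = releases_frame(
            [
                (f"F{i}", 40.0 + rng.uniform(-0.2, 0.2), -85.0 + rng.uniform(-0.2, 0.2),
                 f"chem{i % 2}", rng.uniform(1, 50))
                for i in range(10)
            ]
        )
        m1 = geo.build_air_exposure(small_zips, rel)
        m2 = geo.build_air_exposure(small_zips, rel.sample(frac=1.0, random_state=9))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)

    def test_weighted_sum_mode_discounts_by_distance(self):
        zips = zips_frame([("Z1", 0.0, 0.0, 10_000)])
        off_lat = 10.0 / (R * math.pi / 180.0)
        rel = releases_frame(
            [("F1", 0.0, 0.0, "b", 100.0), ("F2", off_lat, 0.0, "b", 100.0)]
        )
        rel["population"] = 1000
        cfg = geo.KernelConfig(mode="weighted_sum")
        val = geo.build_air_exposure(zips, rel, cfg).values[0, 0]
        # (100*1 + 100*k)/2 with k = exp(-10^2/(2 sigma^2))
        k = math.exp(-100.0 / (2 * cfg.sigma_miles**2))
        assert val == pytest.approx(100.0 * (1 + k) / 2, rel=1e-9)

    def test_rejects_negative_amount_and_empty_chemicals(self, small_zips):
        with pytest.raises(ValueError, match="amount"):
            geo.build_air_exposure(
                small_zips, releases_frame([("F1", 40.0, -85.0, "b", -1.0)])
            )
        with pytest.raises(ValueError, match="chemical"):
            geo.build_air_exposure(small_zips, releases_frame([]))


class TestWaterExposure:
    def test_single_measurement(self, small_zips):
        meas = pd.DataFrame(
            [["Z00000", "chlorate", 4.0, "a"]],
            columns=["zip_id", "chemical_id", "concentration", "source"],
        )
        m = geo.build_water_exposure(small_zips, meas)
        assert m.to_frame().loc["Z00000", "chlorate"] == 4.0

    def test_duplicate_sources_are_averaged(self, small_zips):
        meas = pd.DataFrame(
            [["Z00000", "chlorate", 2.0, "a"], ["Z00000", "chlorate", 6.0, "b"]],
            columns=["zip_id", "chemical_id", "concentration", "source"],
        )
        m = geo.build_water_exposure(small_zips, meas)
        assert m.to_frame().loc["Z00000", "chlorate"] == pytest.approx(4.0)

    def test_unmonitored_zip_absent_not_zero(self, small_zips):
        meas = pd.DataFrame(
            [["Z00000", "chlorate", 4.0, "a"]],
            columns=["zip_id", "chemical_id", "concentration", "source"],
        )
        m = geo.build_water_exposure(small_zips, meas)
        assert "Z00001" not in m.zip_ids

    def test_unknown_zip_warns_and_skips(self, small_zips):
        meas = pd.DataFrame(
            [["Z00000", "chlorate", 4.0, "a"], ["NOPE", "chlorate", 9.0, "a"]],
            columns=["zip_id", "chemical_id", "concentration", "source"],
        )
        with pytest.warns(UserWarning, match="unknown zip"):
            m = geo.build_water_exposure(small_zips, meas)
        assert list(m.zip_ids) == ["Z00000"]
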