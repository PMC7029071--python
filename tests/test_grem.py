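import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from echodens.grem import (
    DetectionGeometry,
    UnsupportedRegimeError,
    estimate_grid,
    grem_density,
    mean_profile_width,
    profile_width_altitude,
    summarize_grem,
)

THETA = np.deg2rad(200.0)


class TestMeanProfileWidth:
    def test_hand_evaluated_reference_case(self):
        w = mean_profile_width(DetectionGeometry(30.0, THETA, np.deg2rad(42.0)))
        assert w == pytest.approx(12.58, abs=0.01)

    def test_vanishing_signal_angle_gives_zero_width(self):
        w = mean_profile_width(DetectionGeometry(30.0, THETA, 1e-9))
        assert w == pytest.approx(0.0, abs=1e-6)

    @given(r=st.floats(1.0, 100.0), alpha=st.floats(5.0, 170.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_radius_and_bounded_by_diameter(self, r, alpha):
        g1 = DetectionGeometry(r, THETA, np.deg2rad(alpha))
        g2 = DetectionGeometry(2 * r, THETA, np.deg2rad(alpha))
        w1, w2 = mean_profile_width(g1), mean_profile_width(g2)
        assert w2 == pytest.approx(2 * w1, rel=1e-12)
        assert 0.0 <= w1 <= 2 * r

    def test_out_of_regime_rejected_not_extrapolated(self):
        with pytest.raises(UnsupportedRegimeError):
            mean_profile_width(DetectionGeometry(30.0, np.deg2rad(90.0), np.deg2rad(42.0)))
        with pytest.raises(UnsupportedRegimeError):
            mean_profile_width(DetectionGeometry(30.0, THETA, np.deg2rad(200.0)))

    def test_matches_geometric_quadrature_oracle(self):
        """Independent oracle: project the sector-intersection region onto
        the axis perpendicular to each heading and average over headings."""

        def width(phi, r, theta, alpha):
            pieces = []
            a2, b2 = phi + np.pi - alpha / 2, phi + np.pi + alpha / 2
            for k in (-2 * np.pi, 0.0, 2 * np.pi):
                lo, hi = max(-theta / 2, a2 + k), min(theta / 2, b2 + k)
                if hi > lo:
                    pieces.append((lo, hi))
            if not pieces:
                return 0.0
            los, his = [0.0], [0.0]
            for a, b in pieces:
                cand = [a, b] + [c for c in
                                 (phi + np.pi / 2, phi - np.pi / 2,
                                  phi + np.pi / 2 - 2 * np.pi, phi - np.pi / 2 + 2 * np.pi)
                                 if a <= c <= b]
                vals = [r * np.sin(psi - phi) for psi in cand]
                los.append(min(vals))
                his.append(max(vals))
            return max(his) - min(los)

        for alpha_deg in (25.0, 42.0, 70.0):
            alpha = np.deg2rad(alpha_deg)
            phis = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
            oracle = np.mean([width(p, 30.0, THETA, alpha) for p in phis])
            formula = mean_profile_width(DetectionGeometry(30.0, THETA, alpha))
            assert formula == pytest.approx(oracle, rel=1e-3)


class TestAltitudeProfileWidth:
    def test_tangent_case_is_exactly_zero(self):
        g = DetectionGeometry(30.0, THETA, np.deg2rad(42.0), dh=30.0)
        assert profile_width_altitude(g) == 0.0

    def test_ground_level_reduces_to_full_chord(self):
        g = DetectionGeometry(30.0, THETA, np.deg2rad(42.0), dh=0.0)
        assert profile_width_altitude(g) == pytest.approx(
            2 * 30.0 * np.sin(np.deg2rad(21.0)), rel=1e-12)
        assert profile_width_altitude(g) == pytest.approx(21.50, abs=0.01)

    def test_elevated_flight_shrinks_width(self):
        g = DetectionGeometry(30.0, THETA, np.deg2rad(42.0), dh=18.0)
        assert profile_width_altitude(g) == pytest.approx(17.20, abs=0.01)


class TestDensity:
    def test_zero_count_zero_density(self):
        assert grem_density(0, 5.4, 28800.0, 12.58) == 0.0

    def test_hand_arithmetic(self):
        d = grem_density(120, 5.4, 28800.0, 12.58)
        assert d == pytest.approx(61.3, abs=0.1)

    def test_doubling_effort_halves_density(self):
        d1 = grem_density(120, 5.4, 28800.0, 12.58)
        d2 = grem_density(120, 5.4, 2 * 28800.0, 12.58)
        assert d2 == pytest.approx(d1 / 2)

    def test_nonpositive_inputs_rejected(self):
        for bad in ((120, 0.0, 1.0, 1.0), (120, 1.0, 0.0, 1.0), (120, 1.0, 1.0, 0.0)):
            with pytest.raises(ValueError):
                grem_density(*bad)
        with pytest.raises(ValueError):
            grem_density(-1, 1.0, 1.0, 1.0)


class TestEstimateGrid:
    @staticmethod
    def _inputs(pip_profile, n_sites=1, z_per_site=4):
        night = pd.Timestamp("2016-06-20")
        rows, nrows, rrows = [], [], []
        for i in range(n_sites):
            sid = f"s{i}"
            for k in range(z_per_site):
                rows.append({"site_id": sid, "species": pip_profile.name,
                             "timestamp": night + pd.Timedelta(hours=22, minutes=10 * k),
                             "variant": "strict", "excluded": False,
                             "night_id": night, "period_id": "P1"})
            nrows.append({"site_id": sid, "night_id": night, "period_id": "P1",
                          "sunset": night + pd.Timedelta(hours=21),
                          "sunrise": night + pd.Timedelta(hours=29),
                          "duration_t": 8 * 3600.0})
            for spl in (90.0, 120.0):
                rrows.append({"site_id": sid, "night_id": night,
                              "spl_db": spl, "r_m": 15.0 if spl == 90.0 else 40.0})
        return pd.DataFrame(rows), pd.DataFrame(nrows), pd.DataFrame(rrows)

    def test_pooling_two_identical_sites_leaves_density_unchanged(
            self, pip_profile, detector):
        calls1, nights1, ranges1 = self._inputs(pip_profile, n_sites=1)
        calls2, nights2, ranges2 = self._inputs(pip_profile, n_sites=2)
        g1 = estimate_grid(calls1, nights1, pip_profile, detector, ranges1)
        g2 = estimate_grid(calls2, nights2, pip_profile, detector, ranges2)
        merged = g1.merge(g2, on=["alpha_deg", "spl_db"], suffixes=("_1", "_2"))
        assert np.allclose(merged["density_per_km2_1"], merged["density_per_km2_2"])
        assert (g2["z"] == 2 * g1["z"]).all()

    def test_zero_passes_give_zero_density_on_full_grid(self, pip_profile, detector):
        # surveyed night with no calls at all: effort counts, densities are 0
        calls, nights, ranges = self._inputs(pip_profile, z_per_site=1)
        grid = estimate_grid(calls.head(0), nights, pip_profile, detector, ranges)
        assert len(grid) == len(pip_profile.signal_angles) * 2 * 2  # alpha x SPL x variant
        assert (grid["density_per_km2"] == 0.0).all()

    def test_excluded_records_do_not_count(self, pip_profile, detector):
        calls, nights, ranges = self._inputs(pip_profile)
        calls.loc[0, "excluded"] = True
        grid = estimate_grid(calls, nights, pip_profile, detector, ranges)
        assert (grid["z"] == 3).all()

    def test_summary_is_mean_over_grid_and_periods(self, pip_profile, detector):
        calls, nights, ranges = self._inputs(pip_profile)
        grid = estimate_grid(calls, nights, pip_profile, detector, ranges)
        summary = summarize_grem(grid)
        expected = grid["density_per_km2"].mean()  # single variant here
        assert summary["mean_density_per_km2"].iloc[0] == pytest.approx(expected)
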