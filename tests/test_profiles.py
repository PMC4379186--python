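"""Profile functions: printed values, symmetry, continuity and the
area-normalization of the localized turnover-rate profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from keradyn import profiles as pf


class TestSpatialGrid:
    def test_default_grid_spans_domain_symmetrically(self, grid):
        assert grid.n_points == 200
        assert grid.x[0] == -22.5 and grid.x[-1] == 22.5
        assert np.all(np.diff(grid.x) > 0)
        np.testing.assert_allclose(grid.x, -grid.x[::-1], atol=1e-12)

    @pytest.mark.parametrize("bad", [{"L": -1.0}, {"n_points": 3},
                                     {"n_points": 201}])
    def test_invalid_grid_rejected(self, bad):
        with pytest.raises(ValueError):
            pf.SpatialGrid(**bad)


class TestDriftSpeeds:
    def test_const_speed_values(self, fixed):
        # zero at the centre, saturating at u near the membrane
        assert pf.eval_drift_speed_const(0.0) == 0.0
        assert abs(pf.eval_drift_speed_const(22.5) - fixed.u) < 1e-12
        assert abs(pf.eval_drift_speed_const(-22.5) - fixed.u) < 1e-12

    def test_const_speed_even_and_bounded(self, grid, fixed):
        v = pf.eval_drift_speed_const(grid.x)
        np.testing.assert_allclose(v, v[::-1], rtol=1e-12)
        assert np.all(v >= 0) and np.all(v < fixed.u)

    def test_var_speed_peak_and_nucleus_values(self):
        # at the first Gaussian centre the second contributes < 1e-12;
        # at the centre both Gaussians are ~2.3 widths out (value frozen
        # from direct evaluation of the printed coefficients)
        assert pf.eval_drift_speed_var(17.39) == pytest.approx(
            0.003372, rel=1e-6)
        assert pf.eval_drift_speed_var(0.0) == pytest.approx(3.386e-5,
                                                             rel=1e-3)
        assert np.all(pf.eval_drift_speed_var(
            np.linspace(-22.5, 22.5, 500)) > 0)

    def test_var_speed_near_mirror_symmetry(self, grid):
        # the fitted Gaussian pair is a near-mirror: mismatch < 1% of the
        # peak speed everywhere (pointwise relative mismatch reaches ~4%
        # only near the centre, where the speed is ~100x below peak)
        u = pf.eval_drift_speed_var(grid.x)
        assert np.max(np.abs(u - u[::-1])) / np.max(u) < 0.01
        assert np.max(np.abs(u - u[::-1]) / u) < 0.04


class TestSmoothSign:
    def test_anchor_values(self):
        assert pf.smooth_sgn(0.0) == 0.0
        assert pf.smooth_sgn(50.0) == pytest.approx(1.0, abs=1e-12)
        assert pf.smooth_sgn(-50.0) == pytest.approx(-1.0, abs=1e-12)

    def test_rejects_nonpositive_smoothing(self):
        with pytest.raises(ValueError):
            pf.smooth_sgn(1.0, a=0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-30, 30), st.floats(-30, 30))
    def test_odd_and_monotone(self, x, y):
        assert pf.smooth_sgn(-x) == pytest.approx(-pf.smooth_sgn(x),
                                                  abs=1e-12)
        if x + 1e-9 < y:  # strict ordering beyond float resolution
            assert pf.smooth_sgn(x) < pf.smooth_sgn(y)


def _domain_integral(func, L=22.5):
    value, _ = quad(lambda t: float(func(np.array([t]))[0]), -L, L,
                    limit=400, epsabs=1e-6)
    return value


class TestRateProfiles:
    @pytest.mark.parametrize("func", [
        lambda x: pf.eval_kass_sources(x, -1.0),
        lambda x: pf.eval_kdis_sinks(x, 0.0),
        lambda x: pf.eval_kdis_mollify(x, -0.5),
    ])
    def test_nonpositive_level_rejected(self, func):
        with pytest.raises(ValueError):
            func(np.zeros(3))

    def test_sources_baseline_at_centre(self):
        # the fitted peaks sit >= 9 widths from the centre
        for k in (1e-3, 0.5):
            assert pf.eval_kass_sources(0.0, k) == pytest.approx(
                0.01 * k, rel=1e-6)

    def test_sources_peaks_near_membrane(self, grid):
        prof = pf.eval_kass_sources(grid.x, 1e-3)
        assert abs(grid.x[np.argmax(prof)]) > 18.0

    def test_sources_area_reflects_tail_clipping(self):
        # the k_max normalization matches a constant rate over the full
        # line; ~5.3% of the peripheral Gaussian mass falls outside the
        # cell, so the domain integral is 0.947 of 2*L*k_ass (value
        # frozen from adaptive quadrature of the printed coefficients)
        ratio = _domain_integral(
            lambda x: pf.eval_kass_sources(x, 1e-3)) / (45.0 * 1e-3)
        assert ratio == pytest.approx(0.9475, abs=0.002)

    def test_sinks_area_normalization(self):
        ratio = _domain_integral(
            lambda x: pf.eval_kdis_sinks(x, 1e-3)) / (45.0 * 1e-3)
        assert abs(ratio - 1.0) < 0.02

    def test_sinks_symmetry_and_band_maxima(self, grid):
        prof = pf.eval_kdis_sinks(grid.x, 1e-3)
        assert np.max(np.abs(prof - prof[::-1])) / np.max(prof) < 0.01
        assert 8.0 < abs(grid.x[np.argmax(prof)]) < 15.0

    def test_sinks_dips_negative_and_clamps(self, grid):
        raw = pf.eval_kdis_sinks(grid.x, 1e-3)
        clamped = pf.eval_kdis_sinks(grid.x, 1e-3, clamp=True)
        assert raw.min() < 0  # signed Gaussian fit dips between peaks
        assert clamped.min() == 0.0
        np.testing.assert_array_equal(clamped, np.maximum(raw, 0.0))

    def test_mollify_branch_values(self):
        k = 0.9998
        kb = 0.01 * k
        kmax = 2.0 * (k - kb)
        assert pf.eval_kdis_mollify(0.0, k) == pytest.approx(kb + kmax)
        assert pf.eval_kdis_mollify(-20.0, k) == pytest.approx(kb)

    def test_mollify_area_normalization(self):
        ratio = _domain_integral(
            lambda x: pf.eval_kdis_mollify(x, 1e-3)) / (45.0 * 1e-3)
        assert abs(ratio - 1.0) < 0.01

    def test_mollify_continuity_at_every_junction(self):
        for knot in (-15.0, -7.5, 7.5, 15.0):
            for edge in (knot - 1.0, knot + 1.0):
                left, right = pf.eval_kdis_mollify(
                    np.array([edge - 1e-9, edge + 1e-9]), 1.0)
                assert abs(left - right) < 1e-7

    def test_rate_profiles_finite_and_symmetric_on_grid(self, grid):
        # the three-Gaussian Sources fit is only approximately mirrored
        # (one right-side vs two left-side peaks): its measured mismatch
        # is 4.7% of the peak; Mollify is symmetric by construction
        sources = pf.eval_kass_sources(grid.x, 1e-3)
        mollify = pf.eval_kdis_mollify(grid.x, 1e-3)
        for prof in (sources, mollify):
            assert np.all(np.isfinite(prof))
        assert np.max(np.abs(sources - sources[::-1])) / np.max(sources) \
            == pytest.approx(0.047, abs=0.005)
        assert np.max(np.abs(mollify - mollify[::-1])) < 1e-12


class TestConcentrationProfiles:
    def test_initial_profile_printed_values(self):
        assert pf.eval_f0(0.0) == pytest.approx(506.5)
        assert pf.eval_f0(-22.4) == pytest.approx(50.0)
        assert pf.eval_f0(22.4) == pytest.approx(50.0)

    def test_initial_profile_continuity_and_floor(self, grid):
        for edge in (-22.0, -20.0, 20.0, 22.0):
            a, b = pf.eval_f0(np.array([edge - 1e-6, edge + 1e-6]))
            assert abs(a - b) < 1e-3
        prof = pf.eval_f0(grid.x)
        assert np.all(prof >= 50.0 - 1e-9)

    def test_initial_profile_symmetric_on_polynomial_region(self, grid):
        # the fitted polynomial P is symmetric; the printed junction
        # branches are not (the left one matches value only, the right
        # one value and slope), so symmetry holds away from |x| > 20
        inner = np.abs(grid.x) <= 20.0
        prof = pf.eval_f0(grid.x)[inner]
        assert np.max(np.abs(prof - prof[::-1])) / np.max(prof) < 0.01

    def test_initial_profile_junctions_asymmetric_as_printed(self):
        # frozen consequence of the printed two-sided mollification
        left = float(pf.eval_f0(-21.0))
        right = float(pf.eval_f0(21.0))
        assert right - left == pytest.approx(75.3, abs=1.0)

    def test_final_profile_printed_values(self):
        assert pf.eval_ffinal(0.0) == pytest.approx(604.1)
        expected_edge = (-0.003255 * 22.5 ** 4 + 2.61e-17 * 22.5 ** 3
                         + 0.4899 * 22.5 ** 2 + 1.558e-15 * 22.5 + 604.1)
        assert pf.eval_ffinal(22.5) == pytest.approx(expected_edge)
        assert pf.eval_ffinal(22.5) == pytest.approx(
            pf.eval_ffinal(-22.5), rel=1e-9)

    def test_both_measured_profiles_have_calibration_mean(self, grid):
        # internal consistency of the published fits: the fluorescence
        # calibration sets the domain-mean concentration to 520 uM
        for func in (pf.eval_f0, pf.eval_ffinal):
            mean = _domain_integral(func) / 45.0
            assert mean == pytest.approx(520.0, rel=0.01)


class TestFluorescenceConversion:
    def test_linear_calibration(self):
        assert pf.fluorescence_to_concentration(0.0, 100.0) == 0.0
        assert pf.fluorescence_to_concentration(100.0, 100.0) == 520.0
        assert (pf.fluorescence_to_concentration(4.0, 2.0, 10.0)
                == 2 * pf.fluorescence_to_concentration(2.0, 2.0, 10.0))

    def test_rejects_nonpositive_mean_fluorescence(self):
        with pytest.raises(ValueError):
            pf.fluorescence_to_concentration(1.0, 0.0)


def test_profile_csv_roundtrip(tmp_path, grid):
    values = pf.eval_f0(grid.x)
    path = tmp_path / "f0.csv"
    pf.export_profile_csv(path, grid.x, values, value_name="f0_uM")
    lines = path.read_text().splitlines()
    assert lines[0] == "x_um,f0_uM"
    assert len(lines) == grid.n_points + 1
    loaded = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(loaded[:, 1], values)
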