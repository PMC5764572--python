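import numpy as np
import pytest

from coloc3d import (
    CACalibration,
    CentroidPair,
    compute_ca_stats,
    correct_displacement,
    fit_ca_gradient,
    select_measurement_region,
)

# Reference chromatic-aberration regime of a well-corrected two-camera path:
# mean shift (13.1, 15.8, 3.5) nm with SD (9.1, 7.5, 17.6) nm laterally/axially.
CA_MEAN = np.array([13.1, 15.8, 3.5])
CA_SD = np.array([9.1, 7.5, 17.6])


def _standard_pairs(n=166, seed=0):
    """Dual-labeled standard: red = green - (CA_MEAN + noise)."""
    rng = np.random.default_rng(seed)
    green = rng.uniform(0, 10_000, size=(n, 3))
    ca = CA_MEAN + CA_SD * rng.standard_normal((n, 3))
    red = green - ca
    return [
        CentroidPair(Xg=g[0], Yg=g[1], Zg=g[2], Xr=r[0], Yr=r[1], Zr=r[2])
        for g, r in zip(green, red)
    ]


class TestComputeCAStats:
    def test_identical_channels_give_zero(self):
        pairs = [CentroidPair(1.0, 2.0, 3.0, 1.0, 2.0, 3.0)] * 3
        calib = compute_ca_stats(pairs)
        assert calib.means == (0.0, 0.0, 0.0)
        assert calib.sds == (0.0, 0.0, 0.0)

    def test_hand_computed_two_pairs(self):
        pairs = [
            CentroidPair(10.0, 20.0, 30.0, 4.0, 8.0, 12.0),  # diff (6, 12, 18)
            CentroidPair(0.0, 0.0, 0.0, -10.0, -20.0, -30.0),  # diff (10, 20, 30)
        ]
        calib = compute_ca_stats(pairs)
        assert calib.means == (8.0, 16.0, 24.0)
        # sample SD with n-1: |d1-d2|/sqrt(2)
        np.testing.assert_allclose(calib.sds, np.array([4, 8, 12]) / np.sqrt(2))

    def test_recovers_reference_ca_regime(self):
        n = 166
        calib = compute_ca_stats(_standard_pairs(n=n, seed=42))
        tol = 3 * CA_SD / np.sqrt(n)
        assert np.all(np.abs(np.array(calib.means) - CA_MEAN) < tol)
        assert np.all(np.abs(np.array(calib.sds) - CA_SD) < 0.3 * CA_SD)

    def test_translation_equivariance(self):
        pairs = _standard_pairs(n=50, seed=1)
        shifted = [
            CentroidPair(p.Xg + 5.0, p.Yg - 3.0, p.Zg + 11.0, p.Xr, p.Yr, p.Zr) for p in pairs
        ]
        a = compute_ca_stats(pairs)
        b = compute_ca_stats(shifted)
        np.testing.assert_allclose(
            np.array(b.means) - np.array(a.means), [5.0, -3.0, 11.0], atol=1e-9
        )
        np.testing.assert_allclose(b.sds, a.sds, atol=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_ca_stats([CentroidPair(0, 0, 0, 0, 0, 0)])

    def test_non_finite_coordinate_names_record(self):
        pairs = _standard_pairs(n=3)
        pairs[1] = CentroidPair(np.nan, 0, 0, 0, 0, 0, pair_id="bad")
        with pytest.raises(ValueError, match="record 1"):
            compute_ca_stats(pairs)


class TestFitCAGradient:
    def test_exact_linear_ca_recovered(self):
        # CAx falls ~30 nm over 280 px: slope -30/280 nm/px
        xs = np.linspace(0, 280, 30)
        pairs = [
            CentroidPair(Xg=30.0 - 30.0 / 280.0 * x, Yg=0, Zg=0, Xr=0, Yr=0, Zr=0, x_px=x, y_px=50)
            for x in xs
        ]
        g = fit_ca_gradient(pairs, "x")
        assert g.slope == pytest.approx(-30.0 / 280.0, abs=1e-12)
        assert g.intercept == pytest.approx(30.0, abs=1e-9)
        assert g.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_gradient_slope_within_ci(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(0, 280, 200)
        noise = 5.0 * rng.standard_normal(200)
        pairs = [
            CentroidPair(Xg=30 - 30 / 280 * x + e, Yg=0, Zg=0, Xr=0, Yr=0, Zr=0, x_px=x, y_px=0)
            for x, e in zip(xs, noise)
        ]
        g = fit_ca_gradient(pairs, "x")
        se = 5.0 / (np.std(xs) * np.sqrt(200))
        assert abs(g.slope - (-30 / 280)) < 3 * se

    def test_constant_ca_gives_zero_slope(self):
        pairs = [
            CentroidPair(Xg=12.0, Yg=0, Zg=0, Xr=0, Yr=0, Zr=0, x_px=x, y_px=0)
            for x in (0.0, 100.0, 200.0)
        ]
        g = fit_ca_gradient(pairs, "x")
        assert g.slope == pytest.approx(0.0, abs=1e-12)
        assert g.intercept == pytest.approx(12.0)

    def test_missing_positions_rejected(self):
        pairs = [CentroidPair(1, 0, 0, 0, 0, 0)] * 5
        with pytest.raises(ValueError, match="field position"):
            fit_ca_gradient(pairs, "x")

    def test_axial_gradient_not_offered(self):
        with pytest.raises(ValueError):
            fit_ca_gradient(_standard_pairs(5), "z")


class TestCorrectDisplacement:
    CALIB = CACalibration(13.1, 15.8, 3.5, 9.1, 7.5, 17.6, n=166)

    def test_mean_subtraction_arithmetic(self):
        pair = CentroidPair(Xg=73.1, Yg=15.8, Zg=3.5, Xr=0.0, Yr=0.0, Zr=0.0)
        sx, sy, sz = correct_displacement(pair, self.CALIB)
        assert sx == pytest.approx(60.0)
        assert sy == pytest.approx(0.0)
        assert sz == pytest.approx(0.0)

    def test_zero_calibration_is_identity(self):
        pair = CentroidPair(5.0, 6.0, 7.0, 1.0, 2.0, 3.0)
        zero = CACalibration(0, 0, 0, 0, 0, 0, n=2)
        assert correct_displacement(pair, zero) == pair.raw_difference

    def test_calibration_set_mean_corrected_to_zero(self):
        pairs = _standard_pairs(n=80, seed=9)
        calib = compute_ca_stats(pairs)
        corrected = np.array([correct_displacement(p, calib) for p in pairs])
        np.testing.assert_allclose(corrected.mean(axis=0), 0.0, atol=1e-9)

    def test_gradient_mode_requires_gradients_and_position(self):
        pair = CentroidPair(1, 2, 3, 0, 0, 0, x_px=10.0, y_px=10.0)
        with pytest.raises(ValueError, match="gradient"):
            correct_displacement(pair, self.CALIB, mode="gradient")


class TestMeasurementRegion:
    def test_window_filtering(self):
        inside = CentroidPair(0, 0, 0, 0, 0, 0, x_px=150.0, y_px=100.0)
        outside = CentroidPair(0, 0, 0, 0, 0, 0, x_px=400.0, y_px=100.0)
        missing = CentroidPair(0, 0, 0, 0, 0, 0)
        kept = select_measurement_region([inside, outside, missing])
        assert kept == [inside]
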