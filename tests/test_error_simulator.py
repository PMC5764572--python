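import numpy as np
import pytest

from coloc3d import SimulationConfig, infer_cdsd, simulate_field, sweep_nuisance, sweep_separations


class TestSimulateField:
    def test_grid_has_551_positions(self):
        cfg = SimulationConfig()
        assert cfg.grid_shape == (29, 19)
        assert cfg.n_positions == 551
        result = simulate_field(cfg)
        assert len(result.records) == 551

    def test_zero_noise_identity(self):
        cfg = SimulationConfig(
            S=60.0, cdsd=(0, 0, 0), ca_sd=(0, 0, 0), z_offset=0.0, seed=5
        )
        result = simulate_field(cfg)
        np.testing.assert_allclose(result.records["Sx"], 60.0, atol=1e-12)
        np.testing.assert_allclose(result.records["Sy"], 0.0, atol=1e-12)
        np.testing.assert_allclose(result.records["Sz"], 0.0, atol=1e-12)
        s = result.summary
        assert s.s3d_mean == pytest.approx(60.0, abs=1e-12)
        assert s.s3d_sd == 0.0
        assert s.alpha_mean == 0.0 and s.beta_mean == 0.0
        assert s.z_offset == 0.0

    def test_seed_determinism(self):
        cfg = SimulationConfig(S=40.0, seed=9, n_reps=2)
        a = simulate_field(cfg)
        b = simulate_field(cfg)
        assert a.records.equals(b.records)

    def test_mean_ca_cancellation(self):
        base = SimulationConfig(S=60.0, seed=21)
        shifted = base.replace(ca_mean=(250.0, -180.0, 90.0))
        a = simulate_field(base)
        b = simulate_field(shifted)
        np.testing.assert_allclose(a.records["Sx"], b.records["Sx"], atol=1e-9)
        np.testing.assert_allclose(a.records["Sz"], b.records["Sz"], atol=1e-9)

    def test_positive_bias_of_raw_mean(self):
        for s_true in (0.0, 20.0, 60.0):
            result = simulate_field(SimulationConfig(S=s_true, seed=2, n_reps=3))
            assert result.summary.s3d_mean >= s_true

    def test_noise_floor_matches_brute_force_oracle(self):
        """At S=0 the mean distance is E|N(0, diag)| with per-axis variance
        2 CDsd^2 + CAsd^2; checked against a direct Monte-Carlo expectation."""
        cfg = SimulationConfig(S=0.0, seed=3, n_reps=20)
        result = simulate_field(cfg)
        sd = np.sqrt(2 * np.array(cfg.cdsd) ** 2 + np.array(cfg.ca_sd) ** 2)
        rng = np.random.default_rng(99)
        oracle = np.linalg.norm(rng.standard_normal((200_000, 3)) * sd, axis=1).mean()
        assert result.summary.s3d_mean == pytest.approx(oracle, rel=0.02)

    def test_gradient_mode_matches_random_mode(self):
        """Linear CA field gradients with matched mean/SD give the same
        summary statistics as randomly drawn CA, within 1 nm."""
        rand = simulate_field(SimulationConfig(S=60.0, ca_mode="random", seed=4, n_reps=10))
        grad = simulate_field(SimulationConfig(S=60.0, ca_mode="gradient", seed=4, n_reps=10))
        assert abs(rand.summary.s3d_mean - grad.summary.s3d_mean) < 1.0
        assert abs(rand.summary.ml3d.mu_hat - grad.summary.ml3d.mu_hat) < 1.0

    def test_z_offset_adds_to_measured_sz(self):
        result = simulate_field(SimulationConfig(S=60.0, z_offset=80.0, seed=6, n_reps=5))
        assert result.summary.z_offset == pytest.approx(80.0, abs=3.0)

    def test_rep_sampling_error_is_small(self):
        cfg = SimulationConfig(S=60.0, seed=8, n_reps=20)
        rm = simulate_field(cfg).rep_means()
        se = rm["s3d_mean"].std(ddof=1)
        assert se <= rm["s3d_sd"].mean() / np.sqrt(551) * 1.5

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(spacing_px=7)


class TestSweeps:
    def test_separation_sweep_monotone(self):
        cfg = SimulationConfig(seed=1, n_reps=2)
        table = sweep_separations(cfg, [0, 10, 15, 20, 40, 60, 80, 100])
        assert (np.diff(table["s3d_mean"]) >= 0).all()

    def test_zs3d_restores_zero_offset_s3d(self):
        cfg = SimulationConfig(S=60.0, seed=13, n_reps=10)
        table = sweep_nuisance(cfg, "z_offset", [0.0, 80.0])
        zero_row, offset_row = table.iloc[0], table.iloc[1]
        assert offset_row["zs3d_mean"] == pytest.approx(zero_row["s3d_mean"], abs=0.5)

    def test_ksd_inflates_raw_sd(self):
        cfg = SimulationConfig(S=60.0, seed=14, n_reps=5)
        table = sweep_nuisance(cfg, "Ksd", [0.0, 15.0])
        assert table.iloc[1]["s3d_sd"] > table.iloc[0]["s3d_sd"]

    def test_large_casd_inflates_separation(self):
        """CA spread at the (26, 23, 43) nm scale inflates a 40 nm true
        separation far above the low-CAsd value."""
        cfg = SimulationConfig(S=40.0, seed=15, n_reps=3)
        scale = 26.0 / 9.1
        table = sweep_nuisance(cfg, "CAsd_scale", [1.0, scale])
        assert table.iloc[0]["s3d_mean"] < 50.0
        assert table.iloc[1]["s3d_mean"] > 55.0

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sweep_nuisance(SimulationConfig(), "coverslip", [1.0])

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            sweep_separations(SimulationConfig(), [])


class TestInferCdsd:
    def test_reference_delta_sd_implies_4nm_lateral(self):
        """A Delta SD of sqrt(2)*4 nm inverts to CDsd ~ (4, 4, 8) nm."""
        target = np.sqrt(2) * 4.0
        (cx, cy, cz), achieved = infer_cdsd(target, S=60.0, config=SimulationConfig(seed=3))
        assert cx == pytest.approx(4.0, abs=0.2)
        assert cz == 2 * cx
        assert achieved == pytest.approx(target, abs=0.1)

    def test_linearity_of_inversion(self):
        cfg = SimulationConfig(seed=4)
        (c1, _, _), _ = infer_cdsd(3.0, S=60.0, config=cfg)
        (c2, _, _), _ = infer_cdsd(6.0, S=60.0, config=cfg)
        assert c2 == pytest.approx(2 * c1, rel=0.05)

    def test_zero_target_unreachable(self):
        with pytest.raises(ValueError):
            infer_cdsd(0.0, S=60.0)
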