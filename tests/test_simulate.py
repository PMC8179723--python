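"""Monte Carlo engine: initialization, diffusion, boundaries, photon statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from nifs import (
    AnnularProfile,
    GaussianEllipsoidProfile,
    Nifs3DProfile,
    SimulationConfig,
    calibrate_brightness,
    run_simulation,
    run_single,
)
from nifs.simulate import (
    apply_boundaries,
    emit_photons,
    init_positions,
    step_particles,
)


def _fcs_config(**kw):
    defaults = dict(
        box=(2e-6, 2e-6, 2e-6), n_particles=100, D=1e-12,
        profile=GaussianEllipsoidProfile(r0=0.5e-6, z0=1.5e-6),
        mode="FCS3D", n_steps=1000, brightness=0.01, seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _nifs_config(**kw):
    defaults = dict(
        box=(1e-6, 1e-6, 1e-6), n_particles=100, D=1e-12,
        profile=Nifs3DProfile(r0=60e-9, z0=12e-9),
        mode="NIFS3D", n_steps=1000, brightness=0.05, seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_zero_particles_rejected(self):
        with pytest.raises(ValueError):
            _fcs_config(n_particles=0)

    def test_brightness_above_bernoulli_cap_rejected(self):
        with pytest.raises(ValueError):
            _fcs_config(brightness=0.2)

    @pytest.mark.parametrize("field,value", [("D", 0.0), ("dt", -1e-7),
                                             ("n_steps", 0), ("mode", "4D")])
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            _fcs_config(**{field: value})

    def test_concentration(self):
        cfg = _fcs_config(box=(1e-6, 1e-6, 1e-6), n_particles=500)
        assert cfg.concentration == pytest.approx(500 / 1e-18)

    def test_scaled_applies_floors(self):
        cfg = _fcs_config(n_steps=10_000_000, n_runs=20)
        small = cfg.scaled(1e-4)
        assert small.n_steps == 100_000
        assert small.n_runs == 4


class TestInitPositions:
    def test_inside_box(self, rng):
        cfg = _fcs_config(n_particles=1000)
        pos = init_positions(cfg, rng)
        assert pos.shape == (1000, 3)
        assert np.all(pos >= 0) and np.all(pos < np.array(cfg.box))

    def test_uniform_marginals(self):
        """Kolmogorov-Smirnov on every coordinate at alpha = 0.01."""
        cfg = _fcs_config(n_particles=100_000)
        pos = init_positions(cfg, np.random.default_rng(7))
        for ax, L in enumerate(cfg.box):
            p = stats.kstest(pos[:, ax] / L, "uniform").pvalue
            assert p > 0.01

    def test_2d_mode_pins_plane_height(self, rng):
        cfg = _fcs_config(mode="2D", profile=AnnularProfile(a0=20e-9, b0=8e-9),
                          z_plane=2.3e-9)
        pos = init_positions(cfg, rng)
        assert np.all(pos[:, 2] == 2.3e-9)


class TestStepParticles:
    def test_zero_diffusion_leaves_positions(self, rng):
        pos = rng.random((50, 3))
        np.testing.assert_array_equal(step_particles(pos, 0.0, 1e-7, rng), pos)

    def test_displacement_standard_deviation(self):
        """Per-axis displacements have std sqrt(2 D dt) (Einstein relation)."""
        D, dt = 3e-11, 1e-7
        rng = np.random.default_rng(11)
        pos = np.zeros((1_000_000, 3))
        disp = step_particles(pos, D, dt, rng)
        sigma = np.sqrt(2 * D * dt)
        assert sigma == pytest.approx(2.449e-9, abs=5e-12)
        for ax in range(3):
            assert disp[:, ax].std() == pytest.approx(sigma, rel=0.005)

    def test_msd_linear_in_time(self):
        """Ensemble MSD after k steps is 2 D k dt per axis within 5%."""
        D, dt, n = 1e-12, 1e-7, 100
        rng = np.random.default_rng(5)
        pos = np.zeros((n, 3))
        ks = [2_000, 5_000, 10_000]
        msds = {}
        step_block = rng.standard_normal((10_000, n, 3)) * np.sqrt(2 * D * dt)
        path = np.cumsum(step_block, axis=0)
        for k in ks:
            msds[k] = np.mean(path[k - 1] ** 2)
        slope = np.polyfit([k * dt for k in ks], [msds[k] for k in ks], 1)[0]
        assert slope == pytest.approx(2 * D, rel=0.05)


class TestBoundaries:
    def test_specular_reflection_at_exit_surface(self):
        cfg = _nifs_config()
        pos = np.array([[0.5e-6, 0.5e-6, -3e-9]])
        out = apply_boundaries(pos, cfg)
        assert out[0, 2] == pytest.approx(3e-9)

    def test_periodic_lateral_wrap(self):
        cfg = _nifs_config()
        pos = np.array([[1e-6 + 2e-9, -1e-9, 5e-9]])
        out = apply_boundaries(pos, cfg)
        assert out[0, 0] == pytest.approx(2e-9)
        assert out[0, 1] == pytest.approx(1e-6 - 1e-9)

    def test_conventional_mode_fully_periodic(self):
        cfg = _fcs_config()
        pos = np.array([[1e-9, 1e-9, -1e-9]])
        out = apply_boundaries(pos, cfg)
        assert out[0, 2] == pytest.approx(2e-6 - 1e-9)

    def test_displacement_beyond_box_rejected(self):
        cfg = _fcs_config()
        with pytest.raises(ValueError):
            apply_boundaries(np.array([[5e-6, 0.0, 0.0]]), cfg)

    def test_reflected_wall_density_stays_uniform(self):
        """Long-run z marginal above the reflecting wall is uniform (chi^2)."""
        cfg = _nifs_config(n_particles=2000, D=1e-11)
        rng = np.random.default_rng(17)
        pos = init_positions(cfg, rng)
        for _ in range(3000):
            pos = apply_boundaries(step_particles(pos, cfg.D, cfg.dt, rng), cfg)
        assert np.all(pos[:, 2] >= 0)
        hist, _ = np.histogram(pos[:, 2], bins=20, range=(0, cfg.box[2]))
        chi2 = np.sum((hist - 100) ** 2 / 100)
        assert stats.chi2.sf(chi2, df=19) > 0.01


class TestEmission:
    def test_zero_brightness_never_emits(self, rng, nifs_profile):
        pos = rng.random((100, 3)) * 1e-7
        assert emit_photons(pos, nifs_profile, 0.0, rng) == 0

    def test_below_exit_plane_never_emits(self, rng, nifs_profile):
        pos = np.array([[0.0, 0.0, -5e-9]] * 1000)
        total = sum(emit_photons(pos, nifs_profile, 0.1, rng) for _ in range(50))
        assert total == 0

    def test_stationary_particle_at_peak_bernoulli_mean(self, nifs_profile):
        """A particle parked at the profile peak emits at brightness per step."""
        rng = np.random.default_rng(23)
        pos = np.zeros((1, 3))
        n, b = 100_000, 0.01
        total = sum(emit_photons(pos, nifs_profile, b, rng) for _ in range(n))
        sigma = np.sqrt(n * b * (1 - b))
        assert abs(total - n * b) < 3 * sigma

    def test_counts_binomial_at_fixed_positions(self, nifs_profile):
        """Per-step counts at frozen positions follow the exact Bernoulli-sum
        (Poisson-binomial) law: chi-square at alpha = 0.01."""
        rng = np.random.default_rng(29)
        pos = np.column_stack([
            rng.uniform(-50e-9, 50e-9, 200),
            rng.uniform(-50e-9, 50e-9, 200),
            rng.uniform(0, 30e-9, 200),
        ])
        b = 0.1
        p = b * nifs_profile.evaluate(pos)
        n_draws = 4000
        draws = np.array([emit_photons(pos, nifs_profile, b, rng)
                          for _ in range(n_draws)])
        pmf = np.array([1.0])
        for pi in p:  # exact distribution by sequential convolution
            new = np.concatenate([pmf * (1 - pi), [0.0]])
            new[1:] += pmf * pi
            pmf = new
        exp = pmf * n_draws
        # merge the sparse tail so every bin has expectation >= 5
        kmax = np.max(np.nonzero(exp >= 5)[0])
        obs = np.bincount(draws, minlength=len(exp)).astype(float)
        obs_b = np.concatenate([obs[:kmax], [obs[kmax:].sum()]])
        exp_b = np.concatenate([exp[:kmax], [exp[kmax:].sum()]])
        chi2 = np.sum((obs_b - exp_b) ** 2 / exp_b)
        assert stats.chi2.sf(chi2, df=len(exp_b) - 1) > 0.01

    def test_probability_above_one_rejected(self, rng, nifs_profile):
        with pytest.raises(ValueError):
            emit_photons(np.zeros((1, 3)), nifs_profile, 1.5, rng)


class TestRunSimulation:
    def test_deterministic_for_fixed_seed(self):
        cfg = _nifs_config(n_steps=5000, n_runs=2)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.counts, tb.counts)

    def test_runs_use_distinct_seeds(self):
        cfg = _fcs_config(n_steps=5000, n_runs=3, n_particles=200, brightness=0.05)
        traces = run_simulation(cfg)
        assert len(traces) == 3
        assert traces[0].seed == cfg.seed and traces[1].seed == cfg.seed + 1
        assert not np.array_equal(traces[0].counts, traces[1].counts)

    @pytest.mark.parametrize("mode", ["FCS3D", "NIFS3D", "2D"])
    def test_numba_and_numpy_engines_agree_exactly(self, mode):
        """Both engines replay the same random stream and must emit
        identical photon counts."""
        if mode == "2D":
            cfg = _fcs_config(mode="2D", profile=AnnularProfile(a0=20e-9, b0=8e-9),
                              n_steps=2000, n_particles=50, brightness=0.1)
        elif mode == "NIFS3D":
            cfg = _nifs_config(n_steps=2000, n_particles=50, brightness=0.1)
        else:
            cfg = _fcs_config(n_steps=2000, n_particles=50, brightness=0.1)
        a = run_single(cfg, cfg.seed, engine="numba")
        b = run_single(cfg, cfg.seed, engine="numpy")
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_trace_length_and_dtype(self):
        cfg = _fcs_config(n_steps=1234)
        tr = run_single(cfg, 0)
        assert len(tr.counts) == 1234
        assert np.issubdtype(tr.counts.dtype, np.integer)

    def test_grid_profile_runs_on_numpy_engine(self):
        from nifs import GridProfile
        src = GaussianEllipsoidProfile(r0=0.5e-6, z0=1.5e-6)
        axes = (np.linspace(-2e-6, 2e-6, 41),) * 3
        cfg = _fcs_config(profile=GridProfile.from_profile(src, axes),
                          n_steps=500, n_particles=50, brightness=0.1)
        tr = run_single(cfg, 1, engine="numpy")
        assert len(tr.counts) == 500


class TestCalibration:
    def test_zero_target_gives_zero(self):
        assert calibrate_brightness(_fcs_config(), 0.0) == 0.0

    def test_target_rate_achieved_within_ten_percent(self):
        cfg = _fcs_config(box=(3e-6, 3e-6, 3e-6), n_particles=800,
                          n_steps=100_000, D=3e-10,
                          profile=GaussianEllipsoidProfile(r0=0.5e-6, z0=1.5e-6))
        b = calibrate_brightness(cfg, 2e5)
        tr = run_single(replace(cfg, brightness=b), seed=99)
        assert tr.mean_rate == pytest.approx(2e5, rel=0.1)

    def test_linear_in_target(self):
        cfg = _fcs_config()
        b1 = calibrate_brightness(cfg, 1e4)
        b2 = calibrate_brightness(cfg, 2e4)
        assert b2 == pytest.approx(2 * b1, rel=1e-9)

    def test_unreachable_rate_raises_or_clips(self):
        cfg = _nifs_config(n_particles=20)
        with pytest.raises(ValueError):
            calibrate_brightness(cfg, 1e7)
        assert calibrate_brightness(cfg, 1e7, cap="clip") == 0.1
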