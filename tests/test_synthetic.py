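"""Generator contracts: known moments, exact round-trips, reproducibility."""

import numpy as np
import pytest

from forcespec import (
    AdhesionModelParams,
    CurveSynthesisParams,
    ParameterError,
    TopographyModelParams,
    draw_rupture_forces,
    extract_adhesion,
    fit_gaussian_peak,
    loop_half_width,
    surface_stats,
    synthesize_force_curve,
    synthesize_friction_loop,
    synthesize_height_map,
)


def compound_poisson_moments(f_i, f_0, lam, noise_sd):
    """Closed-form mean/variance and the SE of their sample estimates."""
    mean = f_0 + lam * f_i
    var = lam * f_i**2 + noise_sd**2
    # fourth central moment of f_0 + f_i*N + eps, N ~ Poisson, eps ~ Normal
    mu4 = f_i**4 * (lam + 3 * lam**2) + 6 * f_i**2 * lam * noise_sd**2 + 3 * noise_sd**4
    return mean, var, mu4


class TestDrawRuptureForces:
    def test_zero_bonds_leaves_only_offset(self):
        draw = draw_rupture_forces(
            AdhesionModelParams(f_i=30, f_0=90, lambda_mean=0, noise_sd=0, n_curves=5, seed=0)
        )
        assert np.all(draw.forces == 90.0)
        assert draw.n_clipped == 0

    def test_sample_moments_match_closed_form(self):
        n = 100_000
        draw = draw_rupture_forces(
            AdhesionModelParams(f_i=30, f_0=90, lambda_mean=1, noise_sd=0, n_curves=n, seed=7)
        )
        mean, var, mu4 = compound_poisson_moments(30, 90, 1, 0)
        assert mean == 120 and var == 900
        se_mean = np.sqrt(var / n)
        se_var = np.sqrt((mu4 - var**2 * (n - 3) / (n - 1)) / n)
        assert abs(draw.forces.mean() - 120) < 3 * se_mean
        assert abs(draw.forces.var(ddof=1) - 900) < 3 * se_var

    @pytest.mark.parametrize("seed", range(20))
    def test_moment_match_across_seeds(self, seed):
        """Mean -> f_0 + lam*f_i and var -> lam*f_i^2 + noise^2, within 4 SE."""
        f_i, f_0, lam, noise = 33.4, 90.0, 4.0, 15.0
        n = 10_000
        draw = draw_rupture_forces(
            AdhesionModelParams(f_i=f_i, f_0=f_0, lambda_mean=lam, noise_sd=noise,
                                n_curves=n, seed=seed)
        )
        mean, var, mu4 = compound_poisson_moments(f_i, f_0, lam, noise)
        se_mean = np.sqrt(var / n)
        se_var = np.sqrt((mu4 - var**2 * (n - 3) / (n - 1)) / n)
        assert abs(draw.forces.mean() - mean) < 4 * se_mean
        assert abs(draw.forces.var(ddof=1) - var) < 4 * se_var

    def test_gaussian_peak_at_target_operating_point(self):
        """Peak of an ensemble tuned to a 347 pN mean lands on the target."""
        f_i, f_0, noise = 33.4, 90.0, 25.0
        lam = (347.0 - f_0) / f_i
        draw = draw_rupture_forces(
            AdhesionModelParams(f_i=f_i, f_0=f_0, lambda_mean=lam, noise_sd=noise,
                                n_curves=300, seed=11)
        )
        fit = fit_gaussian_peak(draw.forces)
        assert fit.converged
        se = max(fit.peak_se, np.sqrt(draw.forces.var(ddof=1) / draw.forces.size))
        assert abs(fit.peak - 347.0) < 2 * se

    def test_negative_draws_clipped_and_flagged(self):
        draw = draw_rupture_forces(
            AdhesionModelParams(f_i=1, f_0=0, lambda_mean=0.1, noise_sd=50,
                                n_curves=2000, seed=3)
        )
        assert draw.n_clipped > 0
        assert np.all(draw.forces >= 0)
        assert np.all(draw.forces[draw.clipped] == 0)

    def test_identical_seeds_bit_identical(self):
        p = AdhesionModelParams(f_i=30, f_0=90, lambda_mean=2, noise_sd=10, n_curves=100, seed=9)
        assert np.array_equal(draw_rupture_forces(p).forces, draw_rupture_forces(p).forces)

    @pytest.mark.parametrize(
        "kwargs,name",
        [
            (dict(f_i=-1), "f_i"),
            (dict(f_0=-5), "f_0"),
            (dict(noise_sd=-1), "noise_sd"),
            (dict(n_curves=0), "n_curves"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, name):
        base = dict(f_i=30, f_0=90, lambda_mean=1, noise_sd=0, n_curves=10, seed=0)
        base.update(kwargs)
        with pytest.raises(ParameterError, match=name):
            AdhesionModelParams(**base)


class TestSynthesizeForceCurve:
    def test_zero_rupture_gives_no_event(self, curve_params):
        curve = synthesize_force_curve(0.0, curve_params)
        assert not extract_adhesion(curve).has_event

    def test_round_trip_exact_at_zero_noise(self, curve_params):
        curve = synthesize_force_curve(350.0, curve_params)
        event = extract_adhesion(curve)
        assert event.has_event
        assert event.adhesion_force_pn == pytest.approx(350.0, abs=1e-9)

    def test_round_trip_under_baseline_drift(self):
        params = CurveSynthesisParams(baseline_drift_slope=0.004)
        curve = synthesize_force_curve(350.0, params)
        event = extract_adhesion(curve)
        step_force = params.spring_constant * 1000 * params.sample_spacing
        assert abs(event.adhesion_force_pn - 350.0) <= step_force

    def test_round_trip_100_random_ruptures(self, curve_params, rng):
        for rupture in rng.uniform(20, 900, size=100):
            event = extract_adhesion(synthesize_force_curve(float(rupture), curve_params))
            assert event.adhesion_force_pn == pytest.approx(rupture, abs=1e-8)

    def test_approach_has_contact_ramp_and_flat_baseline(self, curve_params):
        curve = synthesize_force_curve(200.0, curve_params)
        contact = curve.signal_approach[curve.z_approach < 0]
        free = curve.signal_approach[curve.z_approach > 0]
        assert np.all(contact > 0) and np.ptp(contact) > 0
        assert np.allclose(free, 0.0)

    def test_identical_seeds_bit_identical(self):
        params = CurveSynthesisParams(noise_sd_signal=0.01)
        a = synthesize_force_curve(300.0, params, seed=5)
        b = synthesize_force_curve(300.0, params, seed=5)
        assert np.array_equal(a.signal_retract, b.signal_retract)
        assert np.array_equal(a.signal_approach, b.signal_approach)


class TestSynthesizeFrictionLoop:
    def test_zero_vf_trace_equals_retrace(self):
        loop = synthesize_friction_loop(0.0, offset=0.3, noise_sd=0.0, n_points=64)
        assert np.array_equal(loop.v_trace, loop.v_retrace)
        assert loop_half_width(loop) == 0.0

    def test_half_width_exact_without_noise(self):
        loop = synthesize_friction_loop(0.4, offset=0.0, noise_sd=0.0, n_points=64)
        assert loop_half_width(loop) == pytest.approx(0.4, abs=1e-15)

    def test_half_width_within_3se_under_noise(self):
        true_vf, noise, n = 0.4, 0.05, 512
        loop = synthesize_friction_loop(true_vf, offset=1.0, noise_sd=noise, n_points=n, seed=21)
        # half-width averages (trace-retrace)/2 over ~0.8n points
        se = noise * np.sqrt(2) / 2 / np.sqrt(0.8 * n)
        assert abs(loop_half_width(loop) - true_vf) < 3 * se


class TestSynthesizeHeightMap:
    def test_no_bumps_flat_at_baseline(self):
        params = TopographyModelParams(grid_size=32, bump_count=0, baseline_height=6.9, seed=0)
        hm = synthesize_height_map(params)
        stats = surface_stats(hm, leveling_order=0)
        assert stats.avg_height == pytest.approx(6.9)
        assert stats.sa == pytest.approx(0.0, abs=1e-12) and stats.sq == pytest.approx(0.0, abs=1e-12)

    def test_compaction_scales_height_above_baseline_exactly(self):
        base = dict(grid_size=48, bump_count=120, baseline_height=6.9, seed=42)
        full = synthesize_height_map(TopographyModelParams(**base, compaction_factor=1.0))
        half = synthesize_height_map(TopographyModelParams(**base, compaction_factor=0.5))
        above_full = full.grid.mean() - 6.9
        above_half = half.grid.mean() - 6.9
        assert above_half == pytest.approx(above_full / 2, rel=1e-12)

    def test_default_layer_matches_roughness_target(self):
        """Default protein-layer parameters give Sq within 15% of 2.6 nm."""
        hm = synthesize_height_map(TopographyModelParams(seed=1))
        stats = surface_stats(hm)
        assert abs(stats.sq - 2.6) / 2.6 < 0.15

    def test_identical_seeds_bit_identical(self):
        params = TopographyModelParams(grid_size=32, bump_count=50, seed=8)
        assert np.array_equal(
            synthesize_height_map(params).grid, synthesize_height_map(params).grid
        )
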