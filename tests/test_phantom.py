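import numpy as np
import pytest

from spiralpvm.acquisition import AcquisitionParams
from spiralpvm.curves import DIRECTIONS
from spiralpvm.phantom import (
    RespiratoryTrace,
    build_motion_model,
    encode_phases,
    generate_respiratory_trace,
    generate_stationary_series,
    render_velocity_frames,
    simulate_navigator_gating,
)


class TestMotionModel:
    def test_basal_defaults_prescribe_cohort_means(self):
        model = build_motion_model("basal", seed=1)
        peaks = model.prescribed_peaks("longitudinal")
        assert peaks["S"].amplitude == pytest.approx(6.94)
        assert peaks["D"].amplitude == pytest.approx(-9.45)
        assert peaks["AS"].amplitude == pytest.approx(-2.62)

    def test_zero_overrides_give_zero_profiles(self):
        overrides = {
            d: {name: 0.0 for name in ("S", "D", "AS", "C1", "C2", "C3", "ES", "IR")}
            for d in DIRECTIONS
        }
        model = build_motion_model("mid", amplitude_overrides=overrides, seed=3)
        t = np.linspace(0, 1000, 500)
        for d in DIRECTIONS:
            assert np.all(model.velocity(d, t) == 0.0)

    def test_apical_c3_opposes_basal_c3(self):
        basal = build_motion_model("basal", seed=2)
        apical = build_motion_model("apical", seed=2)
        c3_base = basal.prescribed_peaks("circumferential")["C3"].amplitude
        c3_apex = apical.prescribed_peaks("circumferential")["C3"].amplitude
        assert c3_base < 0 < c3_apex  # untwisting: opposite rotation senses

    def test_mid_level_has_no_global_c3(self):
        model = build_motion_model("mid", seed=1)
        assert "C3" not in model.prescribed_peaks("circumferential")

    @pytest.mark.parametrize("level", ["basal", "mid", "apical"])
    def test_cycle_mean_near_zero(self, level):
        model = build_motion_model(level, seed=4)
        t = np.arange(0.0, model.rr_interval, 0.5)
        for d in DIRECTIONS:
            assert abs(model.velocity(d, t).mean()) <= 0.3

    def test_override_beyond_venc_rejected(self):
        with pytest.raises(ValueError, match="wrap"):
            build_motion_model(
                "mid", amplitude_overrides={"radial": {"D": -25.0}}, seed=1
            )
        with pytest.raises(ValueError, match="wrap"):
            build_motion_model(
                "mid", amplitude_overrides={"longitudinal": {"D": -31.0}}, seed=1
            )

    def test_jitter_is_seed_deterministic(self):
        a = build_motion_model("mid", seed=9, amplitude_jitter=0.1)
        b = build_motion_model("mid", seed=9, amplitude_jitter=0.1)
        for d in DIRECTIONS:
            for x, y in zip(a.peaks[d], b.peaks[d]):
                assert x == y


class TestRender:
    def test_zero_model_renders_zero_fields(self, params):
        overrides = {
            d: {n: 0.0 for n in ("S", "D", "AS", "C1", "C2", "C3", "ES", "IR")}
            for d in DIRECTIONS
        }
        model = build_motion_model("mid", amplitude_overrides=overrides, seed=1)
        out = render_velocity_frames(model, params, grid_size=64, n_frames=4)
        assert np.all(out.truth.velocities == 0.0)

    def test_pure_radial_velocity_points_at_centre(self, params):
        overrides = {
            "longitudinal": {"S": 0.0, "D": 0.0, "AS": 0.0},
            "circumferential": {"C1": 0.0, "C2": 0.0},
            "radial": {"ES": 0.0, "IR": 0.0, "D": 0.0, "AS": 0.0},
        }
        model = build_motion_model(
            "mid", amplitude_overrides=overrides, seed=1, modulation_amp=0.0
        )
        out = render_velocity_frames(model, params, grid_size=64, n_frames=6)
        geom = out.geometry
        f = 5  # t = 105 ms, near the systolic radial peak
        t = out.truth.frame_times[f]
        g = model.velocity("radial", t)
        m = geom.mask[f]
        vx = out.truth.velocities[f, :, :, 0]
        vy = out.truth.velocities[f, :, :, 1]
        rx, ry, _, _ = geom.unit_vectors(f)
        expected = -g * model.transmural("radial", geom.depth[f])
        # brute-force per-pixel check: in-plane velocity is radial with the
        # transmural scaling, and the tangential component vanishes
        assert np.allclose((vx * rx + vy * ry)[m], expected[m], atol=1e-12)
        assert np.allclose((vx * ry - vy * rx)[m], 0.0, atol=1e-12)
        assert np.all(out.truth.velocities[f, :, :, 2][m] == 0.0)

    def test_global_longitudinal_cycle_average_near_zero(self, small_render):
        truth = small_render.truth
        mask = small_render.geometry.mask
        per_frame = np.array(
            [truth.velocities[f, :, :, 2][mask[f]].mean() for f in range(truth.n_frames)]
        )
        assert abs(per_frame.mean()) <= 0.3

    def test_inverted_radii_rejected(self, small_model, params):
        with pytest.raises(ValueError):
            render_velocity_frames(
                small_model, params, grid_size=64, r_endo_mm=30.0, r_epi_mm=20.0
            )

    def test_wall_spans_at_least_seven_pixels(self, small_render):
        # 10 mm wall at 1.4 mm pixels, as in the discussion of resolution
        geom = small_render.geometry
        r_endo = np.hypot(*(geom.endo[0] - geom.center[0]).T).mean()
        r_epi = np.hypot(*(geom.epi[0] - geom.center[0]).T).mean()
        assert (r_epi - r_endo) / geom.pixel_spacing >= 7.0


class TestEncode:
    def test_zero_velocity_zero_background_zero_noise(self, params):
        from spiralpvm.series import VelocityFieldSeries

        truth = VelocityFieldSeries(
            np.zeros((3, 16, 16, 3)), np.array([0.0, 21.0, 42.0]), 1000.0
        )
        enc = encode_phases(truth, params)
        for name in ("reference", "x", "y", "z"):
            assert np.all(enc.phases[name] == 0.0)

    def test_half_venc_gives_half_pi_phase(self, params):
        from spiralpvm.series import VelocityFieldSeries

        v = np.zeros((2, 8, 8, 3))
        v[0, 4, 4, 2] = 15.0  # vz = venc_tp / 2
        truth = VelocityFieldSeries(v, np.array([0.0, 21.0]), 1000.0)
        enc = encode_phases(truth, params)
        assert enc.phases["z"][0, 4, 4] == pytest.approx(np.pi / 2)
        assert enc.phases["reference"][0, 4, 4] == 0.0

    def test_phase_difference_equals_pi_v_over_venc(self, small_render, params):
        rng = np.random.default_rng(0)
        bg = rng.normal(0.0, 0.2, size=(4, 6))
        enc = encode_phases(small_render.truth, params, background_coeffs=bg)
        from spiralpvm._utils import wrap_phase

        for comp in ("x", "y", "z"):
            got = wrap_phase(enc.phases[comp] - enc.phases["reference"])
            bg_diff = np.broadcast_to(
                _poly(bg[("x", "y", "z").index(comp) + 1], 64)
                - _poly(bg[0], 64),
                got.shape,
            )
            expect = wrap_phase(
                np.pi * small_render.truth.component(comp) / params.venc(comp)
                + bg_diff
            )
            assert np.allclose(got, expect, atol=1e-12)

    def test_velocity_at_venc_raises_naming_component(self, params):
        from spiralpvm.series import VelocityFieldSeries

        v = np.zeros((2, 8, 8, 3))
        v[0, 1, 1, 1] = 20.0
        truth = VelocityFieldSeries(v, np.array([0.0, 21.0]), 1000.0)
        with pytest.raises(ValueError, match="component y"):
            encode_phases(truth, params)

    def test_seeded_noise_is_deterministic(self, small_render, params):
        a = encode_phases(small_render.truth, params, noise_sd=0.05, seed=17)
        b = encode_phases(small_render.truth, params, noise_sd=0.05, seed=17)
        for name in a.phases:
            assert np.array_equal(a.phases[name], b.phases[name])


def _poly(coeffs, n):
    from spiralpvm.phantom import polynomial_background

    return polynomial_background(coeffs, n)


class TestStationary:
    def test_zero_background_zero_noise_all_zero(self, params):
        enc = generate_stationary_series(params, grid_size=16)
        for name in enc.phases:
            assert np.all(enc.phases[name] == 0.0)

    def test_same_background_cancels_in_subject_minus_stationary(
        self, small_render, params
    ):
        bg = np.random.default_rng(3).normal(0.0, 0.15, size=(4, 6))
        subject = encode_phases(small_render.truth, params, background_coeffs=bg)
        stationary = generate_stationary_series(
            params,
            grid_size=64,
            frame_times=small_render.truth.frame_times,
            rr_interval=small_render.truth.rr_interval,
            background_coeffs=bg,
        )
        from spiralpvm._utils import wrap_phase

        for comp in ("x", "y", "z"):
            diff_subject = wrap_phase(subject.phases[comp] - subject.phases["reference"])
            diff_phantom = wrap_phase(
                stationary.phases[comp] - stationary.phases["reference"]
            )
            got = wrap_phase(diff_subject - diff_phantom)
            expect = np.pi * small_render.truth.component(comp) / params.venc(comp)
            assert np.allclose(got, expect, atol=1e-9)

    def test_seeded_calls_bit_identical(self, params):
        a = generate_stationary_series(params, grid_size=16, noise_sd=0.05, seed=4)
        b = generate_stationary_series(params, grid_size=16, noise_sd=0.05, seed=4)
        for name in a.phases:
            assert np.array_equal(a.phases[name], b.phases[name])


class TestNavigator:
    def test_perfect_breath_hold_accepts_all_interior_cycles(self):
        mask, eff = simulate_navigator_gating(np.zeros(20), window=5.0)
        assert eff == pytest.approx(19 / 20)
        assert not mask[-1]  # final cycle has no following navigator

    def test_displaced_diaphragm_rejects_everything(self):
        _, eff = simulate_navigator_gating(np.full(15, 10.0), window=5.0)
        assert eff == 0.0

    def test_sinusoidal_trace_matches_exhaustive_enumeration(self):
        i = np.arange(100)
        pos = 8.0 * np.sin(2 * np.pi * i / 5.0)
        mask, eff = simulate_navigator_gating(pos, window=5.0)
        brute = np.zeros(100, dtype=bool)
        for k in range(99):
            brute[k] = abs(pos[k]) <= 2.5 and abs(pos[k + 1]) <= 2.5
        assert np.array_equal(mask, brute)
        single = np.mean(np.abs(pos) <= 2.5)
        assert eff <= single

    def test_dual_never_beats_single_navigator(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            trace = generate_respiratory_trace(
                60,
                amplitude=rng.uniform(0, 10),
                period_cycles=rng.uniform(3, 30),
                noise_sd=rng.uniform(0, 3),
                seed=int(rng.integers(0, 2**31)),
            )
            _, eff = simulate_navigator_gating(trace, window=5.0)
            single = np.mean(np.abs(trace.positions) <= 2.5)
            assert eff <= single + 1e-12

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            simulate_navigator_gating(np.array([1.0]), window=5.0)

    def test_trace_generator_deterministic(self):
        a = generate_respiratory_trace(50, seed=8)
        b = generate_respiratory_trace(50, seed=8)
        assert isinstance(a, RespiratoryTrace)
        assert np.array_equal(a.positions, b.positions)
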