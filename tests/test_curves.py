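import numpy as np
import pytest

from spiralpvm._utils import round_half_away
from spiralpvm.curves import (
    CardiacPhaseMarkers,
    NormalizationConstants,
    VelocityTimeCurve,
    detect_end_systole,
    detect_peaks,
    detect_phase_markers,
    e_over_a,
    summarize_peaks,
    ttp_fixed_difference,
    ttp_fixed_length,
    ttp_percent,
)

RR = 1000.0
GRID = np.arange(60) * RR / 60.0


def bump(t, t0, amp, sigma):
    return amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def radial_like(t, es=350.0, es_depth=-0.8, d=(-4.0, 460.0), a=(-1.6, 870.0)):
    """Radial-style curve: systolic wave, end-systolic notch, rebound, E, A."""
    v = (
        bump(t, 110.0, 2.4, 70.0)
        + bump(t, es, es_depth, 20.0)
        + bump(t, es + 45.0, 0.5, 18.0)
        + bump(t, d[1], d[0], 40.0)
        + bump(t, a[1], a[0], 40.0)
    )
    return VelocityTimeCurve(t, v, "radial", rr_interval=RR)


class TestEndSystole:
    def test_prescribed_notch_recovered_within_one_phase(self):
        curve = radial_like(GRID)
        t_es = detect_end_systole(curve, smooth_window=1)
        assert abs(t_es - 350.0) <= RR / 60.0

    def test_pure_sine_returns_three_quarter_cycle(self):
        v = np.sin(2 * np.pi * GRID / RR)
        curve = VelocityTimeCurve(GRID, v, "radial", rr_interval=RR)
        t_es = detect_end_systole(curve, smooth_window=1)
        assert t_es == pytest.approx(0.75 * RR, abs=RR / 60.0)

    def test_always_positive_curve_not_analyzable(self):
        v = 1.0 + 0.5 * np.sin(2 * np.pi * GRID / RR)
        curve = VelocityTimeCurve(GRID, v, "radial", rr_interval=RR)
        with pytest.raises(ValueError, match="not analyzable"):
            detect_end_systole(curve, smooth_window=1)


class TestPhaseMarkers:
    def _flat_diastasis_curve(self):
        # systolic wave, notch at 350, E-wave, exactly flat zero 500-800,
        # atrial bump at 870
        t = GRID
        v = bump(t, 110, 2.4, 60) + bump(t, 350, -0.8, 18) + bump(t, 430, -4.0, 25)
        v[(t >= 500) & (t <= 800)] = 0.0
        v = v + np.where(t > 800, bump(t, 870, -1.8, 25), 0.0)
        return VelocityTimeCurve(t, v, "radial", rr_interval=RR)

    def test_flat_diastasis_onsets(self):
        curve = self._flat_diastasis_curve()
        markers = detect_phase_markers(curve, 350.0, smooth_window=1)
        assert 470.0 <= markers.t_diastasis_onset <= 535.0
        assert 780.0 <= markers.t_atrial_onset <= 835.0

    def test_markers_strictly_ordered(self):
        markers = detect_phase_markers(radial_like(GRID), 350.0, smooth_window=1)
        assert (
            0
            < markers.t_end_systole
            < markers.t_diastasis_onset
            < markers.t_atrial_onset
            < markers.rr_interval
        )

    def test_uniform_time_scaling_scales_markers(self):
        curve = radial_like(GRID)
        m1 = detect_phase_markers(curve, 350.0, smooth_window=1)
        gamma = 1.3
        scaled = VelocityTimeCurve(
            GRID * gamma, curve.values, "radial", rr_interval=RR * gamma
        )
        m2 = detect_phase_markers(scaled, 350.0 * gamma, smooth_window=1)
        assert m2.t_diastasis_onset == pytest.approx(gamma * m1.t_diastasis_onset)
        assert m2.t_atrial_onset == pytest.approx(gamma * m1.t_atrial_onset)

    def test_invalid_marker_ordering_rejected(self):
        with pytest.raises(ValueError):
            CardiacPhaseMarkers(400.0, 380.0, 800.0, 1000.0)


class TestPeakDetection:
    def test_three_bump_longitudinal_curve(self):
        t = GRID
        v = bump(t, 60, 5.0, 42) + bump(t, 460, -7.0, 42) + bump(t, 870, -2.0, 42)
        curve = VelocityTimeCurve(t, v, "longitudinal", rr_interval=RR)
        markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
        ps = detect_peaks(curve, "longitudinal", "mid", markers, smooth_window=1)
        assert ps.get("S").amplitude == pytest.approx(5.0, rel=0.05)
        assert abs(ps.get("S").ttp_ms - 60) <= RR / 60
        assert ps.get("D").amplitude == pytest.approx(-7.0, rel=0.05)
        assert abs(ps.get("D").ttp_ms - 460) <= RR / 60
        assert ps.get("AS").amplitude == pytest.approx(-2.0, rel=0.05)
        assert abs(ps.get("AS").ttp_ms - 870) <= RR / 60

    def test_all_zero_curve_has_no_peaks(self):
        curve = VelocityTimeCurve(GRID, np.zeros_like(GRID), "longitudinal",
                                  rr_interval=RR)
        markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
        ps = detect_peaks(curve, "longitudinal", "mid", markers, smooth_window=1)
        assert not ps.peaks

    def test_suppressed_atrial_peak_reported_absent(self):
        t = GRID
        rng = np.random.default_rng(0)
        v = bump(t, 55, 4.8, 42) + bump(t, 455, -4.3, 42) + rng.normal(0, 0.02, t.shape)
        curve = VelocityTimeCurve(t, v, "longitudinal", rr_interval=RR)
        markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
        ps = detect_peaks(curve, "longitudinal", "apical", markers, smooth_window=1)
        assert "S" in ps and "D" in ps
        assert "AS" not in ps

    def test_circumferential_triplet(self):
        def circ(t):
            return bump(t, 45, -3.0, 40) + bump(t, 135, 2.3, 50) + bump(t, 390, -1.6, 40)

        curve = VelocityTimeCurve(GRID, circ(GRID), "circumferential", rr_interval=RR)
        markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
        ps = detect_peaks(curve, "circumferential", "basal", markers, smooth_window=1)
        # overlapping bump tails shift the true extrema: the oracle is the
        # densely sampled curve, not the raw bump amplitudes
        dense = np.arange(0.0, RR, 0.25)
        vd = circ(dense)
        c1_true = vd[dense < 100].min()
        c2_true = vd[(dense > 100) & (dense < 250)].max()
        c3_true = vd[(dense > 340) & (dense < 480)].min()
        assert ps.get("C1").amplitude == pytest.approx(c1_true, rel=0.05)
        assert ps.get("C2").amplitude == pytest.approx(c2_true, rel=0.05)
        assert ps.get("C3").amplitude == pytest.approx(c3_true, rel=0.05)
        assert ps.get("C1").ttp_ms < ps.get("C2").ttp_ms

    def test_c3_signs_oppose_between_base_and_apex(self):
        from spiralpvm.phantom import build_motion_model

        markers = CardiacPhaseMarkers(349.0, 540.0, 780.0, RR)
        amps = {}
        for level in ("basal", "apical"):
            model = build_motion_model(level, seed=6)
            v = model.velocity("circumferential", GRID)
            curve = VelocityTimeCurve(GRID, v, "circumferential", rr_interval=RR)
            ps = detect_peaks(curve, "circumferential", level, markers,
                              smooth_window=1)
            amps[level] = ps.get("C3").amplitude
        assert amps["basal"] < 0 < amps["apical"]

    def test_recovery_on_random_synthetic_curves(self):
        # amplitude within 5%, timing within one phase spacing, on curves
        # with physiologic bump placement and widths
        rng = np.random.default_rng(12)
        markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
        for _ in range(100):
            s_amp = rng.uniform(3.0, 8.0)
            d_amp = -rng.uniform(3.0, 9.0)
            a_amp = -rng.uniform(1.0, 3.0)
            s_t = rng.uniform(50, 120)
            d_t = rng.uniform(420, 520)
            a_t = rng.uniform(830, 910)
            t = GRID
            v = (
                bump(t, s_t, s_amp, rng.uniform(42, 60))
                + bump(t, d_t, d_amp, rng.uniform(42, 60))
                + bump(t, a_t, a_amp, rng.uniform(42, 60))
            )
            curve = VelocityTimeCurve(t, v, "longitudinal", rr_interval=RR)
            ps = detect_peaks(curve, "longitudinal", "mid", markers, smooth_window=1)
            for name, amp, t0 in (("S", s_amp, s_t), ("D", d_amp, d_t),
                                  ("AS", a_amp, a_t)):
                pk = ps.get(name)
                assert pk is not None
                assert abs(pk.amplitude - amp) <= 0.05 * abs(amp)
                assert abs(pk.ttp_ms - t0) <= RR / 60.0


class TestTTPNormalization:
    MARKERS = CardiacPhaseMarkers(350.0, 550.0, 800.0, 1000.0)

    def test_systolic_boundary_is_hundred_percent(self):
        assert ttp_percent(350.0, "systolic", self.MARKERS) == pytest.approx(100.0)

    def test_diastolic_boundary_is_hundred_percent(self):
        assert ttp_percent(1000.0, "diastolic", self.MARKERS) == pytest.approx(100.0)

    def test_early_diastolic_example(self):
        assert ttp_percent(467.0, "diastolic", self.MARKERS) == pytest.approx(18.0)

    def test_out_of_cycle_rejected(self):
        with pytest.raises(ValueError):
            ttp_percent(1100.0, "diastolic", self.MARKERS)

    @pytest.mark.parametrize(
        "percent,klass,expected",
        [
            (17.3, "systolic", 60.6),  # basal S_L
            (18.0, "diastolic", 467.0),  # basal D_L
            (79.2, "diastolic", 864.8),  # basal AS_L
            (9.3, "diastolic", 410.5),  # basal C3
            (1.4, "diastolic", 359.1),  # apical C3
            (80.9, "diastolic", 875.9),  # mid AS_R
            (0.0, "systolic", 0.0),
        ],
    )
    def test_fixed_length_conversion_matches_printed_values(
        self, percent, klass, expected
    ):
        assert round_half_away(ttp_fixed_length(percent, klass), 1) == expected

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError):
            ttp_fixed_length(101.0, "systolic")

    def test_affine_difference_rule(self):
        # slope is 3.5 ms/% systolic, 6.5 ms/% diastolic, exactly
        assert round_half_away(ttp_fixed_difference(-3.93, "systolic"), 1) == -13.8
        assert round_half_away(ttp_fixed_difference(8.1, "diastolic"), 1) == 52.7
        a = ttp_fixed_length(40.0, "systolic")
        b = ttp_fixed_length(30.0, "systolic")
        assert a - b == pytest.approx(10.0 * 3.5)
        a = ttp_fixed_length(70.0, "diastolic")
        b = ttp_fixed_length(50.0, "diastolic")
        assert a - b == pytest.approx(20.0 * 6.5)

    @pytest.mark.parametrize("gamma", [0.5, 0.77, 1.0, 1.31, 2.0])
    def test_percent_invariant_under_uniform_time_scaling(self, gamma):
        m = CardiacPhaseMarkers(
            350.0 * gamma, 550.0 * gamma, 800.0 * gamma, 1000.0 * gamma
        )
        assert ttp_percent(460.0 * gamma, "diastolic", m) == pytest.approx(
            ttp_percent(460.0, "diastolic", self.MARKERS), abs=1e-9
        )
        assert ttp_percent(120.0 * gamma, "systolic", m) == pytest.approx(
            ttp_percent(120.0, "systolic", self.MARKERS), abs=1e-9
        )


class TestEOverA:
    def test_simple_ratio(self):
        assert e_over_a(-3.0, -1.5) == pytest.approx(2.0)

    def test_equal_peaks_give_unity(self):
        assert e_over_a(-2.2, -2.2) == pytest.approx(1.0)

    def test_zero_atrial_peak_rejected(self):
        with pytest.raises(ValueError):
            e_over_a(-3.0, 0.0)

    def test_prescribed_ratio_recovered_from_curve(self):
        t = GRID
        v = bump(t, 110, 2.4, 50) + bump(t, 350, -0.8, 20) + \
            bump(t, 460, -4.0, 42) + bump(t, 870, -1.6, 42)
        curve = VelocityTimeCurve(t, v, "radial", rr_interval=RR)
        markers = CardiacPhaseMarkers(350.0, 560.0, 800.0, RR)
        ps = detect_peaks(curve, "radial", "mid", markers, smooth_window=1)
        assert e_over_a(ps.get("D").amplitude, ps.get("AS").amplitude) == \
            pytest.approx(2.5, rel=0.1)


def test_summary_table_layout():
    t = GRID
    v = bump(t, 60, 5.0, 42) + bump(t, 460, -7.0, 42) + bump(t, 870, -2.0, 42)
    curve = VelocityTimeCurve(t, v, "longitudinal", rr_interval=RR)
    markers = CardiacPhaseMarkers(350.0, 550.0, 800.0, RR)
    ps = detect_peaks(curve, "longitudinal", "mid", markers, smooth_window=1)
    df = summarize_peaks(ps, markers)
    assert set(df["peak"]) == {"S_L", "D_L", "AS_L"}
    assert {"amplitude_cm_s", "ttp_ms", "ttp_percent", "ttp_fixed_ms"} <= set(df.columns)
    assert df.attrs["e_over_a"] == pytest.approx(7.0 / 2.0, rel=0.05)


def test_normalization_constants_validated():
    with pytest.raises(ValueError):
        NormalizationConstants(avg_systole=-1.0)
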