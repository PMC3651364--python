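"""Synthetic moving-LV phantom for velocity-encoded short-axis series.

The phantom is a myocardial annulus whose velocity field follows the
velocity-time patterns of a healthy left ventricle: systolic (S),
early-diastolic (D) and atrial-systolic (AS) peaks in the longitudinal and
radial directions, a biphasic early-systolic pair (C1, C2) and an
early-diastolic peak (C3) circumferentially, an end-systolic radial notch
that marks the end of systole, cosine regional modulation around the
circumference and a linear endo-to-epi transmural gradient for radial
velocity. Default peak amplitudes and timings are the healthy-cohort means
for the requested slice level. Velocities are encoded into image phase with
the linear mapping phi = pi * v / venc, on top of a smooth second-order
polynomial background field per encoding, with additive Gaussian phase
noise; a stationary-phantom series with the same background model supports
background correction. A per-cycle diaphragm trace feeds the dual-navigator
respiratory acceptance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._utils import wrap_phase
from .acquisition import AcquisitionParams
from .curves import DIRECTIONS, VelocityPeak
from .geometry import LVGeometry, compute_geometry, pixel_coords
from .series import EncodedSeries, VelocityFieldSeries

SLICE_LEVELS = ("basal", "mid", "apical")

CANONICAL_RR = 1000.0  # ms; timing table below is expressed on this cycle
CANONICAL_END_SYSTOLE = 349.0  # ms

# (name, amplitude cm/s, time ms, width ms); width None is solved so the
# profile integrates to ~zero over the cycle (periodic motion). "ES" is the
# end-systolic radial notch that defines the length of systole; "IR" is the
# small positive isovolumic-relaxation rebound of the biphasic early-
# diastolic radial pattern. Neither is a named, recovered peak.
#
# Named peaks are Gaussian bumps wide enough that the acquired temporal
# resolution resolves their amplitude; the radial E-wave alone uses a
# flat-topped generalized Gaussian (exponent 4) whose compact flanks keep
# the end-systolic notch separable at every heart rate.
_B = None  # balancer width marker
PEAK_WIDTH = 42.0  # ms, width parameter of named peaks
D_RAD_WIDTH = 36.0  # ms, flat-topped radial E-wave width parameter
PEAK_SHAPE = 3.0  # mildly flat-topped: resolvable amplitude, localized TTP
D_RAD_SHAPE = 4.0

# entries: (name, amplitude cm/s, time ms, width ms | _B, exponent)
PEAK_TABLES = {
    "basal": {
        "longitudinal": (
            ("S", 6.94, 58.3, _B, 2.0),
            ("D", -9.45, 458.0, PEAK_WIDTH, PEAK_SHAPE),
            ("AS", -2.62, 881.1, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "radial": (
            ("S", 2.35, 117.5, _B, 2.0),
            ("ES", -0.75, CANONICAL_END_SYSTOLE, 20.0, 2.0),
            ("IR", 0.55, 395.0, 18.0, 2.0),
            ("D", -4.01, 446.5, D_RAD_WIDTH, D_RAD_SHAPE),
            ("AS", -1.41, 864.6, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "circumferential": (
            ("C1", -2.88, 42.3, PEAK_WIDTH, PEAK_SHAPE),
            ("C2", 2.33, 133.8, _B, 2.0),
            ("C3", -1.58, 391.2, PEAK_WIDTH, PEAK_SHAPE),
        ),
    },
    "mid": {
        "longitudinal": (
            ("S", 5.87, 55.6, _B, 2.0),
            ("D", -6.50, 461.2, PEAK_WIDTH, PEAK_SHAPE),
            ("AS", -1.66, 858.5, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "radial": (
            ("S", 2.38, 108.5, _B, 2.0),
            ("ES", -0.75, CANONICAL_END_SYSTOLE, 20.0, 2.0),
            ("IR", 0.55, 395.0, 18.0, 2.0),
            ("D", -3.61, 457.7, D_RAD_WIDTH, D_RAD_SHAPE),
            ("AS", -1.59, 865.7, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "circumferential": (
            ("C1", -3.52, 46.8, PEAK_WIDTH, PEAK_SHAPE),
            ("C2", 1.40, 135.0, _B, 2.0),
        ),
    },
    "apical": {
        "longitudinal": (
            ("S", 4.83, 50.7, _B, 2.0),
            ("D", -4.27, 454.3, PEAK_WIDTH, PEAK_SHAPE),
            ("AS", -0.81, 876.2, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "radial": (
            ("S", 2.14, 110.2, _B, 2.0),
            ("ES", -0.75, CANONICAL_END_SYSTOLE, 20.0, 2.0),
            ("IR", 0.55, 395.0, 18.0, 2.0),
            ("D", -3.99, 484.8, D_RAD_WIDTH, D_RAD_SHAPE),
            ("AS", -1.57, 884.1, PEAK_WIDTH, PEAK_SHAPE),
        ),
        "circumferential": (
            ("C1", -3.50, 49.4, PEAK_WIDTH, PEAK_SHAPE),
            ("C2", 0.39, 138.3, _B, 2.0),
            ("C3", 2.09, 364.3, PEAK_WIDTH, PEAK_SHAPE),
        ),
    },
}

# the peak whose width is solved to balance the cycle integral; the solved
# circumferential C2 width is clipped (exact balance would degenerate at
# the apex), leaving a small residual mean well inside the 0.3 cm/s
# closure bound
_BALANCER = {"longitudinal": "S", "radial": "S", "circumferential": "C2"}
_WIDTH_BOUNDS = {"longitudinal": (10.0, 250.0), "radial": (10.0, 250.0),
                 "circumferential": (45.0, 90.0)}

UNNAMED_FEATURES = frozenset({"ES", "IR"})

DEFAULT_MODULATION_AMP = 0.3
DEFAULT_MODULATION_PHASE = {
    "longitudinal": np.deg2rad(100.0),  # lateral-dominant S_L / D_L
    "radial": np.deg2rad(150.0),  # inferolateral-dominant AS_R
    "circumferential": 0.0,
}
DEFAULT_TRANSMURAL = (1.16, 0.88)  # endo, epi radial scaling


@dataclass(frozen=True)
class Bump:
    """One velocity bump, A * exp(-|dt/w|^p / 2), periodic in the cycle.

    An optional distinct right-side width makes the bump skewed (fast
    upstroke, slow decay), as for the systolic ejection wave.
    """

    name: str
    amplitude: float  # cm/s
    time_ms: float
    width_ms: float
    shape: float = 2.0  # generalized-Gaussian exponent
    width_right_ms: float | None = None  # None: symmetric

    @property
    def _unit_integral(self) -> float:
        from scipy.special import gamma

        p = self.shape
        return 2.0 * 2.0 ** (1.0 / p) * gamma(1.0 / p) / p

    @property
    def area(self) -> float:
        wr = self.width_right_ms if self.width_right_ms is not None else self.width_ms
        return self.amplitude * 0.5 * (self.width_ms + wr) * self._unit_integral


@dataclass
class MotionModel:
    """Separable annulus motion: v(theta, d, t) = g(t) * m(theta) * h(d)."""

    slice_level: str
    rr_interval: float
    t_end_systole: float
    peaks: dict  # direction -> tuple[Bump, ...]
    modulation_amp: dict
    modulation_phase: dict
    transmural_endo: float = DEFAULT_TRANSMURAL[0]
    transmural_epi: float = DEFAULT_TRANSMURAL[1]

    def velocity(self, direction: str, t) -> np.ndarray:
        """Global velocity profile g(t) (cm/s), periodic in rr_interval."""
        t = np.asarray(t, dtype=float)
        rr = self.rr_interval
        out = np.zeros_like(t)
        for b in self.peaks.get(direction, ()):
            if b.amplitude == 0:
                continue
            dt = (t - b.time_ms + rr / 2.0) % rr - rr / 2.0
            if b.width_right_ms is None:
                w = b.width_ms
            else:
                w = np.where(dt >= 0, b.width_right_ms, b.width_ms)
            out = out + b.amplitude * np.exp(-0.5 * np.abs(dt / w) ** b.shape)
        return out

    def modulation(self, direction: str, theta) -> np.ndarray:
        amp = self.modulation_amp.get(direction, 0.0)
        phase = self.modulation_phase.get(direction, 0.0)
        return 1.0 + amp * np.cos(np.asarray(theta) - phase)

    def transmural(self, direction: str, depth) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        if direction != "radial":
            return np.ones_like(depth)
        return self.transmural_endo + (self.transmural_epi - self.transmural_endo) * depth

    def prescribed_peaks(self, direction: str) -> dict:
        return {
            b.name: VelocityPeak(b.name, b.amplitude, b.time_ms)
            for b in self.peaks.get(direction, ())
            if b.name not in UNNAMED_FEATURES and b.amplitude != 0
        }


def _solve_balancer(bumps: list[Bump], direction: str) -> list[Bump]:
    """Adjust one bump's width(s) so the signed bump areas cancel.

    The balancer width is clipped to its direction's bounds; any residual
    mean stays well inside the 0.3 cm/s closure bound.
    """
    name = _BALANCER.get(direction)
    if name is None:
        return bumps
    lo, hi = _WIDTH_BOUNDS[direction]
    others = sum(b.area for b in bumps if b.name != name)
    bal = next((b for b in bumps if b.name == name), None)
    if bal is None or bal.amplitude == 0:
        return bumps
    total = -2.0 * others / (bal.amplitude * bal._unit_integral)
    width = float(np.clip(total / 2.0, lo, hi))
    new = replace(bal, width_ms=width, width_right_ms=None)
    return [new if b.name == name else b for b in bumps]


def build_motion_model(
    slice_level: str,
    amplitude_overrides: dict | None = None,
    seed: int | None = None,
    params: AcquisitionParams = AcquisitionParams(),
    rr_interval: float = CANONICAL_RR,
    t_end_systole: float | None = None,
    amplitude_jitter: float = 0.0,
    time_jitter_ms: tuple[float, float] = (10.0, 25.0),
    modulation_amp: float = DEFAULT_MODULATION_AMP,
    modulation_phase: dict | None = None,
    transmural: tuple[float, float] = DEFAULT_TRANSMURAL,
) -> MotionModel:
    """Build the annulus motion model for one slice level.

    Canonical peak amplitudes/timings are the healthy-cohort means for that
    level; `amplitude_overrides` ({direction: {peak: cm/s}}) replaces
    individual amplitudes (0 suppresses a peak). Timings defined on the
    canonical 1000-ms cycle are warped so systole spans [0, t_end_systole]
    and diastole [t_end_systole, rr_interval]. With `amplitude_jitter` > 0 a
    seeded generator perturbs amplitudes (relative sd) and peak times
    (systolic/diastolic sd in ms) to emulate between-subject variability.
    """
    if slice_level not in SLICE_LEVELS:
        raise ValueError(f"slice_level must be one of {SLICE_LEVELS}")
    if rr_interval <= 0:
        raise ValueError("rr_interval must be positive")
    tes = CANONICAL_END_SYSTOLE if t_end_systole is None else float(t_end_systole)
    if not 0 < tes < rr_interval:
        raise ValueError("t_end_systole must lie inside the cycle")
    rng = np.random.default_rng(seed)
    overrides = amplitude_overrides or {}

    sys_scale = tes / CANONICAL_END_SYSTOLE
    dia_scale = (rr_interval - tes) / (CANONICAL_RR - CANONICAL_END_SYSTOLE)

    # timing of the systolic ejection and of the diastolic events (E-wave,
    # atrial contraction) varies between subjects but coherently across the
    # three velocity directions
    common_shifts = (
        rng.normal(0.0, 0.85 * time_jitter_ms[0]),
        rng.normal(0.0, 0.85 * time_jitter_ms[1]),
    ) if amplitude_jitter > 0 else (0.0, 0.0)

    peaks = {}
    for direction, table in PEAK_TABLES[slice_level].items():
        venc = (
            params.venc_through_plane
            if direction == "longitudinal"
            else params.venc_in_plane
        )
        bumps = []
        common_factor = (
            1.0 + rng.normal(0.0, amplitude_jitter) if amplitude_jitter > 0 else 1.0
        )
        # section-timing shifts are shared across peaks of one direction and
        # drawn per direction-independent class elsewhere; the systolic and
        # diastolic events (E-wave, atrial contraction) move coherently
        shift_sys = common_shifts[0]
        shift_dia = common_shifts[1]
        for name, amp, t0, width_spec, shape in table:
            width = width_spec
            amp = float(overrides.get(direction, {}).get(name, amp))
            if abs(amp) >= venc:
                raise ValueError(
                    f"{direction} peak {name} amplitude {amp} cm/s would wrap "
                    f"(venc {venc} cm/s)"
                )
            systolic = t0 <= CANONICAL_END_SYSTOLE
            scale = sys_scale if systolic else dia_scale
            t0 = t0 * sys_scale if systolic else tes + (t0 - CANONICAL_END_SYSTOLE) * dia_scale
            # widths shrink modestly with a short section but never widen
            # with a long one, so bump tails stay within their sections
            w_scale = float(np.clip(scale, 0.85, 1.0))
            if width is None:
                width = 40.0 * w_scale  # provisional; balancer solves it below
            else:
                width = width * w_scale
            if amplitude_jitter > 0:
                # common-mode per-direction scaling (subject "vigour") plus a
                # smaller independent per-peak perturbation: keeps the bump
                # areas in proportion so the solved balancer width is stable
                amp *= common_factor
                if name not in UNNAMED_FEATURES:
                    amp *= 1.0 + rng.normal(0.0, 0.4 * amplitude_jitter)
                    jit = time_jitter_ms[0] if systolic else time_jitter_ms[1]
                    shift = shift_sys if systolic else shift_dia
                    t0 = float(
                        np.clip(
                            t0 + shift + rng.normal(0.0, 0.5 * jit),
                            5.0,
                            rr_interval - 5.0,
                        )
                    )
            if name == "D":
                # the E-wave starts after isovolumic relaxation: keep the
                # early-diastolic peak a physiologic distance past end
                # systole; the gap shrinks no faster than the bump widths
                t0 = max(t0, tes + 95.0 * w_scale)
            elif name == "C1":
                # C1 follows the R-wave; keep its peak resolvable inside the
                # cycle rather than collapsing into the wrap boundary
                t0 = max(t0, 30.0 * sys_scale)
            elif name == "AS":
                # atrial systole stays clear of the next cycle's ejection
                t0 = min(t0, tes + 0.87 * (rr_interval - tes))
            bumps.append(Bump(name, amp, t0, width, shape))
        peaks[direction] = tuple(_solve_balancer(bumps, direction))

    phases = dict(DEFAULT_MODULATION_PHASE)
    if modulation_phase:
        phases.update(modulation_phase)
    return MotionModel(
        slice_level=slice_level,
        rr_interval=rr_interval,
        t_end_systole=tes,
        peaks=peaks,
        modulation_amp={d: modulation_amp for d in DIRECTIONS},
        modulation_phase=phases,
        transmural_endo=transmural[0],
        transmural_epi=transmural[1],
    )


# ---------------------------------------------------------------------------
# rasterized rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the phantom actually did, for recovery checks downstream."""

    model: MotionModel
    frame_times: np.ndarray
    t_end_systole: float
    global_factors: dict  # direction -> per-frame mean of m(theta)*h(d)
    prescribed_peaks: dict  # direction -> {name: VelocityPeak}
    effective_peaks: dict  # direction -> {name: VelocityPeak} incl. bump overlap
    background_coeffs: np.ndarray | None = None

    def effective_global_curve(self, direction: str, t) -> np.ndarray:
        """Prescribed global profile scaled by the rendered region factor."""
        f = np.interp(
            np.asarray(t, dtype=float) % self.model.rr_interval,
            self.frame_times,
            self.global_factors[direction],
            period=self.model.rr_interval,
        )
        return self.model.velocity(direction, t) * f


@dataclass
class RenderResult:
    truth: VelocityFieldSeries
    geometry: LVGeometry
    magnitude: np.ndarray
    ground_truth: GroundTruth


def _circle(center: np.ndarray, radius: float, n_vertices: int) -> np.ndarray:
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def surface_radii(
    model: MotionModel,
    times: np.ndarray,
    r_endo_mm: float = 20.0,
    r_epi_mm: float = 30.0,
):
    """Endo/epi radii at `times`, following the integrated radial velocity
    of each surface (transmural factor at depth 0 and 1 respectively)."""
    if r_endo_mm >= r_epi_mm:
        raise ValueError("endo radius must be smaller than epi radius")
    rr = model.rr_interval
    tt = np.arange(0.0, rr + 1.0, 1.0)
    g_rad = model.velocity("radial", tt)
    cum = cumulative_trapezoid(g_rad, tt, initial=0.0) * 0.01  # cm/s*ms -> mm
    disp = np.interp(np.asarray(times, dtype=float), tt, cum)
    r_endo = r_endo_mm - model.transmural("radial", 0.0) * disp
    r_epi = r_epi_mm - model.transmural("radial", 1.0) * disp
    if np.any(r_endo <= 0) or np.any(r_epi - r_endo <= 0):
        raise ValueError("annulus collapses under the prescribed motion")
    return r_endo, r_epi


def annulus_contours(
    model: MotionModel,
    times: np.ndarray,
    r_endo_mm: float = 20.0,
    r_epi_mm: float = 30.0,
    center_offset_mm: tuple[float, float] = (3.5, -2.6),
    landmark_angle: float = 2.0,
    contour_vertices: int = 180,
):
    """Per-frame circular endo/epi contours plus the anterior LV-RV landmark."""
    center = np.asarray(center_offset_mm, dtype=float)
    r_endo, r_epi = surface_radii(model, times, r_endo_mm, r_epi_mm)
    landmark = center + (r_epi.max() + 3.0) * np.array(
        [np.cos(landmark_angle), np.sin(landmark_angle)]
    )
    endo = [_circle(center, r, contour_vertices) for r in r_endo]
    epi = [_circle(center, r, contour_vertices) for r in r_epi]
    return endo, epi, landmark, (r_endo, r_epi)


def _effective_peaks(gt_curve, model, direction):
    out = {}
    rr = model.rr_interval
    tt = np.arange(0.0, rr, 1.0)
    e = gt_curve(direction, tt)
    for b in model.peaks.get(direction, ()):
        if b.name in UNNAMED_FEATURES or b.amplitude == 0:
            continue
        half = max(3.0 * b.width_ms, 50.0)
        dt = (tt - b.time_ms + rr / 2.0) % rr - rr / 2.0
        win = np.abs(dt) <= half
        seg = e[win]
        ts = tt[win]
        i = int(np.argmax(seg)) if b.amplitude > 0 else int(np.argmin(seg))
        out[b.name] = VelocityPeak(b.name, float(seg[i]), float(ts[i]))
    return out


def render_velocity_frames(
    model: MotionModel,
    params: AcquisitionParams = AcquisitionParams(),
    grid_size: int | None = None,
    n_frames: int | None = None,
    r_endo_mm: float = 20.0,
    r_epi_mm: float = 30.0,
    center_offset_mm: tuple[float, float] = (3.5, -2.6),
    landmark_angle: float = 2.0,
    contour_vertices: int = 180,
    blood_signal: float = 0.1,
) -> RenderResult:
    """Rasterize the annulus phantom into a per-frame velocity field.

    Contour radii follow the integrated radial velocity of the respective
    surface (wall thickening), the magnitude image emulates a black-blood
    acquisition (myocardium 1.0, blood pool 0.1, air 0) and the returned
    ground truth records the effective (region-factor adjusted) global
    peaks on a dense 1-ms grid.
    """
    grid_size = grid_size or params.matrix_size
    rr = model.rr_interval
    if n_frames is None:
        n_frames = int(np.floor(rr / params.temporal_resolution))
        if n_frames * params.temporal_resolution >= rr:
            n_frames -= 1
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frame_times = np.arange(n_frames) * params.temporal_resolution
    if frame_times[-1] >= rr:
        frame_times = np.linspace(0.0, rr, n_frames, endpoint=False)

    center = np.asarray(center_offset_mm, dtype=float)
    endo, epi, landmark, (r_endo, r_epi) = annulus_contours(
        model, frame_times, r_endo_mm, r_epi_mm, center_offset_mm,
        landmark_angle, contour_vertices,
    )
    half_fov = grid_size * params.pixel_spacing / 2.0
    if r_epi.max() + np.hypot(*center) + 3.0 > half_fov:
        raise ValueError("annulus does not fit inside the image grid")
    geom = compute_geometry(
        endo, epi, landmark, grid_size, params.pixel_spacing, model.slice_level
    )

    vel = np.zeros((n_frames, grid_size, grid_size, 3))
    magnitude = np.zeros((n_frames, grid_size, grid_size))
    factors = {d: np.zeros(n_frames) for d in DIRECTIONS}
    x, y = pixel_coords(grid_size, params.pixel_spacing)
    for f, t in enumerate(frame_times):
        m = geom.mask[f]
        theta = geom.theta[f][m]
        depth = geom.depth[f][m]
        rx, ry, chx, chy = geom.unit_vectors(f)
        mod = {d: model.modulation(d, theta) for d in DIRECTIONS}
        v_long = model.velocity("longitudinal", t) * mod["longitudinal"]
        v_rad = (
            model.velocity("radial", t)
            * mod["radial"]
            * model.transmural("radial", depth)
        )
        v_circ = model.velocity("circumferential", t) * mod["circumferential"]
        vel[f, :, :, 0][m] = -v_rad * rx[m] + v_circ * chx[m]
        vel[f, :, :, 1][m] = -v_rad * ry[m] + v_circ * chy[m]
        vel[f, :, :, 2][m] = v_long
        factors["longitudinal"][f] = mod["longitudinal"].mean()
        factors["radial"][f] = (mod["radial"] * model.transmural("radial", depth)).mean()
        factors["circumferential"][f] = mod["circumferential"].mean()
        inside_endo = (
            np.hypot(x - center[0], y - center[1]) < r_endo[f]
        )
        magnitude[f][inside_endo] = blood_signal
        magnitude[f][m] = 1.0

    truth = VelocityFieldSeries(velocities=vel, frame_times=frame_times, rr_interval=rr)
    gt = GroundTruth(
        model=model,
        frame_times=frame_times,
        t_end_systole=model.t_end_systole,
        global_factors=factors,
        prescribed_peaks={d: model.prescribed_peaks(d) for d in DIRECTIONS},
        effective_peaks={},
    )
    gt.effective_peaks = {
        d: _effective_peaks(gt.effective_global_curve, model, d) for d in DIRECTIONS
    }
    return RenderResult(truth=truth, geometry=geom, magnitude=magnitude, ground_truth=gt)


# ---------------------------------------------------------------------------
# phase encoding
# ---------------------------------------------------------------------------

def polynomial_background(coeffs: np.ndarray, grid_size: int) -> np.ndarray:
    """Second-order 2-D polynomial phase field on normalized [-1,1] coords."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (6,):
        raise ValueError("expected 6 polynomial coefficients")
    u = np.linspace(-1.0, 1.0, grid_size)
    uu, vv = np.meshgrid(u, u, indexing="xy")
    return c[0] + c[1] * uu + c[2] * vv + c[3] * uu**2 + c[4] * uu * vv + c[5] * vv**2


def random_background_coeffs(seed=None, scale: float = 0.08) -> np.ndarray:
    """One 6-coefficient background polynomial per phase set (ref, x, y, z)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, scale, size=(4, 6))


def encode_phases(
    truth: VelocityFieldSeries,
    params: AcquisitionParams = AcquisitionParams(),
    background_coeffs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    magnitude: np.ndarray | None = None,
) -> EncodedSeries:
    """Encode a velocity field into reference + x/y/z phase sets.

    phi_encoded = background + pi * v / venc (in-plane venc for x and y,
    through-plane for z); the reference set carries only its background.
    Independent Gaussian phase noise of sd `noise_sd` rad is added to every
    set and the result is wrapped to [-pi, pi).
    """
    grid = truth.grid_shape[0]
    if background_coeffs is None:
        background_coeffs = np.zeros((4, 6))
    background_coeffs = np.asarray(background_coeffs, dtype=float)
    if background_coeffs.shape != (4, 6):
        raise ValueError("background_coeffs must have shape (4, 6)")
    for comp in ("x", "y", "z"):
        venc = params.venc(comp)
        vmax = np.abs(truth.component(comp)).max()
        if vmax >= venc:
            raise ValueError(
                f"velocity component {comp} reaches {vmax:.2f} cm/s, at or above "
                f"venc {venc} cm/s: phase would wrap"
            )
    rng = np.random.default_rng(seed)
    phases = {}
    for row, name in enumerate(("reference", "x", "y", "z")):
        bg = polynomial_background(background_coeffs[row], grid)
        phi = np.broadcast_to(bg, truth.velocities.shape[:3]).copy()
        if name != "reference":
            phi += np.pi * truth.component(name) / params.venc(name)
        if noise_sd > 0:
            phi += rng.normal(0.0, noise_sd, size=phi.shape)
        phases[name] = wrap_phase(phi)
    if magnitude is None:
        magnitude = np.ones(truth.velocities.shape[:3])
    return EncodedSeries(
        magnitude=np.asarray(magnitude, dtype=float),
        phases=phases,
        frame_times=truth.frame_times,
        params=params,
        background_coeffs=background_coeffs,
    )


def generate_stationary_series(
    params: AcquisitionParams = AcquisitionParams(),
    grid_size: int | None = None,
    frame_times: np.ndarray | None = None,
    rr_interval: float | None = None,
    background_coeffs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> EncodedSeries:
    """Stationary homogeneous phantom: zero velocity, same background model."""
    grid_size = grid_size or params.matrix_size
    rr = rr_interval or params.rr_interval
    if frame_times is None:
        n = int(np.floor(rr / params.temporal_resolution))
        frame_times = np.arange(n) * params.temporal_resolution
        frame_times = frame_times[frame_times < rr]
    truth = VelocityFieldSeries(
        velocities=np.zeros((len(frame_times), grid_size, grid_size, 3)),
        frame_times=frame_times,
        rr_interval=rr,
    )
    return encode_phases(
        truth, params, background_coeffs=background_coeffs, noise_sd=noise_sd, seed=seed
    )


# ---------------------------------------------------------------------------
# respiratory navigator simulation
# ---------------------------------------------------------------------------

@dataclass
class RespiratoryTrace:
    """Diaphragm position (mm from end-expiration) once per cardiac cycle."""

    positions: np.ndarray
    rr_interval: float = 1000.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be a 1-D array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")


def generate_respiratory_trace(
    n_cycles: int,
    rr_interval: float = 1000.0,
    amplitude: float = 3.0,
    period_cycles: float = 12.0,
    drift: float = 0.5,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> RespiratoryTrace:
    """Guided-breathing-like diaphragm trace: slow sinusoid + drift + noise."""
    rng = np.random.default_rng(seed)
    i = np.arange(n_cycles)
    pos = (
        amplitude * np.sin(2 * np.pi * i / period_cycles)
        + drift * i / max(n_cycles - 1, 1)
        + rng.normal(0.0, noise_sd, n_cycles)
    )
    return RespiratoryTrace(positions=pos, rr_interval=rr_interval)


def simulate_navigator_gating(trace, window: float = 5.0):
    """Dual-navigator acceptance: a cycle is kept only when the navigators
    immediately before and after its acquisition both fall inside the window.

    The final cycle has no following navigator and is rejected. Returns the
    per-cycle acceptance mask and the scan efficiency (accepted fraction).
    """
    pos = trace.positions if isinstance(trace, RespiratoryTrace) else np.asarray(trace, float)
    if pos.ndim != 1 or len(pos) < 2:
        raise ValueError("trace needs at least 2 cycles")
    half = window / 2.0
    inside = np.abs(pos) <= half
    mask = np.zeros(len(pos), dtype=bool)
    mask[:-1] = inside[:-1] & inside[1:]
    return mask, float(mask.mean())
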