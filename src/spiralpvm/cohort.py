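"""Cardiac-phase normalization, cohort averaging and 24-segment colour maps.

Heart rate varies between subjects, so averaging velocity-time curves on the
raw ms axis smears the later (diastolic and atrial-systolic) peaks. Each
curve is therefore warped section by section — systole, early diastole,
diastasis, atrial systole — onto a fixed phase template before averaging,
with values resampled by shape-preserving (monotone) piecewise cubic
interpolation. Regional curves from 24 equal-angle segments, normalized and
averaged over subjects, form a segments x time colour grid that summarizes
the regional velocity pattern over the entire cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .curves import CardiacPhaseMarkers, VelocityTimeCurve


@dataclass(frozen=True)
class PhaseTemplate:
    """Target section lengths (ms) and the uniform output grid."""

    systole: float = 350.0
    early_diastole: float = 150.0
    diastasis: float = 300.0
    atrial_systole: float = 200.0
    n_points: int = 60

    def __post_init__(self) -> None:
        for name in ("systole", "early_diastole", "diastasis", "atrial_systole"):
            if getattr(self, name) <= 0:
                raise ValueError(f"template section {name} must be positive")
        if self.n_points < 4:
            raise ValueError("template grid needs at least 4 points")

    @property
    def cycle_length(self) -> float:
        return self.systole + self.early_diastole + self.diastasis + self.atrial_systole

    @property
    def boundaries(self) -> np.ndarray:
        """Section boundary times: 0, ES, diastasis on, atrial on, cycle end."""
        return np.cumsum(
            [0.0, self.systole, self.early_diastole, self.diastasis, self.atrial_systole]
        )

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n_points) * self.cycle_length / self.n_points


DEFAULT_TEMPLATE = PhaseTemplate()


def _marker_times(markers: CardiacPhaseMarkers) -> np.ndarray:
    return np.array(
        [
            0.0,
            markers.t_end_systole,
            markers.t_diastasis_onset,
            markers.t_atrial_onset,
            markers.rr_interval,
        ]
    )


def normalize_curve(
    curve: VelocityTimeCurve,
    markers: CardiacPhaseMarkers,
    template: PhaseTemplate = DEFAULT_TEMPLATE,
    interpolation: str = "pchip",
) -> VelocityTimeCurve:
    """Warp one curve onto the phase template, section by section.

    The warp maps each section boundary onto the corresponding template
    boundary, linearly within each section (monotone by construction), and
    resamples values by piecewise cubic interpolation (monotone PCHIP by
    default, plain cubic spline via ``interpolation='cubic'``). Section
    boundary values are preserved exactly.
    """
    src = _marker_times(markers)
    dst = template.boundaries
    t = curve.times
    if t[0] < 0 or t[-1] >= markers.rr_interval or t[0] > curve.phase_spacing:
        raise ValueError("markers outside curve support: the curve must cover "
                         "the cycle from the R-wave")
    # cyclic closure so the warp input covers [0, rr]
    t_ext = np.concatenate([t, [markers.rr_interval]])
    v_ext = np.concatenate([curve.values, [curve.values[0]]])
    if interpolation == "pchip":
        interp = PchipInterpolator(t_ext, v_ext)
    elif interpolation == "cubic":
        interp = CubicSpline(t_ext, v_ext, bc_type="periodic")
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # inverse warp: template time -> original time, piecewise linear
    original_times = np.interp(template.grid, dst, src)
    values = interp(original_times)
    return VelocityTimeCurve(
        times=template.grid,
        values=values,
        direction=curve.direction,
        region=curve.region,
        rr_interval=template.cycle_length,
    )


def group_average(curves: list[VelocityTimeCurve]):
    """Pointwise mean curve and SD band over subjects on a common grid."""
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(t0) or not np.allclose(c.times, t0):
            raise ValueError("curves are not on the same template grid")
    stack = np.vstack([c.values for c in curves])
    mean = VelocityTimeCurve(
        times=t0,
        values=stack.mean(axis=0),
        direction=curves[0].direction,
        region=curves[0].region,
        rr_interval=curves[0].rr_interval,
    )
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(t0)
    return mean, sd


@dataclass
class ColourGrid:
    """24 angular segments (anterior at top, by increasing theta) x time."""

    values: np.ndarray  # (24, T) cm/s
    times: np.ndarray  # template grid (ms)
    direction: str
    slice_level: str
    marker_columns: tuple  # indices of the three interior section boundaries
    segment_names: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 24:
            raise ValueError("colour grid must have exactly 24 segment rows")
        if self.values.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")
        if list(self.marker_columns) != sorted(set(self.marker_columns)):
            raise ValueError("marker columns must be strictly increasing")

    @property
    def colour_limit(self) -> float:
        """Symmetric colour scale bound for this direction."""
        return float(np.abs(self.values).max())


def build_colour_grid(
    segment_curves: list[VelocityTimeCurve],
    direction: str,
    slice_level: str,
    template: PhaseTemplate = DEFAULT_TEMPLATE,
) -> ColourGrid:
    """Assemble 24 normalized equal-angle segment curves into a colour grid.

    Row order follows increasing theta from the anterior junction (anterior,
    lateral, inferior, septal quadrants top to bottom).
    """
    if len(segment_curves) != 24:
        raise ValueError("expected exactly 24 segment curves")
    grid = template.grid
    for c in segment_curves:
        if len(c.times) != len(grid) or not np.allclose(c.times, grid):
            raise ValueError("segment curves must be on the template grid")
    values = np.vstack([c.values for c in segment_curves])
    interior = template.boundaries[1:4]
    marker_columns = tuple(int(np.searchsorted(grid, b)) for b in interior)
    return ColourGrid(
        values=values,
        times=grid,
        direction=direction,
        slice_level=slice_level,
        marker_columns=marker_columns,
        segment_names=tuple(c.region for c in segment_curves),
    )
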