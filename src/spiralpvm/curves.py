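"""Velocity-time curve analysis: cardiac-phase markers, named peaks and TTP.

The myocardial velocity-time curve of a healthy ventricle carries a small
set of named extrema: systolic (S), early-diastolic (D) and atrial-systolic
(AS) peaks in the longitudinal and radial directions, and a biphasic
early-systolic pair (C1, C2) plus an early-diastolic peak (C3) in the
circumferential direction. End systole is located at the first negative
radial peak after the systolic radial maximum; its time defines the length
of systole. Times to peak (TTP) are reported in ms from the R-wave, as a
percentage of systolic or diastolic length, and converted to a fixed-length
ms scale using population-average lengths of systole (350 ms) and diastole
(650 ms) so that values from hearts beating at different rates can be
compared directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np
import pandas as pd

from ._utils import local_maxima_runs, local_minima_runs, moving_average, round_half_away

SYSTOLIC_PEAKS = frozenset({"S", "C1", "C2"})
DIASTOLIC_PEAKS = frozenset({"D", "AS", "C3"})
DIRECTIONS = ("longitudinal", "radial", "circumferential")
DIRECTION_SUFFIX = {"longitudinal": "L", "radial": "R", "circumferential": ""}


@dataclass
class VelocityTimeCurve:
    times: np.ndarray  # ms
    values: np.ndarray  # cm/s
    direction: str = "longitudinal"
    region: str = "global"
    rr_interval: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    @property
    def phase_spacing(self) -> float:
        return float(np.median(np.diff(self.times)))

    def smoothed(self, window: int) -> np.ndarray:
        return moving_average(self.values, window)


@dataclass(frozen=True)
class CardiacPhaseMarkers:
    t_end_systole: float
    t_diastasis_onset: float
    t_atrial_onset: float
    rr_interval: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.t_end_systole
            < self.t_diastasis_onset
            < self.t_atrial_onset
            < self.rr_interval
        ):
            raise ValueError("markers must satisfy 0 < ES < diastasis < atrial < RR")


@dataclass(frozen=True)
class VelocityPeak:
    name: str
    amplitude: float  # cm/s
    ttp_ms: float  # from the R-wave


@dataclass
class PeakSet:
    direction: str
    peaks: dict = field(default_factory=dict)  # name -> VelocityPeak; absent = missing
    noise_floor: float = 0.0

    def get(self, name: str) -> VelocityPeak | None:
        return self.peaks.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self.peaks


@dataclass(frozen=True)
class NormalizationConstants:
    """Population-average section lengths used for fixed-length TTP (ms)."""

    avg_systole: float = 350.0
    avg_diastole: float = 650.0

    def __post_init__(self) -> None:
        if self.avg_systole <= 0 or self.avg_diastole <= 0:
            raise ValueError("section lengths must be positive")


DEFAULT_CONSTANTS = NormalizationConstants()


def peak_class(name: str) -> str:
    if name in SYSTOLIC_PEAKS:
        return "systolic"
    if name in DIASTOLIC_PEAKS:
        return "diastolic"
    raise ValueError(f"unknown peak name {name!r}")


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------

def detect_end_systole(
    curve: VelocityTimeCurve,
    smooth_window: int = 3,
    min_depth_frac: float = 0.10,
) -> float:
    """Time of end systole: first negative local minimum of the global radial
    curve after its systolic maximum (ties broken to the earliest sample).

    A qualifying minimum must reach below ``min_depth_frac`` of the curve's
    peak magnitude so that noise dips around the zero crossing are not
    mistaken for the end-systolic notch.
    """
    v = curve.smoothed(smooth_window)
    i_max = int(np.argmax(v))
    depth = -min_depth_frac * float(np.abs(v).max())
    for start, _stop in local_minima_runs(v):
        if start > i_max and v[start] < depth:
            return float(curve.times[start])
    raise ValueError("no negative radial minimum after the systolic maximum; "
                     "curve not analyzable")


def detect_phase_markers(
    curve: VelocityTimeCurve,
    t_end_systole: float,
    rel_threshold: float = 0.25,
    sustain: int = 2,
    smooth_window: int = 3,
    default_atrial_fraction: float = 0.75,
) -> CardiacPhaseMarkers:
    """Locate diastasis onset and atrial-systole onset on a global radial curve.

    Diastasis begins at the first time after the early-diastolic peak (D_R)
    at which |v_R| drops below ``rel_threshold`` of |D_R| and stays below for
    ``sustain`` consecutive phases. Atrial systole begins at the last local
    minimum of |v_R| before the atrial peak. If no atrial peak is found the
    onset falls back to ``default_atrial_fraction`` of diastole and the
    marker set is flagged.
    """
    if curve.rr_interval is None:
        raise ValueError("curve must carry rr_interval")
    rr = curve.rr_interval
    t = curve.times
    v = curve.smoothed(smooth_window)
    after_es = np.nonzero(t > t_end_systole)[0]
    if len(after_es) < sustain + 2:
        raise ValueError("too few samples after end systole")
    d_idx = after_es[int(np.argmin(v[after_es]))]
    d_amp = abs(v[d_idx])
    if d_amp <= 0:
        raise ValueError("no early-diastolic radial peak found")
    thr = rel_threshold * d_amp

    t_dia = None
    absv = np.abs(v)
    for i in range(d_idx + 1, len(t) - sustain + 1):
        if np.all(absv[i : i + sustain] < thr):
            t_dia = float(t[i])
            dia_idx = i
            break
    if t_dia is None:
        raise ValueError("no diastasis plateau found after the diastolic peak")

    tail = np.arange(dia_idx + 1, len(t))
    flagged = False
    as_idx = tail[int(np.argmin(v[tail]))] if len(tail) else None
    if as_idx is None or abs(v[as_idx]) < thr:
        # atrial peak absent: fall back to a fixed fraction of diastole
        t_atr = t_end_systole + default_atrial_fraction * (rr - t_end_systole)
        flagged = True
    else:
        seg = absv[dia_idx : as_idx + 1]
        runs = [r for r in local_minima_runs(seg)]
        if runs:
            t_atr = float(t[dia_idx + runs[-1][1]])
        else:
            t_atr = float(t[dia_idx + int(np.argmin(seg))])
        if t_atr < t_dia:
            t_atr = t_dia
    eps = curve.phase_spacing * 0.5
    if t_atr <= t_dia:
        t_atr = t_dia + eps
    return CardiacPhaseMarkers(
        t_end_systole=float(t_end_systole),
        t_diastasis_onset=t_dia,
        t_atrial_onset=min(t_atr, rr - eps),
        rr_interval=rr,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _window(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.nonzero((t > lo) & (t <= hi))[0]


def _noise_floor(t, v, markers, factor):
    # second half of diastasis, linearly detrended: the early part of the
    # window can still carry the decaying early-diastolic tail, which would
    # inflate the floor and mask genuine atrial peaks
    mid = 0.5 * (markers.t_diastasis_onset + markers.t_atrial_onset)
    idx = np.nonzero((t >= mid) & (t <= markers.t_atrial_onset))[0]
    if len(idx) < 3:
        idx = np.nonzero(
            (t >= markers.t_diastasis_onset) & (t <= markers.t_atrial_onset)
        )[0]
    if len(idx) < 2:
        return 1e-9
    resid = v[idx] - np.polyval(np.polyfit(t[idx], v[idx], 1), t[idx])
    return max(factor * float(np.std(resid)), 1e-9)


def _parabolic_refine(t: np.ndarray, v: np.ndarray, idx: int, rr: float):
    """Sub-sample extremum estimate from a 3-point parabola.

    The sampled curve is a linearly interpolated rendering of a smooth
    velocity waveform, so the grid extremum underestimates the true peak;
    a local quadratic fit recovers most of the discretization loss. Falls
    back to the grid sample when the fit is degenerate.
    """
    n = len(v)
    im, ip = (idx - 1) % n, (idx + 1) % n
    tm = t[im] - rr if idx == 0 else t[im]
    tp = t[ip] + rr if idx == n - 1 else t[ip]
    tt = np.array([tm, t[idx], tp])
    vv = np.array([v[im], v[idx], v[ip]])
    a, b, c = np.polyfit(tt - t[idx], vv, 2)
    if a == 0:
        return float(v[idx]), float(t[idx])
    dt = -b / (2 * a)
    h = max(t[idx] - tm, tp - t[idx])
    if not -h <= dt <= h:
        return float(v[idx]), float(t[idx])
    amp = float(a * dt * dt + b * dt + c)
    # the vertex must still be an extremum of the same kind
    if (amp - v[idx]) * np.sign(a) > 0:
        return float(v[idx]), float(t[idx])
    return amp, float(t[idx] + dt)


def detect_peaks(
    curve: VelocityTimeCurve,
    direction: str | None = None,
    slice_level: str = "mid",
    markers: CardiacPhaseMarkers | None = None,
    smooth_window: int = 3,
    noise_floor_factor: float = 3.0,
    report_c3: bool | None = None,
    refine: bool = True,
) -> PeakSet:
    """Detect the named peaks of one velocity-time curve.

    A peak is reported absent (missing from the result) when no qualifying
    extremum exceeds the noise floor, taken as ``noise_floor_factor`` times
    the standard deviation of the curve inside the diastasis window.
    """
    if markers is None:
        raise ValueError("markers are required")
    direction = direction or curve.direction
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    t = curve.times
    v = curve.smoothed(smooth_window)
    floor = _noise_floor(t, v, markers, noise_floor_factor)
    out = PeakSet(direction=direction, noise_floor=floor)
    rr = markers.rr_interval

    def add(name, idx):
        if refine:
            amp, ttp = _parabolic_refine(t, v, idx, rr)
        else:
            amp, ttp = float(v[idx]), float(t[idx])
        out.peaks[name] = VelocityPeak(name, amp, ttp)

    if direction in ("longitudinal", "radial"):
        idx = _window(t, 0.0, markers.t_end_systole)
        if len(idx):
            i = idx[int(np.argmax(v[idx]))]
            if v[i] > floor:
                add("S", i)
        idx = _window(t, markers.t_end_systole, markers.t_diastasis_onset)
        if len(idx):
            i = idx[int(np.argmin(v[idx]))]
            if v[i] < -floor:
                add("D", i)
        idx = _window(t, markers.t_atrial_onset, rr)
        if len(idx):
            i = idx[int(np.argmin(v[idx]))]
            if v[i] < -floor:
                add("AS", i)
        return out

    # circumferential: biphasic early-systolic pair, then early-diastolic C3
    minima = local_minima_runs(v)
    c1_idx = None
    for start, _stop in minima:
        if 0.0 < t[start] <= markers.t_end_systole and v[start] < -floor:
            c1_idx = start
            break
    if c1_idx is not None:
        add("C1", c1_idx)
        apical = slice_level == "apical"
        for start, _stop in local_maxima_runs(v):
            if t[start] <= t[c1_idx] or t[start] > markers.t_end_systole * 1.25:
                continue
            ok = abs(v[start]) > floor if apical else v[start] > floor
            if ok:
                add("C2", start)
                break
    if report_c3 is None:
        report_c3 = slice_level != "mid"
    if report_c3:
        idx = _window(t, markers.t_end_systole, markers.t_diastasis_onset)
        if len(idx):
            if slice_level == "apical":
                i = idx[int(np.argmax(v[idx]))]
                if v[i] > floor:
                    add("C3", i)
            else:
                i = idx[int(np.argmin(v[idx]))]
                if v[i] < -floor:
                    add("C3", i)
    return out


# ---------------------------------------------------------------------------
# TTP normalization
# ---------------------------------------------------------------------------

def ttp_percent(ttp_ms: float, klass: str, markers: CardiacPhaseMarkers) -> float:
    """TTP as a percentage of systolic or diastolic length."""
    if not 0.0 <= ttp_ms <= markers.rr_interval:
        raise ValueError("TTP outside the cardiac cycle")
    if klass == "systolic":
        return 100.0 * ttp_ms / markers.t_end_systole
    if klass == "diastolic":
        return 100.0 * (ttp_ms - markers.t_end_systole) / (
            markers.rr_interval - markers.t_end_systole
        )
    raise ValueError(f"unknown peak class {klass!r}")


def _dec(x: float) -> Decimal:
    return Decimal(repr(float(x)))


def ttp_fixed_length(
    percent: float,
    klass: str,
    constants: NormalizationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert a TTP percentage to ms on the fixed-length cycle.

    Systolic peaks map onto [0, avg_systole]; diastolic peaks onto
    [avg_systole, avg_systole + avg_diastole]. Arithmetic is done in decimal
    so printed-precision inputs convert the way a printed table would.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    p = _dec(percent) / Decimal(100)
    if klass == "systolic":
        value = p * _dec(constants.avg_systole)
    elif klass == "diastolic":
        value = _dec(constants.avg_systole) + p * _dec(constants.avg_diastole)
    else:
        raise ValueError(f"unknown peak class {klass!r}")
    return float(value)


def ttp_fixed_difference(
    delta_percent: float,
    klass: str,
    constants: NormalizationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Fixed-length ms difference for a paired TTP-percentage difference.

    The diastolic offset cancels in a paired difference, leaving the affine
    slope avg_systole/100 (systolic) or avg_diastole/100 (diastolic).
    """
    if klass == "systolic":
        slope = _dec(constants.avg_systole) / Decimal(100)
    elif klass == "diastolic":
        slope = _dec(constants.avg_diastole) / Decimal(100)
    else:
        raise ValueError(f"unknown peak class {klass!r}")
    return float(_dec(delta_percent) * slope)


def e_over_a(d_amplitude: float, as_amplitude: float) -> float:
    """Ratio of early-diastolic to atrial-systolic peak magnitude."""
    if as_amplitude == 0 or not math.isfinite(as_amplitude):
        raise ValueError("atrial-systolic amplitude must be nonzero")
    return abs(d_amplitude) / abs(as_amplitude)


def summarize_peaks(
    peakset: PeakSet,
    markers: CardiacPhaseMarkers,
    constants: NormalizationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Tidy per-peak table: amplitude, TTP ms, TTP %, fixed-length TTP ms."""
    suffix = DIRECTION_SUFFIX[peakset.direction]
    rows = []
    for name, pk in peakset.peaks.items():
        klass = peak_class(name)
        pct = ttp_percent(pk.ttp_ms, klass, markers)
        fixed = ttp_fixed_length(pct, klass, constants)
        label = f"{name}_{suffix}" if suffix else name
        rows.append(
            {
                "peak": label,
                "direction": peakset.direction,
                "class": klass,
                "amplitude_cm_s": pk.amplitude,
                "ttp_ms": pk.ttp_ms,
                "ttp_percent": pct,
                "ttp_fixed_ms": round_half_away(fixed, 1),
            }
        )
    df = pd.DataFrame(rows)
    d, a = peakset.get("D"), peakset.get("AS")
    if d is not None and a is not None and a.amplitude != 0:
        df.attrs["e_over_a"] = e_over_a(d.amplitude, a.amplitude)
    return df
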