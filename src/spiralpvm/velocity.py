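"""Velocity reconstruction: phase differencing, retrospective gating and
stationary-phantom background correction.

Each velocity component is recovered from the wrapped difference between an
encoded phase set and the reference set, v = venc * wrap(dphi) / pi. The
acquired frames are then interpolated linearly (and cyclically across the
R-wave) onto 60 equally spaced cardiac phases. Residual background phase
errors (eddy currents, concomitant gradients) are removed empirically by
subtracting a median-smoothed velocity map measured on a stationary
phantom, pixel by pixel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import median_filter

from ._utils import wrap_phase
from .series import EncodedSeries, VelocityFieldSeries

logger = logging.getLogger(__name__)


def phase_difference_to_velocity(encoded: EncodedSeries) -> VelocityFieldSeries:
    """Convert the four phase sets into a 3-component velocity series.

    No phase unwrapping is attempted: myocardial velocities are assumed to
    stay below venc. A velocity at or beyond venc logs a warning.
    """
    params = encoded.params
    ref = encoded.phases["reference"]
    shape = encoded.magnitude.shape + (3,)
    vel = np.zeros(shape)
    for i, comp in enumerate(("x", "y", "z")):
        venc = params.venc(comp)
        dphi = wrap_phase(encoded.phases[comp] - ref)
        v = venc * dphi / np.pi
        if np.abs(v).max() >= venc * 0.999:
            logger.warning(
                "component %s reaches venc (%g cm/s): possible wrap-through", comp, venc
            )
        vel[..., i] = v
    return VelocityFieldSeries(
        velocities=vel,
        frame_times=encoded.frame_times,
        rr_interval=params.rr_interval,
    )


def retro_gate_interpolate(
    series: VelocityFieldSeries,
    rr_interval: float | None = None,
    n_phases: int = 60,
) -> VelocityFieldSeries:
    """Retrospective gating: per-pixel linear interpolation onto n_phases
    equally spaced times t_k = k * rr / n_phases.

    The gap between the last acquired frame and the first frame of the next
    cycle is interpolated cyclically (retro-gating closes the cycle).
    """
    rr = rr_interval if rr_interval is not None else series.rr_interval
    t = np.asarray(series.frame_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 acquired frames")
    if np.any(np.diff(t) <= 0):
        raise ValueError("acquired frame times must be sorted strictly increasing")
    targets = np.arange(n_phases) * rr / n_phases
    # cyclic extension: previous cycle's last frame and next cycle's first
    t_ext = np.concatenate([[t[-1] - rr], t, [t[0] + rr]])
    idx = np.searchsorted(t_ext, targets, side="right") - 1
    idx = np.clip(idx, 0, len(t_ext) - 2)
    t0 = t_ext[idx]
    t1 = t_ext[idx + 1]
    w = np.where(t1 > t0, (targets - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    # map extension slots back to acquired frame indices
    frame0 = np.where(idx == 0, len(t) - 1, idx - 1)
    frame1 = np.where(idx + 1 == len(t_ext) - 1, 0, idx)
    out = (1.0 - w)[:, None, None, None] * series.velocities[frame0] + w[
        :, None, None, None
    ] * series.velocities[frame1]
    return VelocityFieldSeries(velocities=out, frame_times=targets, rr_interval=rr)


def smooth_background_map(
    stationary: VelocityFieldSeries,
    kernel_size: int = 5,
    temporal_window: int | None = None,
) -> VelocityFieldSeries:
    """Median filtering of a stationary-phantom velocity map.

    A 2-D median of size ``kernel_size`` is applied per component. By
    default each frame is filtered independently; ``temporal_window`` adds a
    temporal extent to the median, and ``temporal_window=0`` takes the
    median across the entire time axis — appropriate because the phantom is
    stationary, so its frames differ only by noise.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be a positive odd integer")
    v = stationary.velocities
    if temporal_window == 0:
        collapsed = np.median(v, axis=0)
        out = np.empty_like(v)
        for c in range(3):
            sm = (
                median_filter(collapsed[:, :, c], size=kernel_size, mode="nearest")
                if kernel_size > 1
                else collapsed[:, :, c]
            )
            out[..., c] = sm[None, :, :]
    elif temporal_window is None or temporal_window == 1:
        if kernel_size == 1:
            out = v.copy()
        else:
            out = np.empty_like(v)
            for f in range(stationary.n_frames):
                for c in range(3):
                    out[f, :, :, c] = median_filter(
                        v[f, :, :, c], size=kernel_size, mode="nearest"
                    )
    else:
        if temporal_window % 2 == 0:
            raise ValueError("temporal_window must be odd (or 0 for the full axis)")
        out = np.empty_like(v)
        for c in range(3):
            out[..., c] = median_filter(
                v[..., c],
                size=(min(temporal_window, v.shape[0]), kernel_size, kernel_size),
                mode="nearest",
            )
    return VelocityFieldSeries(
        velocities=out,
        frame_times=stationary.frame_times,
        rr_interval=stationary.rr_interval,
    )


def subtract_background(
    subject: VelocityFieldSeries, background: VelocityFieldSeries
) -> VelocityFieldSeries:
    """Pixel-by-pixel, frame-by-frame subtraction of the background map."""
    if subject.velocities.shape != background.velocities.shape:
        raise ValueError("subject and background series shapes do not match")
    return VelocityFieldSeries(
        velocities=subject.velocities - background.velocities,
        frame_times=subject.frame_times,
        rr_interval=subject.rr_interval,
    )


def reconstruct_velocities(
    encoded: EncodedSeries,
    stationary: EncodedSeries | None = None,
    rr_interval: float | None = None,
    n_phases: int = 60,
    median_kernel: int = 5,
    median_temporal_window: int | None = 0,
) -> VelocityFieldSeries:
    """Full reconstruction chain: phase difference, retro-gated interpolation
    to n_phases, then optional stationary-phantom background correction."""
    subject = retro_gate_interpolate(
        phase_difference_to_velocity(encoded), rr_interval, n_phases
    )
    if stationary is None:
        return subject
    bg = retro_gate_interpolate(
        phase_difference_to_velocity(stationary), rr_interval, n_phases
    )
    bg = smooth_background_map(bg, median_kernel, median_temporal_window)
    return subtract_background(subject, bg)
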