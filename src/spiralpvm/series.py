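"""In-memory containers for velocity-encoded image series.

A `VelocityFieldSeries` holds per-frame per-pixel three-component velocity in
image coordinates (vx, vy in-plane, vz through-plane, cm/s). An
`EncodedSeries` holds the magnitude image and the four phase sets (reference
plus x/y/z velocity encodings, radians in [-pi, pi)) that a phase-contrast
acquisition produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionParams

PHASE_SET_NAMES = ("reference", "x", "y", "z")
COMPONENT_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class VelocityFieldSeries:
    """frames x rows x cols x 3 velocity grid (cm/s) with frame timing."""

    velocities: np.ndarray
    frame_times: np.ndarray  # ms from the R-wave
    rr_interval: float  # ms

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.velocities.ndim != 4 or self.velocities.shape[-1] != 3:
            raise ValueError("velocities must have shape (frames, rows, cols, 3)")
        if len(self.frame_times) != self.velocities.shape[0]:
            raise ValueError("frame_times length must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.frame_times[0] < 0 or self.frame_times[-1] >= self.rr_interval:
            raise ValueError("frame_times must lie in [0, rr_interval)")

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self):
        return self.velocities.shape[1:3]

    def component(self, name: str) -> np.ndarray:
        return self.velocities[..., COMPONENT_INDEX[name]]


@dataclass
class EncodedSeries:
    """Magnitude plus the four phase sets of one velocity-encoded series."""

    magnitude: np.ndarray
    phases: dict
    frame_times: np.ndarray
    params: AcquisitionParams
    background_coeffs: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        missing = [k for k in PHASE_SET_NAMES if k not in self.phases]
        if missing:
            raise ValueError(f"missing phase sets: {missing}")
        for key in PHASE_SET_NAMES:
            arr = np.asarray(self.phases[key], dtype=float)
            if arr.shape != self.magnitude.shape:
                raise ValueError(f"phase set {key!r} shape mismatch")
            if np.any(arr < -np.pi) or np.any(arr >= np.pi):
                raise ValueError(f"phase set {key!r} not wrapped to [-pi, pi)")
            self.phases[key] = arr
        if len(self.frame_times) != self.magnitude.shape[0]:
            raise ValueError("frame_times length must match frame count")
        if self.frame_times[0] < 0 or self.frame_times[-1] >= self.params.rr_interval:
            raise ValueError("frame_times must lie in [0, rr_interval)")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self):
        return self.magnitude.shape[1:3]
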