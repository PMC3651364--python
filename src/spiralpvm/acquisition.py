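"""Acquisition constants for the retro-gated spiral PVM sequence.

The defaults describe a 13-interleave spiral sequence with bipolar velocity
encoding (venc 30 cm/s through-plane, 20 cm/s in-plane), 21 ms acquired
temporal resolution retrospectively interpolated to 60 cardiac phases, a
360 mm field of view gridded onto a 256x256 matrix (1.4 mm pixels) and a
5 mm navigator acceptance window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class AcquisitionParams:
    venc_through_plane: float = 30.0  # cm/s
    venc_in_plane: float = 20.0  # cm/s
    n_interleaves: int = 13
    spiral_readout_duration: float = 12.0  # ms
    temporal_resolution: float = 21.0  # ms
    fov: float = 360.0  # mm
    matrix_size: int = 256
    n_reconstructed_phases: int = 60
    slice_thickness: float = 8.0  # mm
    navigator_window: float = 5.0  # mm
    rr_interval: float = 1000.0  # ms

    def __post_init__(self) -> None:
        for name in (
            "venc_through_plane",
            "venc_in_plane",
            "n_interleaves",
            "spiral_readout_duration",
            "temporal_resolution",
            "fov",
            "matrix_size",
            "n_reconstructed_phases",
            "slice_thickness",
            "navigator_window",
            "rr_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.matrix_size % 2 != 0:
            raise ValueError("matrix_size must be even")

    @property
    def pixel_spacing(self) -> float:
        """Acquired in-plane pixel size (mm)."""
        return self.fov / self.matrix_size

    @property
    def k_max(self) -> float:
        """Maximum sampled spatial frequency (cycles/mm)."""
        return self.matrix_size / (2.0 * self.fov)

    @property
    def n_dummy_cycles(self) -> int:
        return 1

    @property
    def cycles_per_slice(self) -> int:
        """Cardiac cycles per slice: reference + 3 encodings, interleaved
        acquisitions on consecutive cycles, plus one dummy cycle."""
        return self.n_interleaves * 4 + self.n_dummy_cycles

    def venc(self, component: str) -> float:
        """venc for an image-coordinate velocity component ('x','y','z')."""
        if component in ("x", "y"):
            return self.venc_in_plane
        if component == "z":
            return self.venc_through_plane
        raise ValueError(f"unknown velocity component {component!r}")

    def with_(self, **kwargs) -> "AcquisitionParams":
        return replace(self, **kwargs)
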