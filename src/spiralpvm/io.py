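"""File I/O: NIfTI image series with JSON timing sidecars, contour/ground
truth JSON, trajectory CSV and tidy curve tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .cohort import ColourGrid
from .curves import VelocityTimeCurve
from .series import PHASE_SET_NAMES, EncodedSeries, VelocityFieldSeries
from .spiral import SpiralTrajectory


def _affine(pixel_spacing: float, slice_thickness: float = 8.0) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def _save_nifti(data: np.ndarray, path: Path, pixel_spacing: float) -> None:
    # frames last: NIfTI convention (x, y, 1, t)
    vol = np.moveaxis(np.asarray(data), 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(pixel_spacing)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(vol[:, :, 0, :], -1, 0)


def save_encoded_series(enc: EncodedSeries, outdir, prefix: str = "series") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = enc.params.pixel_spacing
    _save_nifti(enc.magnitude, outdir / f"{prefix}_magnitude.nii.gz", px)
    for name in PHASE_SET_NAMES:
        _save_nifti(enc.phases[name], outdir / f"{prefix}_phase_{name}.nii.gz", px)
    sidecar = {
        "frame_times_ms": list(map(float, enc.frame_times)),
        "params": dataclasses.asdict(enc.params),
    }
    if enc.background_coeffs is not None:
        sidecar["background_coeffs"] = np.asarray(enc.background_coeffs).tolist()
    (outdir / f"{prefix}_timing.json").write_text(json.dumps(sidecar, indent=1))


def load_encoded_series(outdir, prefix: str = "series") -> EncodedSeries:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{prefix}_timing.json").read_text())
    params = AcquisitionParams(**sidecar["params"])
    phases = {
        name: _load_nifti(outdir / f"{prefix}_phase_{name}.nii.gz")
        for name in PHASE_SET_NAMES
    }
    bg = sidecar.get("background_coeffs")
    return EncodedSeries(
        magnitude=_load_nifti(outdir / f"{prefix}_magnitude.nii.gz"),
        phases=phases,
        frame_times=np.asarray(sidecar["frame_times_ms"], dtype=float),
        params=params,
        background_coeffs=None if bg is None else np.asarray(bg),
    )


def save_velocity_series(
    series: VelocityFieldSeries, outdir, pixel_spacing: float, prefix: str = "velocity"
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, comp in enumerate(("x", "y", "z")):
        _save_nifti(
            series.velocities[..., i], outdir / f"{prefix}_v{comp}.nii.gz", pixel_spacing
        )
    sidecar = {
        "frame_times_ms": list(map(float, series.frame_times)),
        "rr_interval_ms": float(series.rr_interval),
    }
    (outdir / f"{prefix}_timing.json").write_text(json.dumps(sidecar, indent=1))


def load_velocity_series(outdir, prefix: str = "velocity") -> VelocityFieldSeries:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{prefix}_timing.json").read_text())
    comps = [_load_nifti(outdir / f"{prefix}_v{c}.nii.gz") for c in ("x", "y", "z")]
    return VelocityFieldSeries(
        velocities=np.stack(comps, axis=-1),
        frame_times=np.asarray(sidecar["frame_times_ms"], dtype=float),
        rr_interval=sidecar["rr_interval_ms"],
    )


def save_contours(endo, epi, landmark, path, slice_level: str = "mid") -> None:
    payload = {
        "slice_level": slice_level,
        "landmark_mm": list(map(float, landmark)),
        "endo": [np.asarray(c).tolist() for c in endo],
        "epi": [np.asarray(c).tolist() for c in epi],
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path):
    payload = json.loads(Path(path).read_text())
    endo = [np.asarray(c, dtype=float) for c in payload["endo"]]
    epi = [np.asarray(c, dtype=float) for c in payload["epi"]]
    return endo, epi, np.asarray(payload["landmark_mm"]), payload["slice_level"]


def trajectory_to_csv(traj: SpiralTrajectory, path) -> None:
    rows = []
    for j in range(traj.n_interleaves):
        rows.append(
            pd.DataFrame(
                {
                    "interleave": j,
                    "kx_cycles_per_mm": traj.kx[j],
                    "ky_cycles_per_mm": traj.ky[j],
                    "t_ms": traj.times,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def curves_to_frame(curves) -> pd.DataFrame:
    """Tidy table (region, direction, time_ms, velocity_cm_s) from curves."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "region": c.region,
                    "direction": c.direction,
                    "time_ms": c.times,
                    "velocity_cm_s": c.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_curves(df: pd.DataFrame, rr_interval: float | None = None):
    out = []
    for (region, direction), g in df.groupby(["region", "direction"], sort=False):
        out.append(
            VelocityTimeCurve(
                times=g["time_ms"].to_numpy(float),
                values=g["velocity_cm_s"].to_numpy(float),
                direction=direction,
                region=region,
                rr_interval=rr_interval,
            )
        )
    return out


def colour_grid_to_csv(grid: ColourGrid, path) -> None:
    df = pd.DataFrame(grid.values, index=grid.segment_names, columns=grid.times)
    df.index.name = "segment"
    df.to_csv(path)
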