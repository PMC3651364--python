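"""LV cylindrical geometry and regional segmentation of short-axis slices.

Image-coordinate velocities are transformed into the cylindrical system
natural to LV anatomy: longitudinal (towards the apex positive), radial
(towards the slice centre positive) and circumferential (clockwise viewed
from the apex positive). The polar axis is defined per frame by the centre
of mass of the myocardial mask and the anterior LV-RV junction landmark.
The myocardium is partitioned angularly (AHA 6/4-segment schemes and a
24 equal-angle scheme) and transmurally into thirds along 360 rays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

from .curves import DIRECTIONS, VelocityTimeCurve
from .series import VelocityFieldSeries

AHA_NAMES_6 = (
    "anterior",
    "anterolateral",
    "inferolateral",
    "inferior",
    "inferoseptal",
    "anteroseptal",
)
AHA_NAMES_4 = ("anterior", "lateral", "inferior", "septal")
LAYER_NAMES = ("endo", "mid", "epi")


def pixel_coords(grid_size: int, pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates (mm), symmetric about the grid centre.

    Returns (x, y) 2-D arrays; x runs along columns, y along rows.
    """
    c = (grid_size - 1) / 2.0
    axis = (np.arange(grid_size) - c) * pixel_spacing
    x, y = np.meshgrid(axis, axis, indexing="xy")
    return x, y


def rasterize_annulus(endo: np.ndarray, epi: np.ndarray, grid_size: int,
                      pixel_spacing: float) -> np.ndarray:
    """Boolean myocardial mask by pixel-centre point-in-polygon membership."""
    x, y = pixel_coords(grid_size, pixel_spacing)
    pts = np.column_stack([x.ravel(), y.ravel()])
    in_epi = Path(epi).contains_points(pts).reshape(x.shape)
    in_endo = Path(endo).contains_points(pts).reshape(x.shape)
    return in_epi & ~in_endo


def _radius_of_angle(polygon: np.ndarray, center: np.ndarray, ref: np.ndarray,
                     theta_query: np.ndarray) -> np.ndarray:
    """Contour radius as a function of angle about `center` (star-shaped)."""
    d = polygon - center
    perp = np.array([-ref[1], ref[0]])
    th = np.arctan2(d @ perp, d @ ref) % (2 * np.pi)
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(th)
    th, r = th[order], r[order]
    th_ext = np.concatenate([th - 2 * np.pi, th, th + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    return np.interp(theta_query, th_ext, r_ext)


@dataclass
class LVGeometry:
    endo: list
    epi: list
    landmark: np.ndarray
    slice_level: str
    grid_size: int
    pixel_spacing: float
    n_rays: int = 360
    # derived, filled by compute_geometry
    mask: np.ndarray = field(default=None, repr=False)
    center: np.ndarray = field(default=None, repr=False)
    theta: np.ndarray = field(default=None, repr=False)
    depth: np.ndarray = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.endo)

    def reference_direction(self, frame: int) -> np.ndarray:
        d = np.asarray(self.landmark, dtype=float) - self.center[frame]
        return d / np.hypot(*d)

    def unit_vectors(self, frame: int):
        """Outward radial and clockwise-from-apex tangential unit vectors."""
        x, y = pixel_coords(self.grid_size, self.pixel_spacing)
        dx = x - self.center[frame, 0]
        dy = y - self.center[frame, 1]
        r = np.hypot(dx, dy)
        r = np.where(r == 0, np.nan, r)
        rx, ry = dx / r, dy / r
        return rx, ry, ry, -rx  # rhat_x, rhat_y, chat_x, chat_y


def compute_geometry(
    endo_contours,
    epi_contours,
    landmark,
    grid_size: int,
    pixel_spacing: float,
    slice_level: str = "mid",
    n_rays: int = 360,
) -> LVGeometry:
    """Rasterize contours and build the per-frame polar coordinate fields.

    The angular coordinate theta runs from the anterior LV-RV junction
    (theta = 0) towards the lateral wall; transmural depth is 0 at the
    endocardium and 1 at the epicardium, assigned by the nearest of
    ``n_rays`` equally spaced endo-epi rays.
    """
    endo_contours = [np.asarray(c, dtype=float) for c in endo_contours]
    epi_contours = [np.asarray(c, dtype=float) for c in epi_contours]
    if len(endo_contours) != len(epi_contours):
        raise ValueError("endo and epi contour lists differ in length")
    n_frames = len(endo_contours)
    landmark = np.asarray(landmark, dtype=float)

    mask = np.zeros((n_frames, grid_size, grid_size), dtype=bool)
    center = np.zeros((n_frames, 2))
    theta = np.full((n_frames, grid_size, grid_size), np.nan)
    depth = np.full((n_frames, grid_size, grid_size), np.nan)
    x, y = pixel_coords(grid_size, pixel_spacing)

    ray_angles = np.arange(n_rays) * 2 * np.pi / n_rays
    for f in range(n_frames):
        m = rasterize_annulus(endo_contours[f], epi_contours[f], grid_size, pixel_spacing)
        if not m.any():
            raise ValueError(f"empty myocardial mask at frame {f}")
        cx = float(x[m].mean())
        cy = float(y[m].mean())
        center[f] = (cx, cy)
        if not Path(endo_contours[f]).contains_point((cx, cy)):
            raise ValueError(f"centre of mass outside endocardium at frame {f}")
        ref = landmark - center[f]
        ref = ref / np.hypot(*ref)
        perp = np.array([-ref[1], ref[0]])

        r_endo_ray = _radius_of_angle(endo_contours[f], center[f], ref, ray_angles)
        r_epi_ray = _radius_of_angle(epi_contours[f], center[f], ref, ray_angles)
        thickness = r_epi_ray - r_endo_ray
        if np.any(thickness <= 0):
            raise ValueError(
                f"non-nested contours (zero or negative wall thickness) at frame {f}"
            )

        dx = x - cx
        dy = y - cy
        r = np.hypot(dx, dy)
        m &= r > 1e-9  # a pixel coinciding with the centre has no angle
        th = np.arctan2(dx * perp[0] + dy * perp[1], dx * ref[0] + dy * ref[1])
        th = th % (2 * np.pi)
        ray_idx = np.rint(th / (2 * np.pi / n_rays)).astype(int) % n_rays
        d = (r - r_endo_ray[ray_idx]) / thickness[ray_idx]
        theta[f][m] = th[m]
        depth[f][m] = np.clip(d[m], 0.0, 1.0)
        mask[f] = m

    return LVGeometry(
        endo=endo_contours,
        epi=epi_contours,
        landmark=landmark,
        slice_level=slice_level,
        grid_size=grid_size,
        pixel_spacing=pixel_spacing,
        n_rays=n_rays,
        mask=mask,
        center=center,
        theta=theta,
        depth=depth,
    )


def erode_geometry_mask(geom: LVGeometry, iterations: int = 1) -> LVGeometry:
    """Copy of the geometry with the myocardial mask eroded per frame.

    A one-pixel boundary guard keeps partial-volume pixels — whose
    reconstructed velocity blends myocardium with blood pool or background
    across the moving contour — out of regional averages.
    """
    if iterations < 1:
        return geom
    from scipy.ndimage import binary_erosion

    new_mask = np.stack(
        [binary_erosion(geom.mask[f], iterations=iterations)
         for f in range(geom.n_frames)]
    )
    if not new_mask.reshape(geom.n_frames, -1).any(axis=1).all():
        raise ValueError("mask erosion emptied the myocardium in some frame")
    out = LVGeometry(
        endo=geom.endo,
        epi=geom.epi,
        landmark=geom.landmark,
        slice_level=geom.slice_level,
        grid_size=geom.grid_size,
        pixel_spacing=geom.pixel_spacing,
        n_rays=geom.n_rays,
        mask=new_mask,
        center=geom.center,
        theta=geom.theta,
        depth=geom.depth,
    )
    return out


# ---------------------------------------------------------------------------
# cylindrical decomposition
# ---------------------------------------------------------------------------

@dataclass
class CylindricalSeries:
    """Per-pixel (v_long, v_rad, v_circ) series on the myocardial mask."""

    v_long: np.ndarray
    v_rad: np.ndarray
    v_circ: np.ndarray
    frame_times: np.ndarray
    rr_interval: float
    geometry: LVGeometry

    def component(self, direction: str) -> np.ndarray:
        return {
            "longitudinal": self.v_long,
            "radial": self.v_rad,
            "circumferential": self.v_circ,
        }[direction]


def to_cylindrical(field: VelocityFieldSeries, geom: LVGeometry) -> CylindricalSeries:
    """Resolve image-coordinate velocities into the LV cylindrical system.

    Longitudinal is +vz (towards apex positive), radial is positive towards
    the per-frame centre, circumferential is positive clockwise as viewed
    from the apex.
    """
    if field.n_frames != geom.n_frames:
        raise ValueError("geometry frames must match field frames")
    shape = (field.n_frames, geom.grid_size, geom.grid_size)
    if field.velocities.shape[:3] != shape:
        raise ValueError("field grid does not match geometry grid")
    v_long = np.zeros(shape)
    v_rad = np.zeros(shape)
    v_circ = np.zeros(shape)
    for f in range(field.n_frames):
        rx, ry, cx, cy = geom.unit_vectors(f)
        m = geom.mask[f]
        vx = field.velocities[f, :, :, 0]
        vy = field.velocities[f, :, :, 1]
        v_long[f][m] = field.velocities[f, :, :, 2][m]
        v_rad[f][m] = -(vx * rx + vy * ry)[m]
        v_circ[f][m] = (vx * cx + vy * cy)[m]
    return CylindricalSeries(
        v_long=v_long,
        v_rad=v_rad,
        v_circ=v_circ,
        frame_times=np.asarray(field.frame_times, dtype=float),
        rr_interval=field.rr_interval,
        geometry=geom,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentModel:
    scheme: str
    names: tuple
    labels: np.ndarray  # (frames, rows, cols) int; -1 outside the myocardium

    @property
    def n_segments(self) -> int:
        return len(self.names)

    def segment_mask(self, segment) -> np.ndarray:
        idx = self.names.index(segment) if isinstance(segment, str) else int(segment)
        return self.labels == idx


def assign_segments(geom: LVGeometry, scheme: str = "aha") -> SegmentModel:
    """Angular segmentation with half-open bins [a, b) starting at theta=0."""
    if scheme == "aha":
        names = AHA_NAMES_4 if geom.slice_level == "apical" else AHA_NAMES_6
    elif scheme == "equal24":
        names = tuple(f"seg{i + 1:02d}" for i in range(24))
    else:
        raise ValueError(f"unknown segmentation scheme {scheme!r}")
    width = 2 * np.pi / len(names)
    labels = np.full(geom.theta.shape, -1, dtype=int)
    valid = geom.mask
    labels[valid] = np.minimum(
        (geom.theta[valid] // width).astype(int), len(names) - 1
    )
    return SegmentModel(scheme=scheme, names=names, labels=labels)


def assign_layers(geom: LVGeometry) -> np.ndarray:
    """Transmural thirds: 0=endo [0,1/3), 1=mid [1/3,2/3), 2=epi [2/3,1]."""
    labels = np.full(geom.depth.shape, -1, dtype=int)
    m = geom.mask
    d = geom.depth
    labels[m & (d < 1.0 / 3.0)] = 0
    labels[m & (d >= 1.0 / 3.0) & (d < 2.0 / 3.0)] = 1
    labels[m & (d >= 2.0 / 3.0)] = 2
    return labels


def region_mask(
    geom: LVGeometry,
    segments: SegmentModel | None = None,
    segment=None,
    layers: np.ndarray | None = None,
    layer: str | None = None,
) -> np.ndarray:
    """Boolean (frames, rows, cols) mask for a segment/layer/global region."""
    m = geom.mask.copy()
    if segment is not None:
        if segments is None:
            raise ValueError("segment requested but no SegmentModel given")
        m &= segments.segment_mask(segment)
    if layer is not None:
        if layers is None:
            raise ValueError("layer requested but no layer labels given")
        m &= layers == LAYER_NAMES.index(layer)
    return m


def region_average(
    cyl: CylindricalSeries,
    segments: SegmentModel | None = None,
    segment=None,
    layers: np.ndarray | None = None,
    layer: str | None = None,
    region_label: str | None = None,
) -> dict:
    """Unweighted per-frame pixel mean over a region, one curve per direction."""
    m = region_mask(cyl.geometry, segments, segment, layers, layer)
    counts = m.reshape(m.shape[0], -1).sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("empty region in at least one frame")
    if region_label is None:
        parts = []
        if segment is not None:
            parts.append(str(segment) if isinstance(segment, str)
                         else segments.names[int(segment)])
        if layer is not None:
            parts.append(layer)
        region_label = "/".join(parts) if parts else "global"
    out = {}
    for direction in DIRECTIONS:
        comp = cyl.component(direction)
        vals = np.array(
            [comp[f][m[f]].mean() for f in range(m.shape[0])]
        )
        out[direction] = VelocityTimeCurve(
            times=cyl.frame_times,
            values=vals,
            direction=direction,
            region=region_label,
            rr_interval=cyl.rr_interval,
        )
    return out
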