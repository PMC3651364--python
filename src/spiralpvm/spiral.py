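"""Interleaved spiral trajectory design and gridding reconstruction.

K-space is covered by uniformly rotated Archimedean spiral interleaves
sampled uniformly in arc length out to k_max = matrix/(2*FOV). The forward
model (`sample_kspace`) is an exact direct discrete Fourier sum used as an
oracle; `grid_reconstruct` implements standard density-compensated
convolution gridding with a Kaiser-Bessel kernel on a 2x oversampled grid,
deapodization and cropping. `zero_fill_interpolate` doubles the image grid
by symmetric zero padding of k-space (sinc interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift
from scipy.special import i0

from .acquisition import AcquisitionParams

KERNEL_WIDTH = 4  # grid cells, on the oversampled grid
OVERSAMPLE = 2


@dataclass
class SpiralTrajectory:
    """Per-interleave k-space coordinates (cycles/mm) and sample times (ms)."""

    kx: np.ndarray  # (n_interleaves, n_samples)
    ky: np.ndarray
    times: np.ndarray  # (n_samples,), shared by all interleaves
    k_max: float
    fov: float

    @property
    def n_interleaves(self) -> int:
        return self.kx.shape[0]

    @property
    def n_samples(self) -> int:
        return self.kx.shape[1]

    def flat(self):
        return self.kx.ravel(), self.ky.ravel()


def _archimedean_arc(n_turns: float, n_samples: int):
    """tau values giving uniform arc-length sampling of r = tau, phi = 2*pi*n*tau."""
    tau_fine = np.linspace(0.0, 1.0, 50 * n_samples)
    phi = 2 * np.pi * n_turns * tau_fine
    # ds/dtau for r = tau (unit outer radius)
    ds = np.sqrt(1.0 + phi**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(tau_fine))])
    s_targets = np.linspace(0.0, s[-1], n_samples)
    return np.interp(s_targets, s, tau_fine)


def design_trajectory(
    params: AcquisitionParams = AcquisitionParams(),
    samples_per_interleave: int = 1024,
) -> SpiralTrajectory:
    """Idealized constant-angular-density Archimedean spiral interleaf set.

    The number of turns per interleave, matrix/(2*n_interleaves), makes the
    radial spacing of adjacent arms 1/FOV so the stated FOV is fully
    sampled; interleaves are uniform rotations of one another and each
    starts at k = 0.
    """
    n_turns = params.matrix_size / (2.0 * params.n_interleaves)
    tau = _archimedean_arc(n_turns, samples_per_interleave)
    r = params.k_max * tau
    phi = 2 * np.pi * n_turns * tau
    base = r * np.exp(1j * phi)
    rot = np.exp(2j * np.pi * np.arange(params.n_interleaves) / params.n_interleaves)
    k = rot[:, None] * base[None, :]
    times = np.linspace(0.0, params.spiral_readout_duration, samples_per_interleave)
    return SpiralTrajectory(
        kx=k.real.copy(), ky=k.imag.copy(), times=times, k_max=params.k_max,
        fov=params.fov,
    )


# ---------------------------------------------------------------------------
# forward model (oracle) and exact adjoint
# ---------------------------------------------------------------------------

def _image_coords(n: int, pixel_spacing: float):
    axis = (np.arange(n) - n // 2) * pixel_spacing
    x, y = np.meshgrid(axis, axis, indexing="xy")
    return x.ravel(), y.ravel()


def sample_kspace(
    image: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
    pixel_spacing: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Exact direct DFT of `image` at arbitrary k-space coordinates."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    x, y = _image_coords(image.shape[0], pixel_spacing)
    img = image.ravel().astype(complex)
    kx = np.asarray(kx, dtype=float).ravel()
    ky = np.asarray(ky, dtype=float).ravel()
    out = np.empty(len(kx), dtype=complex)
    for i in range(0, len(kx), chunk):
        sl = slice(i, i + chunk)
        phase = np.exp(-2j * np.pi * (np.outer(kx[sl], x) + np.outer(ky[sl], y)))
        out[sl] = phase @ img
    return out


def adjoint_sample(
    kdata: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
    n: int,
    pixel_spacing: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Exact adjoint of `sample_kspace` (conjugate-transposed Fourier sum)."""
    x, y = _image_coords(n, pixel_spacing)
    kdata = np.asarray(kdata, dtype=complex).ravel()
    kx = np.asarray(kx, dtype=float).ravel()
    ky = np.asarray(ky, dtype=float).ravel()
    out = np.zeros(n * n, dtype=complex)
    for i in range(0, len(kx), chunk):
        sl = slice(i, i + chunk)
        phase = np.exp(2j * np.pi * (np.outer(x, kx[sl]) + np.outer(y, ky[sl])))
        out += phase @ kdata[sl]
    return out.reshape(n, n)


# ---------------------------------------------------------------------------
# Kaiser-Bessel gridding
# ---------------------------------------------------------------------------

def _kb_beta(width: int = KERNEL_WIDTH, os: float = OVERSAMPLE) -> float:
    return np.pi * np.sqrt((width**2 / os**2) * (os - 0.5) ** 2 - 0.8)


def _kb_kernel(d: np.ndarray, beta: float, width: int = KERNEL_WIDTH) -> np.ndarray:
    inside = np.abs(d) <= width / 2.0
    arg = 1.0 - (2.0 * d / width) ** 2
    arg = np.where(inside, np.clip(arg, 0.0, None), 0.0)
    return np.where(inside, i0(beta * np.sqrt(arg)), 0.0)


def _kb_deapodize(n_os: int, beta: float, width: int = KERNEL_WIDTH) -> np.ndarray:
    """Continuous FT of the KB kernel on image positions (1-D profile)."""
    p = np.arange(n_os) - n_os // 2
    f = p / n_os  # cycles per grid unit
    arg = beta**2 - (np.pi * width * f) ** 2
    out = np.where(
        arg > 0,
        np.sinh(np.sqrt(np.abs(arg))) / np.sqrt(np.abs(arg)),
        np.sinc(np.sqrt(np.abs(arg)) / np.pi),
    )
    return out


def _grid_degrid(values, u, v, g, beta):
    """Convolve sample weights with the gridding kernel and read back at the
    sample positions (one step of iterative density estimation)."""
    grid = np.zeros((g, g))
    base_u = np.floor(u).astype(int)
    base_v = np.floor(v).astype(int)
    half = KERNEL_WIDTH // 2
    taps = []
    for du in range(-half + 1, half + 1):
        wu = _kb_kernel(base_u + du - u, beta)
        iu = np.mod(base_u + du, g)
        for dv in range(-half + 1, half + 1):
            wv = _kb_kernel(base_v + dv - v, beta)
            iv = np.mod(base_v + dv, g)
            taps.append((iu, iv, wu * wv))
            np.add.at(grid, (iv, iu), values * wu * wv)
    out = np.zeros_like(values)
    for iu, iv, wuv in taps:
        out += grid[iv, iu] * wuv
    return out


def _density_weights(
    kx, ky, matrix_size: int, pixel_spacing: float, beta: float, n_iter: int = 10
) -> np.ndarray:
    """Iterative sample-density compensation (Pipe-Menon style).

    Weights are refined so that the kernel-convolved weighted sampling
    density is flat; this adapts to the uniform-arc-length spiral, whose
    density is constant over most of k-space but elevated where the arms
    converge at the centre.
    """
    g = OVERSAMPLE * matrix_size
    u = np.asarray(kx).ravel() * (matrix_size * pixel_spacing) * OVERSAMPLE + g // 2
    v = np.asarray(ky).ravel() * (matrix_size * pixel_spacing) * OVERSAMPLE + g // 2
    w = np.ones(u.shape)
    for _ in range(n_iter):
        dens = _grid_degrid(w, u, v, g, beta)
        w = w / np.maximum(dens, 1e-12)
    return w


def _grid_adjoint(kdata, kx, ky, matrix_size, pixel_spacing, beta):
    g = OVERSAMPLE * matrix_size
    grid = np.zeros((g, g), dtype=complex)
    # k in oversampled grid units from the grid centre
    u = kx * (matrix_size * pixel_spacing) * OVERSAMPLE + g // 2
    v = ky * (matrix_size * pixel_spacing) * OVERSAMPLE + g // 2
    base_u = np.floor(u).astype(int)
    base_v = np.floor(v).astype(int)
    half = KERNEL_WIDTH // 2
    for du in range(-half + 1, half + 1):
        wu = _kb_kernel(base_u + du - u, beta)
        iu = np.mod(base_u + du, g)
        for dv in range(-half + 1, half + 1):
            wv = _kb_kernel(base_v + dv - v, beta)
            iv = np.mod(base_v + dv, g)
            np.add.at(grid, (iv, iu), kdata * wu * wv)
    img = fftshift(ifft2(ifftshift(grid))) * g * g
    deap = _kb_deapodize(g, beta)
    img = img / np.outer(deap, deap)
    lo = (g - matrix_size) // 2
    return img[lo : lo + matrix_size, lo : lo + matrix_size]


def _dirichlet(k: np.ndarray, n: int, dx: float) -> np.ndarray:
    """Closed-form 1-D DFT of an all-ones image row at frequency k."""
    k = np.asarray(k, dtype=float)
    z = np.exp(-2j * np.pi * k * dx)
    num = 1.0 - z**n
    den = 1.0 - z
    small = np.abs(den) < 1e-12
    ratio = np.where(small, n, num / np.where(small, 1.0, den))
    # phase reference at the centred pixel x = -n//2 * dx
    return ratio * np.exp(2j * np.pi * k * dx * (n // 2))


def grid_reconstruct(
    kdata: np.ndarray,
    traj: SpiralTrajectory,
    matrix_size: int,
    pixel_spacing: float | None = None,
) -> np.ndarray:
    """Density-compensated Kaiser-Bessel gridding reconstruction.

    The operator is normalized against the analytic spiral samples of a
    unit constant image, so extended objects reconstruct at their true
    intensity (an impulse calibration would be biased by the unsampled
    k-space corners).
    """
    kdata = np.asarray(kdata, dtype=complex).ravel()
    kx, ky = traj.flat()
    if kdata.size == 0:
        raise ValueError("empty k-space data")
    if kdata.shape != kx.shape:
        raise ValueError("kdata length does not match trajectory samples")
    if pixel_spacing is None:
        pixel_spacing = traj.fov / matrix_size
    beta = _kb_beta()
    w = _density_weights(kx, ky, matrix_size, pixel_spacing, beta)
    img = _grid_adjoint(kdata * w, kx, ky, matrix_size, pixel_spacing, beta)
    s_const = _dirichlet(kx, matrix_size, pixel_spacing) * _dirichlet(
        ky, matrix_size, pixel_spacing
    )
    ref = _grid_adjoint(s_const * w, kx, ky, matrix_size, pixel_spacing, beta)
    c = matrix_size // 2
    scale = ref[c - 2 : c + 3, c - 2 : c + 3].real.mean()
    return img / scale


def zero_fill_interpolate(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Sinc interpolation by symmetric zero padding of k-space.

    Output pixel pitch is input pitch / factor; original sample values are
    reproduced exactly at the original grid positions.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return np.asarray(image).copy()
    image = np.asarray(image)
    n = image.shape[0]
    k = fftshift(fft2(ifftshift(image)))
    g = factor * n
    pad = np.zeros((g, g), dtype=complex)
    lo = (g - n) // 2
    pad[lo : lo + n, lo : lo + n] = k
    out = fftshift(ifft2(ifftshift(pad))) * factor**2
    if np.isrealobj(image):
        out = out.real
    return out
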