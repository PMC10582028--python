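"""Tomographic reconstruction: weighted back-projection, Fourier-crop binning,
direct per-particle reconstruction from projections, and anisotropic-diffusion
denoising.

Slab geometry: the tomogram x and y axes coincide with the image axes at zero
tilt, z is the thickness direction, and the rotation center is the volume
center.  Tilt is about y.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .errors import TomopipeError
from .ctf import CtfParams, phase_flip, particle_defocus
from .simulator import TiltSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Tomogram",
    "wbp_reconstruct",
    "fourier_crop",
    "reconstruct_particle",
    "nad_denoise",
]


@dataclass
class Tomogram:
    """Reconstructed density volume with voxel size and provenance."""

    volume: np.ndarray  # [x, y, z]
    voxel_size: float  # Angstrom
    binning: int = 1
    provenance: dict = field(default_factory=dict)

    @property
    def thickness(self) -> int:
        return self.volume.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape


def _ramp_filter_stack(images: np.ndarray, filter_name: str) -> np.ndarray:
    """1D filter each image along x (perpendicular to the y tilt axis).

    Images are zero-padded to twice their width before filtering so the ramp's
    long-range kernel does not wrap around circularly.
    """
    if filter_name == "none":
        return images.astype(np.float64, copy=True)
    n = images.shape[1]
    n_pad = sfft.next_fast_len(2 * n)
    k = np.abs(np.fft.fftfreq(n_pad))
    if filter_name == "ramp":
        h = k
    elif filter_name == "ramp*hamming":
        h = k * (0.54 + 0.46 * np.cos(np.pi * np.minimum(k / 0.5, 1.0)))
    else:
        raise TomopipeError(f"unknown WBP filter '{filter_name}' "
                            "(choose ramp, ramp*hamming, none)")
    padded = np.zeros((images.shape[0], n_pad, images.shape[2]))
    lo = (n_pad - n) // 2
    padded[:, lo:lo + n, :] = images
    spec = sfft.fft(padded, axis=1)
    out = np.real(sfft.ifft(spec * h[None, :, None], axis=1))
    out = np.ascontiguousarray(out[:, lo:lo + n, :])
    # the ramp has zero DC response: enforce it exactly per filtered line
    # (cropping the padded result leaves a small residual otherwise)
    out -= out.mean(axis=1, keepdims=True)
    return out


def _backproject(filtered: np.ndarray, tilt_angles: np.ndarray,
                 out_shape: tuple[int, int, int],
                 center_offset: np.ndarray | None = None) -> np.ndarray:
    """Voxel-driven gathering back-projection (linear interpolation along x).

    Tilt about y keeps the y coordinate fixed, so each voxel (x, y, z) samples
    image i at (u, y) with u = cx + (x-cx) cos t + (z-cz) sin t.  An optional
    ``center_offset`` shifts the reconstruction center in image coordinates
    (used for particle reconstruction from substack windows).
    """
    nx_out, ny_out, nz_out = out_shape
    nx_img = filtered.shape[1]
    cx_out = (nx_out - 1) / 2.0
    cz_out = (nz_out - 1) / 2.0
    cx_img = (nx_img - 1) / 2.0
    if center_offset is None:
        center_offset = np.zeros(len(tilt_angles))
    xs = np.arange(nx_out) - cx_out
    zs = np.arange(nz_out) - cz_out
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    out = np.zeros(out_shape, dtype=np.float64)
    for i, angle in enumerate(tilt_angles):
        theta = np.radians(angle)
        u = cx_img + center_offset[i] + X * np.cos(theta) + Z * np.sin(theta)
        u0 = np.floor(u).astype(int)
        frac = u - u0
        valid = (u0 >= -1) & (u0 <= nx_img - 1)
        u0c = np.clip(u0, 0, nx_img - 1)
        u1c = np.clip(u0 + 1, 0, nx_img - 1)
        w0 = np.where((u0 >= 0) & valid, 1.0 - frac, 0.0)
        w1 = np.where((u0 + 1 <= nx_img - 1) & valid, frac, 0.0)
        img = filtered[i]
        # gather: out[x, :, z] += w0 * img[u0, :] + w1 * img[u1, :]
        out += (img[u0c.ravel(), :].reshape(nx_out, nz_out, -1) *
                w0[..., None]).transpose(0, 2, 1) + \
               (img[u1c.ravel(), :].reshape(nx_out, nz_out, -1) *
                w1[..., None]).transpose(0, 2, 1)
    return out * (np.pi / (2.0 * max(len(tilt_angles), 1)))


def wbp_reconstruct(tilt_series: TiltSeries, thickness: int,
                    filter_name: str = "ramp*hamming") -> Tomogram:
    """Weighted back-projection of an aligned tilt series into a slab tomogram."""
    if len(tilt_series) == 1:
        warnings.warn("single-image stack: reconstruction is a smeared volume")
    filtered = _ramp_filter_stack(tilt_series.images, filter_name)
    nx, ny = tilt_series.images.shape[1:3]
    volume = _backproject(filtered, tilt_series.tilt_angles, (nx, ny, thickness))
    return Tomogram(volume=volume.astype(np.float32),
                    voxel_size=tilt_series.pixel_size,
                    binning=1,
                    provenance={"filter": filter_name,
                                "tilt_angles": tilt_series.tilt_angles.tolist(),
                                "ctf_corrected": False})


def fourier_crop(data: np.ndarray, factor: int, stack: bool = False) -> np.ndarray:
    """Bin by Fourier cropping (centered window); the mean is preserved exactly.

    ``factor`` must be a positive power of two not exceeding any binned axis.
    With ``stack=True`` the first axis indexes images and only the trailing two
    axes are cropped.
    """
    if factor < 1 or factor & (factor - 1):
        raise TomopipeError(f"binning factor must be a positive power of 2, got {factor}")
    if factor == 1:
        return np.asarray(data).copy()
    data = np.asarray(data, dtype=float)
    axes = tuple(range(1, data.ndim)) if stack else tuple(range(data.ndim))
    for ax in axes:
        if data.shape[ax] // factor < 1:
            raise TomopipeError(f"factor {factor} exceeds axis {ax} of size "
                                f"{data.shape[ax]}")
    spec = sfft.fftshift(sfft.fftn(data, axes=axes), axes=axes)
    slices = [slice(None)] * data.ndim
    n_in = n_out = 1
    for ax in axes:
        size = data.shape[ax]
        new = size // factor
        lo = size // 2 - new // 2
        slices[ax] = slice(lo, lo + new)
        n_in *= size
        n_out *= new
    cropped = spec[tuple(slices)]
    out = sfft.ifftn(sfft.ifftshift(cropped, axes=axes), axes=axes)
    return np.real(out) * (n_out / n_in)


def reconstruct_particle(tilt_series: TiltSeries, position: np.ndarray, box: int,
                         ctf_params: CtfParams | None = None,
                         per_particle_ctf: bool | None = None,
                         thickness: int | None = None,
                         filter_name: str = "ramp*hamming",
                         handedness: int = 1,
                         binning: int = 1,
                         context_pad: int | None = None) -> np.ndarray | None:
    """Reconstruct one subtomogram directly from the projections.

    ``position`` is the 0-based voxel position in the tomogram frame (the frame
    of :func:`wbp_reconstruct` with the given ``thickness``).  For each tilt the
    particle's projected image location is computed from the tilt geometry, a
    padded window is cut, optionally phase-flipped at the particle's own
    height-dependent defocus, ramp-filtered, and back-projected into a ``box``^3
    volume.  Returns ``None`` (with a logged reason) when the projected window
    falls off any image.

    Per-particle CTF correction defaults to on for binning < 4 and off
    otherwise, where its effect is negligible.
    """
    if per_particle_ctf is None:
        per_particle_ctf = binning < 4
        logger.info("per-particle CTF defaulted to %s at binning %d",
                    per_particle_ctf, binning)
    nx_img, ny_img = tilt_series.images.shape[1:3]
    nz = thickness if thickness is not None else nx_img
    center = np.array([(nx_img - 1) / 2.0, (ny_img - 1) / 2.0, (nz - 1) / 2.0])
    rel = np.asarray(position, dtype=float) - center
    # margin so the ramp filter sees context around the particle
    pad = 2 * box if context_pad is None else context_pad
    win = box + 2 * pad
    images = np.empty((len(tilt_series), win, ny_img), dtype=np.float64)
    u_offsets = np.empty(len(tilt_series))
    y0 = int(round(rel[1] + (ny_img - 1) / 2.0))

    for i, angle in enumerate(tilt_series.tilt_angles):
        theta = np.radians(angle)
        u = (nx_img - 1) / 2.0 + rel[0] * np.cos(theta) + rel[2] * np.sin(theta)
        ui = int(round(u))
        lo = ui - win // 2
        hi = lo + win
        core_off = (ui - box // 2 < 0 or ui + box - box // 2 > nx_img or
                    y0 - box // 2 < 0 or y0 + box - box // 2 > ny_img)
        if core_off:
            logger.warning("particle at %s: window off image at tilt %.1f deg; skipped",
                           np.round(position, 1).tolist(), angle)
            return None
        # zero-fill where only the filter-context margin runs off the image
        window = np.zeros((win, ny_img), dtype=np.float64)
        src_lo, src_hi = max(lo, 0), min(hi, nx_img)
        window[src_lo - lo:src_hi - lo, :] = \
            tilt_series.images[i, src_lo:src_hi, :]
        if per_particle_ctf and ctf_params is not None:
            dz = particle_defocus(float(tilt_series.defocus[i]),
                                  rel[2] * np.cos(theta) - rel[0] * np.sin(theta),
                                  tilt_series.pixel_size, handedness)
            window = phase_flip(window, ctf_params.with_defocus(dz))
        images[i] = window
        u_offsets[i] = u - ui  # sub-voxel residual of the window centering

    filtered = _ramp_filter_stack(images, filter_name)
    ylo = y0 - box // 2
    sub = filtered[:, :, ylo:ylo + box]
    vol = _backproject(sub, tilt_series.tilt_angles, (box, box, box),
                       center_offset=u_offsets)
    return vol.astype(np.float32)


def nad_denoise(volume: np.ndarray, kappa: float, n_iterations: int,
                dt: float = 0.1) -> np.ndarray:
    """Edge-stopping (Perona-Malik) diffusion, conservative explicit scheme.

    The diffusivity is g(|grad|) = 1 / (1 + (|grad| / kappa)^2); fluxes are
    differenced so the total voxel sum is conserved.  ``dt`` must not exceed
    the 3D explicit-stability bound 0.15.
    """
    if n_iterations < 0:
        raise TomopipeError("n_iterations must be >= 0")
    if dt > 0.15 or dt <= 0:
        raise TomopipeError(f"dt={dt} outside the stable range (0, 0.15] for 3D")
    out = np.asarray(volume, dtype=np.float64).copy()
    for _ in range(n_iterations):
        total = np.zeros_like(out)
        for axis in range(out.ndim):
            grad = np.diff(out, axis=axis)  # face-centered forward difference
            g = 1.0 / (1.0 + (grad / kappa) ** 2)
            flux = g * grad
            pad = [(0, 0)] * out.ndim
            pad[axis] = (1, 1)
            flux = np.pad(flux, pad)  # zero-flux boundaries
            total += np.diff(flux, axis=axis)
        out += dt * total
    return out
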