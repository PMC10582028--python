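"""Contrast transfer function: evaluation, phase flipping, per-particle defocus,
and a 1D rotational-average defocus estimator.

Sign convention: defocus is in micrometers, positive = underfocus, everywhere in
the package.  Negative input defocus (the acquisition-software convention) is
normalized on construction with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft
from scipy.optimize import brentq

from .errors import EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "CtfParams",
    "electron_wavelength",
    "ctf_value",
    "apply_ctf",
    "phase_flip",
    "particle_defocus",
    "estimate_defocus",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


@dataclass(frozen=True)
class CtfParams:
    """Microscope and defocus parameters.

    voltage in kV; spherical aberration in mm; amplitude contrast as a fraction;
    defocus in um (positive underfocus); pixel size in Angstrom.
    """

    voltage: float = 300.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.07
    defocus: float = 3.0
    pixel_size: float = 1.0
    phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise EstimationError("voltage must be > 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise EstimationError("amplitude_contrast must be in [0, 1]")
        if not self.pixel_size > 0:
            raise EstimationError("pixel_size must be > 0")
        if self.defocus < 0:
            logger.info("negative defocus %.3f um normalized to positive-underfocus "
                        "convention", self.defocus)
            object.__setattr__(self, "defocus", -self.defocus)

    def with_defocus(self, defocus_um: float) -> "CtfParams":
        return replace(self, defocus=abs(defocus_um))


def _aberration_phase(params: CtfParams, freq: np.ndarray) -> np.ndarray:
    """chi(f): defocus + spherical-aberration phase, radians; freq in 1/A."""
    lam = electron_wavelength(params.voltage)
    dz = params.defocus * 1e4  # um -> A
    cs = params.spherical_aberration * 1e7  # mm -> A
    f2 = np.asarray(freq, dtype=float) ** 2
    return (np.pi * lam * dz * f2 - 0.5 * np.pi * cs * lam ** 3 * f2 * f2
            + params.phase_shift)


def ctf_value(params: CtfParams, spatial_frequency: np.ndarray) -> np.ndarray:
    """CTF(f) = -sqrt(1-A^2) sin(chi) - A cos(chi); vectorizes over any grid."""
    chi = _aberration_phase(params, spatial_frequency)
    a = params.amplitude_contrast
    return -np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)


def first_zero(params: CtfParams, f_max: float | None = None) -> float:
    """First positive frequency where the CTF crosses zero (1/A), by root finding."""
    if f_max is None:
        f_max = 0.5 / params.pixel_size
    f = np.linspace(1e-6, f_max, 4000)
    vals = ctf_value(params, f)
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise EstimationError("no CTF zero below the requested frequency")
    i = sign_change[0]
    return brentq(lambda x: ctf_value(params, x), f[i], f[i + 1])


def _freq_grid_2d(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    fx = np.fft.fftfreq(shape[0], d=pixel_size)
    fy = np.fft.rfftfreq(shape[1], d=pixel_size)
    return np.hypot(fx[:, None], fy[None, :])


def apply_ctf(image: np.ndarray, params: CtfParams) -> np.ndarray:
    """Multiply the image spectrum by the CTF (forward model for simulation)."""
    freq = _freq_grid_2d(image.shape, params.pixel_size)
    spec = sfft.rfft2(image)
    return sfft.irfft2(spec * ctf_value(params, freq), s=image.shape)


def phase_flip(image: np.ndarray, params: CtfParams,
               tilt_deg: float | None = None,
               strip_width: int = 256, handedness: int = 1) -> np.ndarray:
    """Phase-flip CTF correction: invert the sign of Fourier components where
    the CTF is negative.  The amplitude spectrum is untouched.

    With ``tilt_deg`` given, the image is corrected in overlapping strips
    perpendicular to the tilt axis (the y/second axis): each strip gets the
    defocus at its distance from the tilt axis, ``defocus + handedness * d *
    tan(tilt)``, blended with 50%-overlap cosine weights.
    """
    image = np.asarray(image, dtype=float)
    if tilt_deg is None or abs(tilt_deg) < 1e-9:
        return _phase_flip_constant(image, params)
    nx = image.shape[0]
    cx = (nx - 1) / 2.0
    half = max(strip_width // 2, 8)
    centers = np.arange(half // 2, nx + half // 2, half)
    out = np.zeros_like(image)
    weight = np.zeros(nx)
    tan_t = np.tan(np.radians(tilt_deg))
    for center in centers:
        lo = max(0, int(center) - half)
        hi = min(nx, int(center) + half)
        if hi <= lo:
            continue
        d_off = (center - cx) * params.pixel_size * tan_t * 1e-4  # A -> um
        local = params.with_defocus(params.defocus + handedness * d_off)
        corrected = _phase_flip_constant(image[lo:hi, :], local)
        w = np.hanning(hi - lo) + 1e-3
        out[lo:hi, :] += corrected * w[:, None]
        weight[lo:hi] += w
    return out / weight[:, None]


def _phase_flip_constant(image: np.ndarray, params: CtfParams) -> np.ndarray:
    freq = _freq_grid_2d(image.shape, params.pixel_size)
    vals = ctf_value(params, freq)
    sign = np.where(vals < 0.0, -1.0, 1.0)
    if np.all(vals <= 0.0) or np.all(vals >= 0.0):
        # constant CTF sign across the band (first zero beyond Nyquist):
        # there is no contrast inversion to correct
        return image.copy()
    return sfft.irfft2(sfft.rfft2(image) * sign, s=image.shape)


def particle_defocus(global_defocus: float, z_offset: float, pixel_size: float,
                     handedness: int = 1) -> float:
    """Defocus at a particle's height: global + handedness * z_offset * pixel (um).

    ``z_offset`` in voxels relative to the tomogram mid-plane; ``handedness``
    is +/-1 and surfaced explicitly because the sign is dataset-dependent.
    """
    if handedness not in (1, -1):
        raise EstimationError("handedness must be +1 or -1")
    return global_defocus + handedness * z_offset * pixel_size * 1e-4


def estimate_defocus(image: np.ndarray, params: CtfParams,
                     search_min: float = 1.0, search_max: float = 6.0,
                     step: float = 0.05,
                     fit_band: tuple[float, float] = (0.05, 0.9),
                     reject_score: float = 0.4) -> dict:
    """Grid-search defocus from the rotationally averaged power spectrum.

    The log power spectrum is background-subtracted with a low-order polynomial
    fit, then correlated against the model CTF^2 over the fit band (fractions of
    Nyquist).  Returns ``{"defocus", "score", "reliable", "profile"}``; a score
    below ``reject_score`` flags the estimate unreliable (e.g. pure noise input).
    """
    if not (search_max > search_min > 0 and step > 0):
        raise EstimationError("bad search range")
    image = np.asarray(image, dtype=float)
    spec = np.abs(sfft.rfft2(image - image.mean())) ** 2
    freq = _freq_grid_2d(image.shape, params.pixel_size)
    if spec.std() == 0:
        raise EstimationError("flat image: no spectral variance")
    nyquist = 0.5 / params.pixel_size
    n_bins = min(image.shape) // 2
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    idx = np.clip(np.digitize(freq.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=spec.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    radial = sums / np.maximum(counts, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    band = (centers >= fit_band[0] * nyquist) & (centers <= fit_band[1] * nyquist)
    if band.sum() < 10:
        raise EstimationError("fit band too narrow for the image size")
    log_p = np.log(np.maximum(radial[band], 1e-30))
    # low-order polynomial background in log space
    coeffs = np.polyfit(centers[band], log_p, 3)
    signal = log_p - np.polyval(coeffs, centers[band])

    best = (None, -np.inf)
    grid = np.arange(search_min, search_max + step / 2, step)
    for dz in grid:
        model = ctf_value(params.with_defocus(dz), centers[band]) ** 2
        model = model - model.mean()
        s = signal - signal.mean()
        denom = np.linalg.norm(model) * np.linalg.norm(s)
        score = float(model @ s / denom) if denom > 0 else 0.0
        if score > best[1]:
            best = (float(dz), score)
    defocus, score = best
    return {
        "defocus": defocus,
        "score": score,
        "reliable": score >= reject_score,
        "profile": {"frequency": centers[band].tolist(),
                    "spectrum": signal.tolist()},
    }
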