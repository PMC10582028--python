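"""Missing-wedge-aware 3D template matching with fast local normalization,
micrograph/CC-map cleanup utilities, and capped sigma-threshold peak extraction.

The engine correlates a rotated, wedge-filtered template against the tomogram
for every orientation of a search grid, keeping the per-voxel best score and
orientation index.  Local normalization follows the masked cross-correlation
scheme: with mask weights :math:`w` and the rotated template :math:`T`,

.. math::

    cc(v) = \\frac{\\sum_i w_i (T_i - \\bar T_w)\\, D(v+i)}
                 {\\sqrt{\\sum_i w_i (T_i-\\bar T_w)^2}\\;
                  \\sqrt{\\sum_i w_i D(v+i)^2 - (\\sum_i w_i D(v+i))^2 / W}}

which is bounded in [-1, 1]; all convolutions run through FFTs.  Chunked and
unchunked execution produce identical maps (seam-free stitching with an overlap
of one template box).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

from .errors import TomopipeError
from .formats_io import ParticleRecord
from .geometry import OrientationGrid, WedgeSpec, wedge_mask, rotate_volume

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "soft_sphere_mask",
    "lowpass_filter",
    "fourier_resample",
    "prepare_template",
    "erase_gold",
    "erase_grid_edge",
    "taper_edges",
    "match_template",
    "postprocess_cc",
    "extract_peaks",
]


# ---------------------------------------------------------------------------
# Template preparation
# ---------------------------------------------------------------------------

def soft_sphere_mask(box: int, radius: float | None = None,
                     soft_edge: float = 3.0) -> np.ndarray:
    """Spherical mask with a cosine edge; default radius leaves the edge inside."""
    if radius is None:
        radius = box / 2.0 - soft_edge - 1.0
    c = (box - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(box) - c,) * 3, indexing="ij")
    d = np.sqrt(x * x + y * y + z * z) - radius
    t = np.clip(d / max(soft_edge, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def lowpass_filter(volume: np.ndarray, voxel_size: float, resolution: float,
                   soft_shells: float = 3.0) -> np.ndarray:
    """Low-pass at ``resolution`` Angstrom with a cosine edge of ``soft_shells``
    Fourier voxels.  The edge ramps down *inside* the cutoff, so no power
    survives beyond it."""
    if not np.isfinite(resolution) or resolution <= 0:
        return np.asarray(volume, dtype=float).copy()
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in volume.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    f = np.sqrt(sum(g * g for g in grids))
    cutoff = 1.0 / resolution
    shell = 1.0 / (volume.shape[0] * voxel_size)  # one Fourier voxel in 1/A
    edge = max(min(soft_shells * shell, cutoff), 1e-12)
    t = np.clip((f - (cutoff - edge)) / edge, 0.0, 1.0)
    window = 0.5 * (1.0 + np.cos(np.pi * t))
    return np.real(sfft.ifftn(sfft.fftn(volume) * window))


def fourier_resample(volume: np.ndarray, source_voxel_size: float,
                     target_voxel_size: float) -> np.ndarray:
    """Resample to a new voxel size by centered Fourier cropping/padding."""
    if source_voxel_size <= 0 or target_voxel_size <= 0:
        raise TomopipeError("voxel sizes must be > 0")
    ratio = source_voxel_size / target_voxel_size
    new_shape = tuple(max(2, int(round(n * ratio)) // 2 * 2) for n in volume.shape)
    if new_shape == volume.shape:
        return np.asarray(volume, dtype=float).copy()
    spec = sfft.fftshift(sfft.fftn(volume))
    out_spec = np.zeros(new_shape, dtype=complex)
    src_slices, dst_slices = [], []
    for n_old, n_new in zip(volume.shape, new_shape):
        n = min(n_old, n_new)
        src_slices.append(slice(n_old // 2 - n // 2, n_old // 2 - n // 2 + n))
        dst_slices.append(slice(n_new // 2 - n // 2, n_new // 2 - n // 2 + n))
    out_spec[tuple(dst_slices)] = spec[tuple(src_slices)]
    scale = np.prod(new_shape) / np.prod(volume.shape)
    return np.real(sfft.ifftn(sfft.ifftshift(out_spec))) * scale


def prepare_template(volume: np.ndarray, source_voxel_size: float,
                     target_voxel_size: float, lowpass: float = np.inf,
                     mask_soft_edge: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample to the tomogram voxel size, low-pass to a conservative
    resolution, and normalize to zero mean / unit variance inside a soft
    spherical mask.  Returns (template, mask)."""
    if np.isfinite(lowpass) and lowpass < 2.0 * target_voxel_size:
        raise TomopipeError(
            f"low-pass {lowpass} A is beyond Nyquist ({2 * target_voxel_size} A) "
            f"at {target_voxel_size} A/voxel")
    resampled = fourier_resample(volume, source_voxel_size, target_voxel_size)
    filtered = lowpass_filter(resampled, target_voxel_size, lowpass)
    mask = soft_sphere_mask(filtered.shape[0], soft_edge=mask_soft_edge)
    w = mask / mask.sum()
    mean = float((filtered * w).sum())
    var = float((w * (filtered - mean) ** 2).sum())
    template = (filtered - mean) / np.sqrt(max(var, 1e-30))
    return template, mask


# ---------------------------------------------------------------------------
# Micrograph cleanup
# ---------------------------------------------------------------------------

def _fill_with_background(image: np.ndarray, region: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Replace ``region`` pixels by background mean plus variance-matched noise."""
    out = image.copy()
    background = image[~region]
    mu = float(background.mean()) if background.size else float(image.mean())
    sd = float(background.std()) if background.size else float(image.std())
    out[region] = mu + rng.normal(0.0, sd, size=int(region.sum()))
    return out


def erase_gold(image: np.ndarray, bead_diameter_px: float,
               positions: np.ndarray | None = None,
               detect_sigma: float = 5.0, seed: int = 0) -> np.ndarray:
    """Erase gold beads: each disc (plus a 2-px margin) becomes local background.

    Without explicit ``positions`` the beads are found by matched filtering with
    a disc kernel on the mean-subtracted image; detection is polarity-agnostic
    (|response| above ``detect_sigma`` response-sigmas), since the bead contrast
    sign depends on the image convention.  Zero detections is a valid outcome.
    """
    if bead_diameter_px <= 2:
        raise TomopipeError("bead diameter must exceed 2 px")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    r = bead_diameter_px / 2.0
    if positions is None:
        ir = int(np.ceil(r))
        yy, xx = np.meshgrid(np.arange(-ir, ir + 1), np.arange(-ir, ir + 1),
                             indexing="ij")
        disc = (np.hypot(xx, yy) <= r).astype(float)
        disc -= disc.mean()
        disc /= np.linalg.norm(disc)
        response = ndimage.convolve(image - image.mean(), disc, mode="reflect")
        resp_sd = response.std()
        hits = np.abs(response) > detect_sigma * resp_sd
        # keep one detection per connected blob of suprathreshold response
        labels, n = ndimage.label(hits)
        positions = np.array(ndimage.maximum_position(
            np.abs(response), labels, index=range(1, n + 1))) if n else np.zeros((0, 2))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return image.copy()
    region = np.zeros(image.shape, dtype=bool)
    gx, gy = np.meshgrid(np.arange(image.shape[0]), np.arange(image.shape[1]),
                         indexing="ij")
    for pos in positions:
        region |= np.hypot(gx - pos[0], gy - pos[1]) <= r + 2.0
    return _fill_with_background(image, region, rng)


def erase_grid_edge(image: np.ndarray, intensity_drop_threshold: float = 0.5,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Erase a grid bar/hole edge: the largest connected low-intensity region
    touching the image border, with mean below ``threshold * image mean``, is
    replaced by matched background.  Returns (cleaned image, replaced-pixel mask).
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    cutoff = intensity_drop_threshold * image.mean()
    low = image < cutoff
    labels, n = ndimage.label(low)
    best_label, best_size = 0, 0
    for lab in range(1, n + 1):
        comp = labels == lab
        touches = comp[0, :].any() or comp[-1, :].any() or \
            comp[:, 0].any() or comp[:, -1].any()
        if not touches:
            continue
        if image[comp].mean() >= cutoff:
            continue
        size = int(comp.sum())
        if size > best_size:
            best_label, best_size = lab, size
    if best_label == 0:
        return image.copy(), np.zeros(image.shape, dtype=bool)
    region = ndimage.binary_dilation(labels == best_label, iterations=1)
    return _fill_with_background(image, region, rng), region


def taper_edges(data: np.ndarray, width_px: int) -> np.ndarray:
    """Cosine-taper the border band toward the data mean; interior untouched."""
    if width_px == 0:
        return np.asarray(data).copy()
    if width_px >= min(data.shape) / 2:
        raise TomopipeError("taper width must be below half the smallest dimension")
    data = np.asarray(data, dtype=float)
    window = np.ones(data.shape)
    for axis, n in enumerate(data.shape):
        prof = np.ones(n)
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(width_px) + 1) /
                                   (width_px + 1)))
        prof[:width_px] = ramp
        prof[-width_px:] = ramp[::-1]
        shape = [1] * data.ndim
        shape[axis] = n
        window = window * prof.reshape(shape)
    mean = data.mean()
    out = data.copy()
    band = window < 1.0  # interior stays bit-identical
    out[band] = mean + (data[band] - mean) * window[band]
    return out


# ---------------------------------------------------------------------------
# Matching engine
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Per-voxel best cross-correlation and the grid index achieving it."""

    cc_map: np.ndarray
    orient_map: np.ndarray
    grid: OrientationGrid
    chunk_layout: tuple = ()
    valid_mask: np.ndarray | None = field(default=None, repr=False)


def _good_fft_size(n: int) -> int:
    """Smallest 5-smooth integer >= n (5-smooth transforms are fastest here)."""
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def _origin_embed(kernel: np.ndarray, shape: tuple[int, ...],
                  out: np.ndarray | None = None) -> np.ndarray:
    """Place a small kernel into a large array with its center voxel at index 0.

    The kernel is split at its center and wrapped into the 8 corner blocks
    (equivalent to zero-pad + circular shift, without copying the big array).
    """
    if out is None:
        out = np.zeros(shape, dtype=kernel.dtype)
    b = kernel.shape
    splits = [(s // 2, s - s // 2) for s in b]  # (center, remainder)
    for cx, kx in ((slice(0, splits[0][1]), slice(splits[0][0], b[0])),
                   (slice(shape[0] - splits[0][0], shape[0]), slice(0, splits[0][0]))):
        for cy, ky in ((slice(0, splits[1][1]), slice(splits[1][0], b[1])),
                       (slice(shape[1] - splits[1][0], shape[1]), slice(0, splits[1][0]))):
            for cz, kz in ((slice(0, splits[2][1]), slice(splits[2][0], b[2])),
                           (slice(shape[2] - splits[2][0], shape[2]), slice(0, splits[2][0]))):
                out[cx, cy, cz] = kernel[kx, ky, kz]
    return out


def _mask_is_isotropic(mask: np.ndarray) -> bool:
    rot = np.swapaxes(mask, 0, 2)[::-1]  # 90-degree rotation
    denom = np.abs(mask).max() or 1.0
    return bool(np.abs(rot - mask).max() / denom < 1e-3)


class _ChunkMatcher:
    """Correlates every grid orientation against one zero-padded data block."""

    def __init__(self, data: np.ndarray, box: int, global_var: float,
                 dtype=np.float64):
        self.data_shape = data.shape
        self.box = box
        self.dtype = np.dtype(dtype)
        pad_shape = tuple(_good_fft_size(s + box) for s in data.shape)
        self.pad_shape = pad_shape
        padded = np.zeros(pad_shape, dtype=self.dtype)
        padded[:data.shape[0], :data.shape[1], :data.shape[2]] = data
        self.f_data = sfft.rfftn(padded)
        self.f_data2 = sfft.rfftn(padded * padded)
        self.eps = 1e-6 * global_var
        self._kernel_buf = np.zeros(pad_shape, dtype=self.dtype)
        self._denominator_cache: np.ndarray | None = None

    def _crop(self, arr: np.ndarray) -> np.ndarray:
        return arr[:self.data_shape[0], :self.data_shape[1], :self.data_shape[2]]

    def denominator(self, mask: np.ndarray, cacheable: bool) -> np.ndarray:
        """sqrt of the mask-local data variance (epsilon-floored), plus the
        bad-region mask in ``self._bad``."""
        if cacheable and self._denominator_cache is not None:
            return self._denominator_cache
        w_total = float(mask.sum())
        f_mask = sfft.rfftn(_origin_embed(mask.astype(self.dtype), self.pad_shape))
        s1 = sfft.irfftn(self.f_data * np.conj(f_mask), s=self.pad_shape)
        s2 = sfft.irfftn(self.f_data2 * np.conj(f_mask), s=self.pad_shape)
        var = self._crop(s2 - s1 * s1 / w_total)
        denom = np.sqrt(np.maximum(var, self.eps * w_total))
        self._bad = var < self.eps * w_total
        if cacheable:
            self._denominator_cache = denom
        return denom

    def numerator(self, template_rot: np.ndarray, mask_rot: np.ndarray
                  ) -> np.ndarray:
        """Mask-weighted correlation numerator, scaled by the template norm.

        Dividing by the (orientation-independent, for isotropic masks) local
        denominator is deferred to the caller so the per-orientation maximum
        can be tracked on numerators alone.
        """
        w = mask_rot
        w_total = float(w.sum())
        t_mean = float((w * template_rot).sum() / w_total)
        kernel = (w * (template_rot - t_mean)).astype(self.dtype)
        norm_t = np.sqrt(float((kernel * (template_rot - t_mean)).sum()))
        f_kernel = sfft.rfftn(_origin_embed(kernel, self.pad_shape,
                                            out=self._kernel_buf))
        np.conjugate(f_kernel, out=f_kernel)
        np.multiply(f_kernel, self.f_data, out=f_kernel)
        num = sfft.irfftn(f_kernel, s=self.pad_shape)
        return self._crop(num) * (1.0 / max(norm_t, 1e-30))


def match_template(tomogram: np.ndarray, template: np.ndarray, mask: np.ndarray,
                   grid: OrientationGrid, wedge_spec: WedgeSpec | None = None,
                   chunk_size: int | tuple[int, int, int] | None = None,
                   precision: str = "double") -> MatchResult:
    """Wedge-aware, locally normalized template matching over an orientation grid.

    For each grid orientation the template is rotated, wedge-filtered in Fourier
    space (the wedge lives in the tomogram frame, so it is applied after
    rotation), masked and correlated against the tomogram.  ``chunk_size`` tiles
    the volume (overlap = one template box) without changing the result; ``None``
    processes the whole volume as one chunk.  ``precision`` selects the FFT
    dtype: ``"double"`` (default) or ``"single"`` for large exhaustive searches
    where throughput matters more than the last digits of the score.
    """
    if precision not in ("single", "double"):
        raise TomopipeError("precision must be 'single' or 'double'")
    dtype = np.float32 if precision == "single" else np.float64
    volume = np.asarray(tomogram, dtype=np.float32)
    box = template.shape[0]
    if template.shape != mask.shape:
        raise TomopipeError("template and mask shapes differ")
    if chunk_size is not None:
        chunks = np.atleast_1d(np.asarray(chunk_size, dtype=int))
        chunks = np.broadcast_to(chunks, (3,)).copy()
        if np.any(chunks < box):
            raise TomopipeError(f"chunk size {tuple(chunks)} smaller than the "
                                f"template box {box}")
    else:
        chunks = np.array(volume.shape)

    wedge_filter = None
    if wedge_spec is not None:
        wedge_filter = wedge_mask(wedge_spec, template.shape)

    global_var = float(volume.var())
    isotropic = _mask_is_isotropic(mask)
    if not isotropic:
        logger.info("anisotropic mask: per-orientation local moments")

    cc_map = np.full(volume.shape, -np.inf, dtype=np.float32)
    orient_map = np.zeros(volume.shape, dtype=np.int32)

    starts = [list(range(0, volume.shape[d], chunks[d])) for d in range(3)]
    layout = tuple(len(s) for s in starts)
    margin = box  # cc at voxel v needs data within v +/- box

    # pre-rotate all templates/masks once (small volumes, cheap vs the big FFTs)
    rotated: list[tuple[np.ndarray, np.ndarray]] = []
    for rot in grid.matrices:
        t_rot = rotate_volume(template, rot)
        m_rot = mask if isotropic else rotate_volume(mask, rot)
        if wedge_filter is not None:
            t_rot = np.real(sfft.ifftn(sfft.fftn(t_rot) * wedge_filter))
        rotated.append((t_rot.astype(np.float64), m_rot.astype(np.float64)))

    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                hi = np.minimum(np.array([sx, sy, sz]) + chunks, volume.shape)
                lo = np.array([sx, sy, sz])
                ext_lo = np.maximum(lo - margin, 0)
                ext_hi = np.minimum(hi + margin, volume.shape)
                block = volume[ext_lo[0]:ext_hi[0], ext_lo[1]:ext_hi[1],
                               ext_lo[2]:ext_hi[2]]
                matcher = _ChunkMatcher(block, box, global_var, dtype=dtype)
                sub = tuple(slice(off, off + n)
                            for off, n in zip(lo - ext_lo, hi - lo))
                best = np.full(tuple(hi - lo), -np.inf, dtype=dtype)
                best_idx = np.zeros(tuple(hi - lo), dtype=np.int32)
                if isotropic:
                    # one denominator for all orientations: track numerators only
                    denom = matcher.denominator(mask.astype(np.float64), True)
                    for j, (t_rot, m_rot) in enumerate(rotated):
                        num = matcher.numerator(t_rot, m_rot)[sub]
                        better = num > best
                        best[better] = num[better]
                        best_idx[better] = j
                    cc = best / denom[sub]
                    cc[matcher._bad[sub]] = 0.0
                else:
                    for j, (t_rot, m_rot) in enumerate(rotated):
                        denom = matcher.denominator(m_rot, False)
                        num = matcher.numerator(t_rot, m_rot)
                        cc_j = num / denom
                        cc_j[matcher._bad] = 0.0
                        cc_j = cc_j[sub]
                        better = cc_j > best
                        best[better] = cc_j[better]
                        best_idx[better] = j
                    cc = best
                cc_map[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = \
                    np.clip(cc, -1.0, 1.0)
                orient_map[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = best_idx
    return MatchResult(cc_map=cc_map, orient_map=orient_map, grid=grid,
                       chunk_layout=layout)


# ---------------------------------------------------------------------------
# CC-map post-processing and peak extraction
# ---------------------------------------------------------------------------

def postprocess_cc(cc_map: np.ndarray, island_max_size: float,
                   dilation: int = 0) -> np.ndarray:
    """Zero connected high-CC components larger than ``island_max_size`` voxels.

    Component finding thresholds at mean + 2 sigma of the map; point-like peaks
    survive, extended ridges (membranes, edges) are removed.  ``dilation``
    grows the zeroed region by that many voxels.
    """
    cc = np.asarray(cc_map, dtype=np.float32).copy()
    if not np.isfinite(island_max_size):
        return cc
    thr = cc.mean() + 2.0 * cc.std()
    labels, n = ndimage.label(cc > thr)
    if n == 0:
        return cc
    sizes = ndimage.sum_labels(np.ones_like(cc), labels, index=range(1, n + 1))
    big = np.isin(labels, np.nonzero(sizes > island_max_size)[0] + 1)
    if dilation > 0:
        big = ndimage.binary_dilation(big, iterations=dilation)
    cc[big] = 0.0
    return cc


def extract_peaks(match_result: MatchResult, threshold_sigma: float | None = None,
                  max_particles: int | None = None,
                  exclusion_radius: float = 10.0,
                  valid_mask: np.ndarray | None = None,
                  tomogram_id: int = 1) -> list[ParticleRecord]:
    """Greedy descending-CC peak extraction with non-maximum suppression.

    Map statistics (mean, sigma) are computed once over the valid region before
    any selection; extraction stops at ``mean + threshold_sigma * sigma`` or at
    ``max_particles``, whichever bites first.  Each row carries the 1-based
    position, peak CC and the Euler triplet of the winning grid orientation.
    """
    if threshold_sigma is None and max_particles is None:
        raise TomopipeError("need a sigma threshold and/or a particle cap")
    cc = np.array(match_result.cc_map, dtype=np.float64)
    region = np.ones(cc.shape, dtype=bool) if valid_mask is None else valid_mask
    mean = float(cc[region].mean())
    sigma = float(cc[region].std())
    floor = -np.inf if threshold_sigma is None else mean + threshold_sigma * sigma
    cap = np.inf if max_particles is None else max_particles

    work = np.where(region, cc, -np.inf)
    records: list[ParticleRecord] = []
    grid_orients = match_result.grid.orientations
    r = exclusion_radius
    ir = int(np.ceil(r))
    while len(records) < cap:
        flat = int(np.argmax(work))
        peak = np.unravel_index(flat, work.shape)
        value = work[peak]
        if not np.isfinite(value) or value < floor:
            break
        idx = int(match_result.orient_map[peak])
        ori = grid_orients[idx]
        records.append(ParticleRecord(
            tag=len(records) + 1, cc=float(value),
            x=int(peak[0]) + 1, y=int(peak[1]) + 1, z=int(peak[2]) + 1,
            tdrot=ori.tdrot, tilt=ori.tilt, narot=ori.narot,
            class_id=0, tomogram_id=tomogram_id))
        lo = np.maximum(np.array(peak) - ir, 0)
        hi = np.minimum(np.array(peak) + ir + 1, work.shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        gx, gy, gz = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)),
                                 indexing="ij")
        ball = ((gx - peak[0]) ** 2 + (gy - peak[1]) ** 2 +
                (gz - peak[2]) ** 2) <= r * r
        work[sub][ball] = -np.inf
    return records
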