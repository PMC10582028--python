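"""Subtomogram extraction, constrained alignment, noise-trap multi-reference
classification, wedge-compensated averaging, half-set splitting and FSC.

Pose semantics: a particle with Euler triplet R and residual shift s looks like
``shift(rotate(reference, R), s)`` inside its box.  Averaging therefore undoes
the shift, rotates by the inverse, and compensates each particle's missing
wedge in Fourier space:

.. math::

    \\bar V = \\mathcal{F}^{-1}\\left[\\frac{\\sum_i \\mathcal{F}[R_i^{-1} P_i]}
              {\\max(\\sum_i R_i^{-1} W_i,\\ \\epsilon)}\\right]

with a denominator floor of 1% of its maximum to keep never-sampled
frequencies from amplifying noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import scipy.fft as sfft
from scipy.ndimage import shift as nd_shift

from .errors import TomopipeError, EstimationError
from .formats_io import ParticleRecord
from .geometry import (Orientation, OrientationGrid, WedgeSpec, euler_to_matrix,
                       matrix_to_euler, rotate_volume, symmetrize, wedge_mask)
from .reconstruction import Tomogram, reconstruct_particle
from .simulator import TiltSeries
from .template_matching import lowpass_filter, soft_sphere_mask

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleStack",
    "ClassModel",
    "FscCurve",
    "extract_particles",
    "make_noise_trap",
    "align_particle",
    "classify_mra",
    "average_particles",
    "split_half_sets",
    "compute_fsc",
    "resolution_at",
]


@dataclass
class ParticleStack:
    """Cubic particle boxes with a congruent table and per-particle wedges."""

    boxes: np.ndarray  # (n, b, b, b)
    table: list[ParticleRecord]
    wedges: list[WedgeSpec]
    binning: int = 1

    def __post_init__(self) -> None:
        if len(self.table) != len(self.boxes):
            raise TomopipeError("table length does not match stack length")
        if len(self.wedges) not in (0, len(self.boxes)):
            raise TomopipeError("wedge list must be empty or congruent")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class ClassModel:
    """References for multi-reference alignment; noise traps flagged parallel."""

    references: list[np.ndarray]
    is_noise_trap: list[bool]
    alignment_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.references) != len(self.is_noise_trap):
            raise TomopipeError("is_noise_trap must parallel references")
        if not any(not t for t in self.is_noise_trap):
            raise TomopipeError("need at least one non-noise reference")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _fold_shifts(record: ParticleRecord) -> ParticleRecord:
    """Recenter: move integer parts of the sub-voxel shifts into the position."""
    out = dc_replace(record)
    for pos_name, shift_name in (("x", "dx"), ("y", "dy"), ("z", "dz")):
        shift = getattr(out, shift_name)
        whole = int(round(shift))
        setattr(out, pos_name, getattr(out, pos_name) + whole)
        setattr(out, shift_name, shift - whole)
    return out


def extract_particles(source: Tomogram | TiltSeries, table: list[ParticleRecord],
                      box: int, recenter: bool = True,
                      randomize_orientations: bool = False,
                      seed: int = 0, wedge: WedgeSpec | None = None,
                      thickness: int | None = None,
                      ctf_params=None) -> ParticleStack:
    """Extract subtomograms by cropping a tomogram or by direct reconstruction
    from a tilt series (one mini weighted back-projection per particle).

    With ``recenter`` the accumulated sub-voxel shifts are folded into the
    integer positions (residual |shift| < 0.5).  ``randomize_orientations``
    replaces the Euler triplets with uniform random rotations — used to break
    the orientation bias a restricted-range angular search imprints along the
    missing wedge.  Out-of-bounds particles are skipped and logged.
    """
    if not table:
        raise TomopipeError("empty particle table")
    if box % 2:
        raise TomopipeError("box size must be even")
    rng = np.random.default_rng(seed)
    records = [(_fold_shifts(r) if recenter else dc_replace(r)) for r in table]
    if randomize_orientations:
        from scipy.spatial.transform import Rotation
        for rec in records:
            q = rng.normal(size=4)
            ori = matrix_to_euler(Rotation.from_quat(q / np.linalg.norm(q)).as_matrix())
            rec.tdrot, rec.tilt, rec.narot = ori.tdrot, ori.tilt, ori.narot

    boxes, kept, wedges = [], [], []
    if isinstance(source, Tomogram):
        vol = source.volume
        h = box // 2
        for rec in records:
            pos = np.array([rec.x - 1, rec.y - 1, rec.z - 1])
            lo = pos - h
            hi = lo + box
            if np.any(lo < 0) or np.any(hi > np.array(vol.shape)):
                logger.warning("particle %d at %s out of bounds; skipped",
                               rec.tag, pos.tolist())
                continue
            boxes.append(np.array(vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                                  dtype=np.float32))
            kept.append(rec)
            wedges.append(wedge)
        binning = source.binning
    elif isinstance(source, TiltSeries):
        series_wedge = wedge or WedgeSpec(tuple(source.tilt_angles))
        for rec in records:
            pos = np.array([rec.x - 1, rec.y - 1, rec.z - 1], dtype=float)
            sub = reconstruct_particle(source, pos, box, ctf_params=ctf_params,
                                       thickness=thickness)
            if sub is None:
                continue
            boxes.append(sub)
            kept.append(rec)
            wedges.append(series_wedge)
        binning = 1
    else:
        raise TomopipeError(f"cannot extract from {type(source).__name__}")
    if not boxes:
        raise TomopipeError("no particle could be extracted (all out of bounds)")
    wedges = [w for w in wedges if w is not None]
    if wedges and len(wedges) != len(boxes):
        raise TomopipeError("wedge specification missing for some particles")
    return ParticleStack(boxes=np.stack(boxes), table=kept, wedges=wedges,
                         binning=binning)


# ---------------------------------------------------------------------------
# Noise traps
# ---------------------------------------------------------------------------

def make_noise_trap(template: np.ndarray, lowpass: float, seed: int,
                    voxel_size: float = 1.0,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """A pure-noise reference with the template's box, band limit and in-mask
    scale: Gaussian noise low-passed at the template's cutoff, zero in-mask
    mean, std matched to the template's in-mask std."""
    if mask is None:
        mask = soft_sphere_mask(template.shape[0])
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=template.shape)
    noise = lowpass_filter(noise, voxel_size, lowpass)
    w = mask / mask.sum()
    t_mean = float((template * w).sum())
    t_std = float(np.sqrt((w * (template - t_mean) ** 2).sum()))
    n_mean = float((noise * w).sum())
    n_std = float(np.sqrt((w * (noise - n_mean) ** 2).sum()))
    return (noise - n_mean) * (t_std / max(n_std, 1e-30))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _parabolic_offset(values: np.ndarray) -> float:
    """Sub-voxel offset of a 3-point parabola peak; 0 when degenerate."""
    a, b, c = values
    denom = a - 2 * b + c
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def align_particle(particle: np.ndarray, reference: np.ndarray,
                   mask: np.ndarray, local_grid: OrientationGrid,
                   wedge_spec: WedgeSpec | None = None,
                   shift_limit: float = 4.0,
                   center: Orientation | None = None
                   ) -> tuple[Orientation, np.ndarray, float]:
    """Constrained alignment of one particle against one reference.

    Every candidate orientation (the local grid composed onto ``center``) is
    applied to the reference, the particle's wedge is imposed on it so both
    volumes live in the same sampled Fourier subspace, and the masked
    cross-correlation is maximized over shifts within ``shift_limit`` voxels
    (sub-voxel peak by parabolic interpolation).
    """
    if mask is None or not np.any(mask > 0):
        raise EstimationError("empty alignment mask")
    box = particle.shape[0]
    if shift_limit > box / 4:
        raise EstimationError("shift_limit must be <= box/4")
    wedge_filter = None
    if wedge_spec is not None:
        wedge_filter = wedge_mask(wedge_spec, particle.shape)
    center_mat = np.eye(3) if center is None else euler_to_matrix(center)

    p_masked = (particle - particle.mean()) * mask
    p_norm = np.linalg.norm(p_masked)
    if p_norm == 0:
        raise EstimationError("flat particle")
    f_particle = sfft.rfftn(p_masked)

    limit = int(np.floor(shift_limit))
    best = (None, np.zeros(3), -np.inf, None)
    for j, rel in enumerate(local_grid.matrices):
        rot = center_mat @ rel
        ref_rot = rotate_volume(reference, rot)
        if wedge_filter is not None:
            ref_rot = np.real(sfft.ifftn(sfft.fftn(ref_rot) * wedge_filter))
        ref_m = (ref_rot - ref_rot.mean()) * mask
        norm = np.linalg.norm(ref_m) * p_norm
        if norm == 0:
            continue
        cc_vol = sfft.irfftn(f_particle * np.conj(sfft.rfftn(ref_m)),
                             s=particle.shape) / norm
        cc_shifted = sfft.fftshift(cc_vol)
        c = box // 2
        window = cc_shifted[c - limit:c + limit + 1,
                            c - limit:c + limit + 1,
                            c - limit:c + limit + 1]
        peak = np.unravel_index(int(np.argmax(window)), window.shape)
        value = float(window[peak])
        if value > best[2]:
            shift = np.array(peak, dtype=float) - limit
            best = (rot, shift, value, (window, peak))
    rot, shift, value, extra = best
    if rot is None:
        raise EstimationError("no valid orientation candidate")
    window, peak = extra
    for ax in range(3):
        if 0 < peak[ax] < window.shape[ax] - 1:
            sel = list(peak)
            vals = []
            for d in (-1, 0, 1):
                sel[ax] = peak[ax] + d
                vals.append(window[tuple(sel)])
            shift[ax] += _parabolic_offset(np.array(vals))
    shift = np.clip(shift, -shift_limit, shift_limit)
    # cc_vol peak at +s means the reference must be shifted by +s to match:
    # the particle center sits at box center + s.
    return matrix_to_euler(rot), shift, value


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def average_particles(stack: ParticleStack, table: list[ParticleRecord] | None = None,
                      symmetry: str | None = None,
                      denominator_floor: float = 0.01) -> np.ndarray:
    """Wedge-compensated average of the stack in the reference frame."""
    table = table if table is not None else stack.table
    if len(table) != len(stack):
        raise TomopipeError("table and stack lengths differ")
    if len(stack) == 0:
        raise TomopipeError("zero particles to average")
    box = stack.boxes.shape[1]
    num = np.zeros((box, box, box), dtype=complex)
    den = np.zeros((box, box, box))
    full = np.ones((box, box, box))
    for i, rec in enumerate(table):
        inv = euler_to_matrix(Orientation(rec.tdrot, rec.tilt, rec.narot)).T
        particle = stack.boxes[i].astype(np.float64)
        shift = np.array([rec.dx, rec.dy, rec.dz])
        if np.any(np.abs(shift) > 1e-9):
            particle = nd_shift(particle, -shift, order=1, mode="constant")
        aligned = rotate_volume(particle, inv)
        num += sfft.fftn(aligned)
        if stack.wedges:
            w_centered = sfft.fftshift(wedge_mask(stack.wedges[i],
                                                  (box, box, box)))
            den += sfft.ifftshift(rotate_volume(w_centered, inv))
        else:
            den += full
    floor = denominator_floor * den.max()
    avg = np.real(sfft.ifftn(num / np.maximum(den, floor)))
    if symmetry and symmetry.upper() != "C1":
        avg = symmetrize(avg, symmetry)
    return avg.astype(np.float32)


# ---------------------------------------------------------------------------
# Multi-reference classification
# ---------------------------------------------------------------------------

def classify_mra(stack: ParticleStack, class_model: ClassModel,
                 n_iterations: int, local_grid: OrientationGrid,
                 shift_limit: float = 4.0,
                 use_current_orientation: bool = True
                 ) -> tuple[np.ndarray, list[ParticleRecord],
                            list[np.ndarray], list[dict]]:
    """Noise-trap multi-reference alignment and classification.

    Each iteration aligns every particle against every reference, assigns it to
    the best-correlating class, then rebuilds the non-noise class averages by
    wedge-compensated averaging of their members.  Noise traps stay fixed —
    they exist to soak up false positives, not to converge.  Returns
    (assignments, refined table, class references, per-iteration report).
    """
    if n_iterations < 1:
        raise TomopipeError("n_iterations must be >= 1")
    refs = [np.array(r, dtype=np.float64) for r in class_model.references]
    mask = class_model.alignment_mask
    if mask is None:
        mask = soft_sphere_mask(stack.boxes.shape[1])
    table = [dc_replace(r) for r in stack.table]
    assignments = np.zeros(len(stack), dtype=int)
    report: list[dict] = []
    for iteration in range(n_iterations):
        for i in range(len(stack)):
            rec = table[i]
            center = Orientation(rec.tdrot, rec.tilt, rec.narot) \
                if use_current_orientation else None
            wedge = stack.wedges[i] if stack.wedges else None
            best = (-np.inf, 0, None, None)
            for k, ref in enumerate(refs):
                ori, shift, cc = align_particle(
                    stack.boxes[i], ref, mask, local_grid, wedge_spec=wedge,
                    shift_limit=shift_limit, center=center)
                if cc > best[0]:
                    best = (cc, k, ori, shift)
            cc, k, ori, shift = best
            assignments[i] = k
            rec.cc = cc
            rec.class_id = k
            rec.tdrot, rec.tilt, rec.narot = ori.tdrot, ori.tilt, ori.narot
            rec.dx, rec.dy, rec.dz = float(shift[0]), float(shift[1]), float(shift[2])
        counts = {k: int((assignments == k).sum()) for k in range(len(refs))}
        report.append({"iteration": iteration + 1, "counts": counts,
                       "mean_cc": {k: float(np.mean([table[i].cc for i in
                                                     np.nonzero(assignments == k)[0]]))
                                   if counts[k] else None
                                   for k in range(len(refs))}})
        for k in range(len(refs)):
            if class_model.is_noise_trap[k]:
                continue
            members = np.nonzero(assignments == k)[0]
            if len(members) == 0:
                warnings.warn(f"class {k} emptied out; keeping previous reference")
                continue
            sub = ParticleStack(
                boxes=stack.boxes[members],
                table=[table[i] for i in members],
                wedges=[stack.wedges[i] for i in members] if stack.wedges else [],
                binning=stack.binning)
            refs[k] = average_particles(sub).astype(np.float64)
    return assignments, table, refs, report


# ---------------------------------------------------------------------------
# Half sets and FSC
# ---------------------------------------------------------------------------

def split_half_sets(table: list[ParticleRecord], mode: str = "even-odd",
                    seed: int | None = None
                    ) -> tuple[list[ParticleRecord], list[ParticleRecord]]:
    """Disjoint, exhaustive split into half-sets (sizes differ by <= 1).

    ``mode``: ``"even-odd"`` (by table row parity, deterministic) or
    ``"random"`` (seeded permutation).  The ``half_set`` field is written.
    """
    if len(table) < 2:
        raise TomopipeError("need at least 2 particles to split")
    idx = np.arange(len(table))
    if mode == "even-odd":
        in_a = idx % 2 == 0
    elif mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(table))
        in_a = np.zeros(len(table), dtype=bool)
        in_a[perm[: (len(table) + 1) // 2]] = True
    else:
        raise TomopipeError(f"unknown split mode '{mode}'")
    half_a, half_b = [], []
    for i, rec in enumerate(table):
        out = dc_replace(rec)
        out.half_set = 1 if in_a[i] else 2
        (half_a if in_a[i] else half_b).append(out)
    return half_a, half_b


@dataclass
class FscCurve:
    """Fourier shell correlation between two maps, one shell per Fourier voxel."""

    values: np.ndarray
    box: int
    voxel_size: float

    @property
    def frequencies(self) -> np.ndarray:
        """Shell center frequencies in 1/A."""
        return np.arange(len(self.values)) / (self.box * self.voxel_size)

    def write(self, path) -> None:
        from pathlib import Path
        lines = [f"{f:.6f} {v:.6f}" for f, v in zip(self.frequencies, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")


def compute_fsc(volume_a: np.ndarray, volume_b: np.ndarray,
                mask: np.ndarray | None = None,
                voxel_size: float = 1.0) -> FscCurve:
    """Shell-wise normalized cross-correlation of the Fourier coefficients."""
    if volume_a.shape != volume_b.shape:
        raise TomopipeError("volume boxes differ")
    if mask is not None:
        volume_a = volume_a * mask
        volume_b = volume_b * mask
    n = volume_a.shape[0]
    fa = sfft.fftn(volume_a)
    fb = sfft.fftn(volume_b)
    freqs = [np.fft.fftfreq(s) * s for s in volume_a.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(sum(g * g for g in grids))
    shells = np.minimum(np.round(radius).astype(int), n // 2)
    n_shells = n // 2 + 1
    cross = np.bincount(shells.ravel(), weights=np.real(fa * np.conj(fb)).ravel(),
                        minlength=n_shells)
    pa = np.bincount(shells.ravel(), weights=np.abs(fa.ravel()) ** 2,
                     minlength=n_shells)
    pb = np.bincount(shells.ravel(), weights=np.abs(fb.ravel()) ** 2,
                     minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = cross / np.sqrt(pa * pb)
    fsc = np.nan_to_num(fsc, nan=0.0)
    if volume_a.any() and volume_b.any():
        fsc[0] = 1.0
    return FscCurve(values=fsc[:n_shells], box=n, voxel_size=voxel_size)


def resolution_at(fsc: FscCurve, threshold: float = 0.143
                  ) -> tuple[float, bool]:
    """Resolution in Angstrom at the first threshold crossing.

    Linear interpolation between shells; when the curve never crosses, the
    Nyquist bound ``2 * voxel_size`` is returned with ``crossed=False``.
    """
    values = fsc.values
    for s in range(1, len(values)):
        if values[s] < threshold <= values[s - 1]:
            frac = (values[s - 1] - threshold) / (values[s - 1] - values[s])
            crossing = (s - 1) + frac
            return float(fsc.box * fsc.voxel_size / crossing), True
    return 2.0 * fsc.voxel_size, False
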