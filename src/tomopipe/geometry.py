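"""Rotations, orientation grids, point-group symmetry, and missing-wedge masks.

Euler convention: ``(tdrot, tilt, narot)`` in degrees, intrinsic ZXZ, active —
first a rotation by *tdrot* about z, then *tilt* about the new x, then *narot*
about the new z.  The tilt axis of the tomographic geometry is the volume y axis
throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .errors import GeometryError

__all__ = [
    "Orientation",
    "OrientationGrid",
    "SymmetryGroup",
    "WedgeSpec",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_distance",
    "generate_grid",
    "wedge_mask",
    "rotate_volume",
    "symmetrize",
]


@dataclass(frozen=True)
class Orientation:
    """ZXZ Euler triplet in degrees; canonical ranges tdrot,narot in [0,360), tilt in [0,180]."""

    tdrot: float
    tilt: float
    narot: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.tdrot, self.tilt, self.narot])):
            raise GeometryError("non-finite Euler angle")

    def canonical(self) -> "Orientation":
        return Orientation(self.tdrot % 360.0, self.tilt, self.narot % 360.0)


def euler_to_matrix(orientation: Orientation) -> np.ndarray:
    """Active rotation matrix of the ZXZ triplet (3x3, right-handed)."""
    return Rotation.from_euler(
        "ZXZ", [orientation.tdrot, orientation.tilt, orientation.narot],
        degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> Orientation:
    """Inverse of :func:`euler_to_matrix`; rejects improper (reflecting) operators."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise GeometryError(f"rotation operator must be 3x3, got {matrix.shape}")
    if abs(np.linalg.det(matrix) - 1.0) > 1e-6:
        raise GeometryError(f"improper operator: det={np.linalg.det(matrix):.6f}")
    with warnings.catch_warnings():
        # zero-tilt gimbal degeneracy is expected; any (a, 0, b) with a+b fixed is fine
        warnings.simplefilter("ignore", UserWarning)
        tdrot, tilt, narot = Rotation.from_matrix(matrix).as_euler("ZXZ", degrees=True)
    return Orientation(tdrot % 360.0, abs(tilt) if tilt > -1e-12 else tilt,
                       narot % 360.0).canonical()


def rotation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic distance between two rotation operators, degrees."""
    return float(np.degrees((Rotation.from_matrix(a) *
                             Rotation.from_matrix(b).inv()).magnitude()))


# ---------------------------------------------------------------------------
# Symmetry groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetryGroup:
    """A point group given as explicit rotation operators (always contains identity)."""

    label: str
    rotations: tuple = ()  # tuple of 3x3 arrays

    def __len__(self) -> int:
        return len(self.rotations)


def symmetry_group(label: str) -> SymmetryGroup:
    """C-groups (``C1``..``Cn``, axis z) and the octahedral group ``O``."""
    label = label.strip().upper()
    if label.startswith("C") and label[1:].isdigit():
        n = int(label[1:])
        if n < 1:
            raise GeometryError(f"bad cyclic order in '{label}'")
        rots = tuple(Rotation.from_euler("z", 360.0 * k / n, degrees=True).as_matrix()
                     for k in range(n))
        return SymmetryGroup(label, rots)
    if label == "O":
        octa = Rotation.create_group("O")
        return SymmetryGroup("O", tuple(octa.as_matrix()))
    raise GeometryError(
        f"unsupported symmetry '{label}'; supported: C1..Cn, O")


# ---------------------------------------------------------------------------
# Orientation grids
# ---------------------------------------------------------------------------

@dataclass
class OrientationGrid:
    orientations: list[Orientation]
    cone_sampling: float
    cone_range: float
    inplane_sampling: float
    inplane_range: float
    symmetry: str = "C1"
    matrices: np.ndarray = field(default=None, repr=False)  # (n,3,3), cached

    def __post_init__(self) -> None:
        if self.matrices is None:
            self.matrices = np.stack([euler_to_matrix(o) for o in self.orientations]) \
                if self.orientations else np.zeros((0, 3, 3))

    def __len__(self) -> int:
        return len(self.orientations)


def _cone_axes(cone_sampling: float, cone_range: float) -> np.ndarray:
    """Deterministic area-regular golden-angle spiral on the spherical cap.

    The cap has full opening angle ``cone_range`` (half-angle cone_range/2)
    about +z.  Point count is chosen so nearest-neighbour spacing is about
    ``cone_sampling`` degrees.
    """
    if cone_range <= 0 or cone_sampling >= cone_range:
        return np.array([[0.0, 0.0, 1.0]])
    half = np.radians(min(cone_range, 360.0) / 2.0)
    s = np.radians(cone_sampling)
    solid_angle = 2.0 * np.pi * (1.0 - np.cos(half))
    # the 1.4 oversampling keeps the covering radius well inside the nominal
    # sampling step (a bare Omega/s^2 spiral leaves gaps close to s itself)
    n = max(2, int(np.ceil(1.4 * solid_angle / (s * s))))
    # uniform in z over [cos(half), 1], golden-angle azimuth
    i = np.arange(n) + 0.5
    z = 1.0 - (1.0 - np.cos(half)) * (i / n)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    axes = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # always include the exact cone axis
    return np.vstack([[0.0, 0.0, 1.0], axes])


def generate_grid(cone_sampling: float, cone_range: float,
                  inplane_sampling: float, inplane_range: float,
                  symmetry: str = "C1") -> OrientationGrid:
    """Build the rotation search grid, reduced by the point symmetry of the template.

    Cone axes cover the spherical cap of half-angle ``cone_range/2``; each axis
    carries ``inplane_range / inplane_sampling`` in-plane angles.  Two grid
    members are duplicates if their geodesic distance, minimized over the
    symmetry group, is below half the smaller sampling step.
    """
    if cone_sampling <= 0 or inplane_sampling <= 0:
        raise GeometryError("sampling steps must be > 0")
    if inplane_sampling > inplane_range:
        warnings.warn("in-plane sampling exceeds range: single in-plane angle")
        inplane_angles = np.array([0.0])
    else:
        n_ip = int(round(inplane_range / inplane_sampling))
        inplane_angles = (np.arange(n_ip) * inplane_sampling) % 360.0
    if cone_sampling >= cone_range > 0:
        warnings.warn("cone sampling exceeds cone range: axis search disabled")
    axes = _cone_axes(cone_sampling, cone_range)

    group = symmetry_group(symmetry)
    group_quats = Rotation.from_matrix(np.stack(group.rotations)) if len(group) else None
    tol = np.cos(np.radians(0.5 * min(cone_sampling, inplane_sampling)) / 2.0)

    # orientation = (axis tilt) * (in-plane rotation about template z):
    # R = R_axis @ Rz(inplane)
    candidates: list[Rotation] = []
    for axis in axes:
        # rotation taking +z to `axis` with no superfluous twist
        zax = np.array([0.0, 0.0, 1.0])
        v = np.cross(zax, axis)
        c = float(np.dot(zax, axis))
        if np.linalg.norm(v) < 1e-12:
            r_axis = Rotation.identity() if c > 0 else Rotation.from_euler(
                "x", 180, degrees=True)
        else:
            angle = np.arccos(np.clip(c, -1, 1))
            r_axis = Rotation.from_rotvec(v / np.linalg.norm(v) * angle)
        for ang in inplane_angles:
            candidates.append(r_axis * Rotation.from_euler("z", ang, degrees=True))

    kept: list[Rotation] = []
    kept_quats: list[np.ndarray] = []
    for rot in candidates:
        is_dup = False
        if kept:
            # |<q1, q2>| close to 1  <=>  small geodesic distance
            q_orbit = (rot * group_quats).as_quat() if len(group) > 1 \
                else rot.as_quat()[None, :]
            dots = np.abs(np.asarray(kept_quats) @ q_orbit.T)
            if dots.max() > tol:
                is_dup = True
        if not is_dup:
            kept.append(rot)
            kept_quats.append(rot.as_quat())
    orientations = [matrix_to_euler(r.as_matrix()) for r in kept]
    return OrientationGrid(orientations=orientations,
                           cone_sampling=cone_sampling, cone_range=cone_range,
                           inplane_sampling=inplane_sampling,
                           inplane_range=inplane_range, symmetry=symmetry,
                           matrices=np.stack([r.as_matrix() for r in kept]))


# ---------------------------------------------------------------------------
# Wedge masks
# ---------------------------------------------------------------------------

@dataclass
class WedgeSpec:
    """Single-axis tilt geometry for Fourier-space sampling masks.

    ``tilt_angles`` in degrees (tilt about the volume y axis); ``soft_edge_width``
    in Fourier voxels (0 = binary mask).
    """

    tilt_angles: tuple
    soft_edge_width: float = 0.0

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.tilt_angles)
        if len(angles) == 0:
            raise GeometryError("empty tilt list")
        if any(not (-90.0 < a < 90.0) for a in angles):
            raise GeometryError("tilt angles must lie in (-90, 90) degrees")
        object.__setattr__(self, "tilt_angles", angles)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float,
                   soft_edge_width: float = 0.0) -> "WedgeSpec":
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(start + i * step for i in range(n)), soft_edge_width)


def wedge_mask(spec: WedgeSpec, box_shape: tuple[int, int, int]) -> np.ndarray:
    """Fourier-domain sampling mask for a single-axis tilt geometry.

    A Fourier voxel is sampled when it lies within half a voxel of a central
    section whose normal is the beam direction of some tilt in the continuously
    covered range ``[min(tilts), max(tilts)]``.  The mask is constant along the
    tilt axis (ky), Hermitian-symmetric, and laid out in numpy fft order.
    An optional cosine ramp of ``soft_edge_width`` Fourier voxels softens the
    boundary.
    """
    nx, ny, nz = box_shape
    kx = np.fft.fftfreq(nx) * nx
    kz = np.fft.fftfreq(nz) * nz
    KX, KZ = np.meshgrid(kx, kz, indexing="ij")
    theta_min = np.radians(min(spec.tilt_angles))
    theta_max = np.radians(max(spec.tilt_angles))

    # distance (in voxels) from (kx,kz) to the nearest sampled central section:
    # section at tilt theta has normal n = (sin t, 0, cos t); d = |kx sin t + kz cos t|
    rho = np.hypot(KX, KZ)
    # kx sin t + kz cos t = rho * sin(t + gamma), gamma = atan2(kz, kx)
    gamma = np.arctan2(KZ, KX)
    lo = theta_min + gamma
    hi = theta_max + gamma
    # min over t in [lo,hi] of |sin|: zero iff the interval straddles a multiple of pi
    k_lo = np.ceil(lo / np.pi)
    straddles = (k_lo * np.pi) <= hi
    end_min = np.minimum(np.abs(np.sin(lo)), np.abs(np.sin(hi)))
    dist = np.where(straddles, 0.0, rho * end_min)

    half_thickness = 0.5  # central-section thickness: 1 Fourier voxel
    if spec.soft_edge_width > 0:
        ramp = (dist - half_thickness) / spec.soft_edge_width
        mask2d = np.where(dist <= half_thickness, 1.0,
                          np.where(ramp >= 1.0, 0.0,
                                   0.5 * (1.0 + np.cos(np.pi * np.clip(ramp, 0, 1)))))
    else:
        mask2d = (dist <= half_thickness).astype(float)
    return np.broadcast_to(mask2d[:, None, :], (nx, ny, nz)).copy()


# ---------------------------------------------------------------------------
# Real-space rotation and symmetrization
# ---------------------------------------------------------------------------

def rotate_volume(volume: np.ndarray, matrix: np.ndarray,
                  order: int = 1) -> np.ndarray:
    """Actively rotate a volume about its center (linear interpolation by default).

    ``matrix`` maps template-frame coordinates to rotated-frame coordinates; the
    resampling therefore pulls with the inverse operator.
    """
    matrix = np.asarray(matrix, dtype=float)
    center = (np.array(volume.shape) - 1) / 2.0
    inv = matrix.T  # inverse of a rotation
    offset = center - inv @ center
    return affine_transform(volume, inv, offset=offset, order=order,
                            mode="constant", cval=0.0, prefilter=order > 1)


def symmetrize(volume: np.ndarray, symmetry: str) -> np.ndarray:
    """Average over the orbit of the point group (mean of rotated copies)."""
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise GeometryError("symmetrize expects a cubic volume")
    group = symmetry_group(symmetry)
    if len(group) == 1:
        return volume.copy()
    acc = np.zeros_like(volume, dtype=float)
    for rot in group.rotations:
        acc += rotate_volume(volume, rot)
    return acc / len(group)
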