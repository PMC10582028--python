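"""Synthetic ground-truth data: phantoms, particle fields, tilt series.

The generator emulates a dose-symmetric single-axis acquisition of a volume
containing copies of a density phantom at random poses, with CTF modulation,
additive Gaussian noise and optional gold beads.  Default acquisition geometry
is -45..+45 degrees in 3-degree increments (31 images), tilting about the
volume y axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.ndimage import affine_transform

from .errors import SimulationError
from .geometry import Orientation, euler_to_matrix, matrix_to_euler, rotate_volume
from .ctf import CtfParams, apply_ctf
from .formats_io import ParticleRecord, write_mrc, write_table

__all__ = [
    "TiltScheme",
    "GroundTruth",
    "TiltSeries",
    "make_phantom",
    "place_particles",
    "render_specimen",
    "simulate_tilt_series",
    "degrade_to_snr",
]


# ---------------------------------------------------------------------------
# Tilt scheme
# ---------------------------------------------------------------------------

@dataclass
class TiltScheme:
    """Angular range, increment, acquisition ordering and per-image dose.

    ``ordering`` is ``"dose-symmetric"`` (Hagen-style, groups of ``group_size``
    per branch, starting on the positive branch) or ``"sequential"``.
    ``zero_tilt_dose`` optionally overrides the dose of the 0-degree image,
    emulating hybrid schemes that spend extra dose on the untilted view.
    """

    start: float = -45.0
    stop: float = 45.0
    increment: float = 3.0
    ordering: str = "dose-symmetric"
    dose_per_tilt: float = 3.0  # e-/A^2
    zero_tilt_dose: float | None = None
    group_size: int = 2

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise SimulationError("tilt scheme needs start < stop")
        if not self.increment > 0:
            raise SimulationError("tilt increment must be > 0")

    @property
    def angles(self) -> np.ndarray:
        """Tilt angles sorted ascending (the on-disk image order)."""
        n = int(round((self.stop - self.start) / self.increment)) + 1
        return self.start + np.arange(n) * self.increment

    def acquisition_order(self) -> np.ndarray:
        """Indices into :attr:`angles` in the order the images were acquired."""
        angles = self.angles
        if self.ordering == "sequential":
            return np.arange(len(angles))
        if self.ordering != "dose-symmetric":
            raise SimulationError(f"unknown ordering '{self.ordering}'")
        zero = int(np.argmin(np.abs(angles)))
        pos = list(range(zero + 1, len(angles)))       # increasing positive tilts
        neg = list(range(zero - 1, -1, -1))            # decreasing negative tilts
        # Hagen-style grouping: the zero image opens the first (positive) group,
        # then branches alternate in full groups: 0,+3 | -3,-6 | +6,+9 | ...
        order = [zero]
        take_positive = True
        first_group = True
        while pos or neg:
            branch = pos if (take_positive and pos) or not neg else neg
            count = self.group_size - 1 if first_group else self.group_size
            for _ in range(max(count, 1)):
                if branch:
                    order.append(branch.pop(0))
            first_group = False
            take_positive = not take_positive
        return np.array(order)

    def dose_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-image dose, pre-exposure) in on-disk (angle-sorted) order.

        Pre-exposure is the dose accumulated before each image was recorded,
        following the acquisition order; non-decreasing along acquisition.
        """
        angles = self.angles
        dose = np.full(len(angles), float(self.dose_per_tilt))
        if self.zero_tilt_dose is not None:
            dose[int(np.argmin(np.abs(angles)))] = float(self.zero_tilt_dose)
        order = self.acquisition_order()
        pre = np.zeros(len(angles))
        acc = 0.0
        for idx in order:
            pre[idx] = acc
            acc += dose[idx]
        return dose, pre


@dataclass
class TiltSeries:
    """Image stack sorted by tilt angle, with per-image acquisition metadata."""

    images: np.ndarray  # (n_tilts, nx, ny)
    tilt_angles: np.ndarray  # degrees, ascending
    acquisition_index: np.ndarray  # position of each image in acquisition order
    accumulated_dose: np.ndarray  # pre-exposure per image, e-/A^2
    defocus: np.ndarray  # per-image defocus, um (positive underfocus)
    pixel_size: float = 1.0  # Angstrom

    def __len__(self) -> int:
        return self.images.shape[0]

    def write(self, stack_path: str | Path, metadata_path: str | Path | None = None) -> Path:
        """MRC stack plus a sidecar JSON of per-image metadata."""
        stack_path = Path(stack_path)
        write_mrc(self.images.transpose(1, 2, 0), stack_path,
                  voxel_size=self.pixel_size)
        if metadata_path is None:
            metadata_path = stack_path.with_suffix(".json")
        meta = {
            "pixel_size": self.pixel_size,
            "tilt_angles": [float(a) for a in self.tilt_angles],
            "acquisition_index": [int(i) for i in self.acquisition_index],
            "accumulated_dose": [float(d) for d in self.accumulated_dose],
            "defocus_um": [float(d) for d in self.defocus],
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=1))
        return stack_path

    @classmethod
    def read(cls, stack_path: str | Path,
             metadata_path: str | Path | None = None) -> "TiltSeries":
        from .formats_io import read_mrc
        stack_path = Path(stack_path)
        vol, header = read_mrc(stack_path)
        images = vol.transpose(2, 0, 1)
        if metadata_path is None:
            metadata_path = stack_path.with_suffix(".json")
        meta = json.loads(Path(metadata_path).read_text())
        return cls(images=images,
                   tilt_angles=np.array(meta["tilt_angles"]),
                   acquisition_index=np.array(meta["acquisition_index"]),
                   accumulated_dose=np.array(meta["accumulated_dose"]),
                   defocus=np.array(meta["defocus_um"]),
                   pixel_size=meta.get("pixel_size", header.voxel_size))


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def _soft_step(distance: np.ndarray, edge: float) -> np.ndarray:
    """Cosine step across a surface: 1 inside, 0.5 at distance 0, 0 outside.

    The ramp spans [-edge/2, +edge/2] so the half-max isosurface coincides with
    the nominal geometric surface.
    """
    t = np.clip(distance / max(edge, 1e-9) + 0.5, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def make_phantom(kind: str, box: int, params: dict | None = None) -> np.ndarray:
    """Density phantom, centered, non-negative, zero at the box faces.

    Kinds: ``torus`` (a bagel, ring radius R / tube radius r), ``sphere``
    (radius), ``asymmetric-blob`` (sum of displaced Gaussians, seeded).
    """
    if box < 16:
        raise SimulationError("phantom box must be >= 16")
    params = dict(params or {})
    c = (box - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(box) - c,) * 3, indexing="ij")
    edge = float(params.pop("edge", 2.0))
    if kind == "torus":
        ring = float(params.pop("ring_radius", box / 5.0))
        tube = float(params.pop("tube_radius", box / 10.0))
        if ring + tube + edge >= box / 2.0:
            raise SimulationError("torus radii exceed the box")
        d = np.sqrt((np.hypot(x, y) - ring) ** 2 + z ** 2) - tube
        vol = _soft_step(d, edge)
    elif kind == "sphere":
        radius = float(params.pop("radius", box / 4.0))
        if radius + edge >= box / 2.0:
            raise SimulationError("sphere radius exceeds the box")
        d = np.sqrt(x ** 2 + y ** 2 + z ** 2) - radius
        vol = _soft_step(d, edge)
    elif kind == "asymmetric-blob":
        seed = int(params.pop("seed", 0))
        n_blobs = int(params.pop("n_blobs", 6))
        spread = float(params.pop("spread", box / 6.0))
        sigma = float(params.pop("sigma", box / 12.0))
        rng = np.random.default_rng(seed)
        vol = np.zeros((box, box, box))
        for _ in range(n_blobs):
            pos = rng.uniform(-spread, spread, size=3)
            amp = rng.uniform(0.5, 1.0)
            vol += amp * np.exp(-(((x - pos[0]) ** 2 + (y - pos[1]) ** 2 +
                                   (z - pos[2]) ** 2) / (2 * sigma ** 2)))
    else:
        raise SimulationError(f"unknown phantom kind '{kind}'")
    if params:
        raise SimulationError(f"unknown phantom parameter(s): {sorted(params)}")
    # enforce exact zeros on the faces via a soft box-edge window
    face_dist = np.minimum.reduce([
        x + c, c - x, y + c, c - y, z + c, c - z])
    vol = vol * np.clip(face_dist / 1.5, 0.0, 1.0)
    return vol


# ---------------------------------------------------------------------------
# Particle placement and rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True particle poses (0-based positions) and bead positions for a specimen."""

    positions: np.ndarray  # (n, 3) voxels, 0-based
    orientations: list[Orientation]
    bead_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    seed: int = 0
    snr: float | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def to_records(self, tomogram_id: int = 1) -> list[ParticleRecord]:
        recs = []
        for i, (pos, ori) in enumerate(zip(self.positions, self.orientations)):
            recs.append(ParticleRecord(
                tag=i + 1, cc=1.0,
                x=int(round(pos[0])) + 1, y=int(round(pos[1])) + 1,
                z=int(round(pos[2])) + 1,
                tdrot=ori.tdrot, tilt=ori.tilt, narot=ori.narot,
                tomogram_id=tomogram_id))
        return recs

    def write_table(self, path: str | Path) -> Path:
        return write_table(self.to_records(), path)


def _random_rotation(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def place_particles(volume_shape: tuple[int, int, int], n: int,
                    min_dist: float, border: float, seed: int,
                    n_beads: int = 0) -> GroundTruth:
    """Uniform random placement with a hard pairwise minimum distance.

    Orientations are Haar-uniform (normalized-Gaussian quaternions).  Raises
    :class:`SimulationError` when the packing request is infeasible or when
    bounded rejection sampling cannot satisfy it.
    """
    shape = np.asarray(volume_shape, dtype=float)
    placeable = np.prod(np.maximum(shape - 2 * border, 0))
    exclusion = (4.0 / 3.0) * np.pi * (min_dist / 2.0) ** 3
    if placeable <= 0 or n * exclusion > 0.5 * placeable:
        raise SimulationError(
            f"infeasible packing: {n} particles with min_dist={min_dist} in "
            f"{volume_shape} (border {border})")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * n
    while len(positions) < n:
        if attempts >= max_attempts:
            raise SimulationError(
                f"placement failed after {max_attempts} attempts: min_dist="
                f"{min_dist} too restrictive for {volume_shape}")
        attempts += 1
        cand = rng.uniform(border, shape - border)
        if all(np.linalg.norm(cand - p) >= min_dist for p in positions):
            positions.append(cand)
    orientations = [matrix_to_euler(_random_rotation(rng).as_matrix())
                    for _ in range(n)]
    beads = rng.uniform(border / 2, shape - border / 2, size=(n_beads, 3)) \
        if n_beads else np.zeros((0, 3))
    return GroundTruth(positions=np.array(positions), orientations=orientations,
                       bead_positions=beads, seed=seed)


def render_specimen(ground_truth: GroundTruth, phantom: np.ndarray,
                    volume_shape: tuple[int, int, int],
                    bead_params: dict | None = None) -> np.ndarray:
    """Paste rotated phantom copies (and optional beads) into an empty volume.

    Beads are solid soft-edged spheres of ``bead_params['diameter']`` voxels at
    ``bead_params['density']`` times the phantom peak density.  Overlaps add.
    """
    volume = np.zeros(volume_shape, dtype=np.float32)
    box = phantom.shape[0]
    half = box // 2
    for pos, ori in zip(ground_truth.positions, ground_truth.orientations):
        rotated = rotate_volume(phantom, euler_to_matrix(ori))
        # sub-voxel placement via the interpolating paste
        ipos = np.floor(pos).astype(int)
        frac = pos - ipos
        if np.any(frac > 1e-6):
            shift_mat = np.eye(3)
            center = (np.array(rotated.shape) - 1) / 2.0
            rotated = affine_transform(rotated, shift_mat,
                                       offset=-frac, order=1, mode="constant")
        lo = ipos - half
        hi = lo + box
        src_lo = np.maximum(0, -lo)
        src_hi = box - np.maximum(0, hi - np.array(volume_shape))
        dst_lo = np.maximum(lo, 0)
        dst_hi = np.minimum(hi, np.array(volume_shape))
        if np.any(src_hi <= src_lo):
            continue
        volume[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] += \
            rotated[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    if len(ground_truth.bead_positions):
        bead_params = dict(bead_params or {})
        diameter = float(bead_params.get("diameter", 10.0))
        density = float(bead_params.get("density", 10.0)) * \
            (phantom.max() if phantom.size else 1.0)
        r = diameter / 2.0
        ir = int(np.ceil(r + 2))
        gx, gy, gz = np.meshgrid(*(np.arange(-ir, ir + 1),) * 3, indexing="ij")
        d = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2) - r
        bead = density * _soft_step(d, 1.0)
        for pos in ground_truth.bead_positions:
            ipos = np.round(pos).astype(int)
            lo = ipos - ir
            hi = lo + bead.shape[0]
            src_lo = np.maximum(0, -lo)
            src_hi = bead.shape[0] - np.maximum(0, hi - np.array(volume_shape))
            dst_lo = np.maximum(lo, 0)
            dst_hi = np.minimum(hi, np.array(volume_shape))
            if np.any(src_hi <= src_lo):
                continue
            volume[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] += \
                bead[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return volume


# ---------------------------------------------------------------------------
# Tilt-series simulation
# ---------------------------------------------------------------------------

def project(volume: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Parallel-beam projection at one tilt (about y): rotate, then sum along z."""
    if abs(tilt_deg) < 1e-12:
        return volume.sum(axis=2)
    theta = np.radians(tilt_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return rotate_volume(volume, rot_y).sum(axis=2)


def simulate_tilt_series(specimen: np.ndarray, tilt_scheme: TiltScheme,
                         ctf_params: CtfParams | None = None,
                         noise_sigma: float = 0.0, seed: int = 0,
                         defocus_spread: float = 0.0) -> TiltSeries:
    """Project the specimen at every scheme angle, CTF-modulate, add noise.

    Per-image defocus is ``ctf_params.defocus`` plus a deterministic
    acquisition-order ramp of total amplitude ``defocus_spread`` (um), standing
    in for focus drift.  Images are returned sorted by tilt angle; the
    acquisition order, accumulated dose, and defocus ride along as metadata.
    """
    if noise_sigma < 0:
        raise SimulationError("noise_sigma must be >= 0")
    if not np.all(np.isfinite(specimen)):
        raise SimulationError("specimen contains non-finite voxels")
    angles = tilt_scheme.angles
    order = tilt_scheme.acquisition_order()
    _, pre_exposure = tilt_scheme.dose_table()
    acq_position = np.empty(len(angles), dtype=int)
    acq_position[order] = np.arange(len(angles))

    pixel = ctf_params.pixel_size if ctf_params is not None else 1.0
    base_defocus = ctf_params.defocus if ctf_params is not None else 0.0
    n = len(angles)
    defoci = base_defocus + defocus_spread * (acq_position / max(n - 1, 1) - 0.5)

    rng = np.random.default_rng(seed)
    images = np.empty((n, specimen.shape[0], specimen.shape[1]), dtype=np.float32)
    for i, angle in enumerate(angles):
        img = project(specimen, angle)
        if ctf_params is not None:
            img = apply_ctf(img, ctf_params.with_defocus(defoci[i]))
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        images[i] = img
    return TiltSeries(images=images, tilt_angles=angles,
                      acquisition_index=acq_position,
                      accumulated_dose=pre_exposure, defocus=defoci,
                      pixel_size=pixel)


def degrade_to_snr(images: np.ndarray, target_snr: float, seed: int = 0,
                   snr_cap: float = 1e6) -> np.ndarray:
    """Add white Gaussian noise so signal-variance / noise-variance = target_snr."""
    if not target_snr > 0:
        raise SimulationError("target_snr must be > 0")
    images = np.asarray(images, dtype=np.float32)
    sig_var = float(images.var())
    if sig_var == 0:
        raise SimulationError("zero-variance input: SNR undefined")
    if target_snr >= snr_cap:
        return images.copy()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(sig_var / target_snr)
    return images + rng.normal(0.0, sigma, size=images.shape).astype(np.float32)
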