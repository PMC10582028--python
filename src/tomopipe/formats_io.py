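"""On-disk formats: MRC2014 volumes/stacks, particle tables, STAR export, JSON config.

Conventions
-----------
* In-memory volumes are numpy arrays indexed ``[x, y, z]`` (and images ``[x, y]``);
  on disk the MRC x axis is fastest, so arrays are transposed at the I/O boundary.
* Particle tables are plain-text, whitespace-separated, one row per particle, with a
  fixed documented column order (see :class:`ParticleRecord`).  Positions in tables
  are 1-based voxel indices; all computation is 0-based.  Records keep the table
  convention verbatim; ``ParticleRecord.position`` yields the 0-based coordinate.
* Config merging is whole-file validate-then-merge: any unknown key or type mismatch
  fails before a pipeline run starts.
"""

from __future__ import annotations

import json
import math
import struct
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, FormatError

__all__ = [
    "VolumeHeaderInfo",
    "ParticleRecord",
    "EffectiveConfig",
    "read_mrc",
    "write_mrc",
    "read_table",
    "write_table",
    "records_to_array",
    "array_to_records",
    "export_star",
    "read_star",
    "load_defaults",
    "merge_config",
]

# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_HEADER_SIZE = 1024
_MODE_DTYPES = {
    0: np.int8,
    1: np.int16,
    2: np.float32,
    6: np.uint16,
    12: np.float16,
}


@dataclass
class VolumeHeaderInfo:
    """Subset of the MRC2014 header the pipeline cares about."""

    shape: tuple[int, int, int]  # (nx, ny, nz)
    voxel_size: float  # Angstrom
    mode: int = 2
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise FormatError(f"non-positive MRC shape {self.shape}")
        if not self.voxel_size > 0:
            raise FormatError(f"non-positive voxel size {self.voxel_size}")


def read_mrc(path: str | Path) -> tuple[np.ndarray, VolumeHeaderInfo]:
    """Read an MRC2014 volume or stack.

    Returns the data as a float array indexed ``[x, y, z]`` and the header info.
    Only axis order mapc,mapr,maps = 1,2,3 (the overwhelmingly common layout) is
    supported; anything else raises :class:`FormatError`.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise FormatError(f"{path}: file too short for an MRC header "
                          f"({len(raw)} < {_MRC_HEADER_SIZE} bytes)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    mapc, mapr, maps_ = struct.unpack_from("<3i", raw, 64)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    origin = struct.unpack_from("<3f", raw, 196)
    map_id = raw[208:212]
    if map_id not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: bad MAP identifier {map_id!r} (field 'map')")
    if mode not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (field 'mode')")
    if (mapc, mapr, maps_) != (1, 2, 3):
        raise FormatError(f"{path}: unsupported axis order mapc,mapr,maps="
                          f"{(mapc, mapr, maps_)}")
    if min(nx, ny, nz) <= 0:
        raise FormatError(f"{path}: non-positive dimensions {(nx, ny, nz)} (field 'nx/ny/nz')")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    count = nx * ny * nz
    offset = _MRC_HEADER_SIZE + nsymbt
    expected = offset + count * dtype.itemsize
    if len(raw) < expected:
        raise FormatError(f"{path}: truncated data section "
                          f"({len(raw)} < {expected} bytes)")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    # disk order is z-slowest; bring to [x, y, z]
    volume = np.ascontiguousarray(data.reshape(nz, ny, nx).transpose(2, 1, 0))
    if mx <= 0 or cella[0] <= 0:
        voxel = 1.0
    else:
        voxel = cella[0] / mx
    header = VolumeHeaderInfo(shape=(nx, ny, nz), voxel_size=float(voxel),
                              mode=mode, origin=tuple(origin))
    return volume.astype(np.float32) if mode != 2 else volume, header


def write_mrc(volume: np.ndarray, path: str | Path,
              voxel_size: float = 1.0,
              origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Path:
    """Write ``volume`` (indexed ``[x, y, z]``, or 2D ``[x, y]``) as MRC2014 mode 2."""
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[:, :, None]
    if volume.ndim != 3:
        raise FormatError(f"expected 2D or 3D data, got ndim={volume.ndim}")
    if not np.all(np.isfinite(volume)):
        raise FormatError("refusing to write non-finite voxel data")
    if not voxel_size > 0:
        raise FormatError(f"non-positive voxel size {voxel_size}")
    vol32 = volume.astype("<f4", copy=False)
    nx, ny, nz = vol32.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(vol32.min()), float(vol32.max()),
                     float(vol32.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    struct.pack_into("<i", header, 108, 20140)  # nversion
    struct.pack_into("<3f", header, 196, *origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0, 0))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(vol32.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(vol32.transpose(2, 1, 0)).tobytes())
    return path


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

#: column order of the table dialect (one row per particle)
TABLE_COLUMNS = (
    "tag", "cc", "x", "y", "z", "dx", "dy", "dz",
    "tdrot", "tilt", "narot", "class_id", "tomogram_id", "half_set",
)


@dataclass
class ParticleRecord:
    """One particle-table row.

    ``x, y, z`` are 1-based integer voxel positions (table dialect); ``dx, dy, dz``
    sub-voxel shifts in voxels; ``tdrot, tilt, narot`` ZXZ Euler angles in degrees;
    ``half_set`` is 1 or 2, or 0 when unassigned.
    """

    tag: int
    cc: float = 0.0
    x: int = 1
    y: int = 1
    z: int = 1
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    tdrot: float = 0.0
    tilt: float = 0.0
    narot: float = 0.0
    class_id: int = 0
    tomogram_id: int = 1
    half_set: int = 0

    def __post_init__(self) -> None:
        for name in TABLE_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise FormatError(f"particle {self.tag}: non-finite field {name}")

    @property
    def position(self) -> np.ndarray:
        """0-based floating-point position (x,y,z) including sub-voxel shift."""
        return np.array([self.x - 1 + self.dx, self.y - 1 + self.dy,
                         self.z - 1 + self.dz])


def write_table(records: Sequence[ParticleRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for rec in records:
        vals = []
        for name in TABLE_COLUMNS:
            v = getattr(rec, name)
            if name in ("tag", "x", "y", "z", "class_id", "tomogram_id", "half_set"):
                vals.append(str(int(v)))
            else:
                vals.append(f"{float(v):.8g}")
        lines.append(" ".join(vals))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_table(path: str | Path) -> list[ParticleRecord]:
    path = Path(path)
    records: list[ParticleRecord] = []
    n_expected = len(TABLE_COLUMNS)
    warned_extra = False
    seen_tags: set[int] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < n_expected:
            raise FormatError(f"{path}:{lineno}: expected {n_expected} columns, "
                              f"got {len(parts)}")
        if len(parts) > n_expected and not warned_extra:
            warnings.warn(f"{path}:{lineno}: ignoring {len(parts) - n_expected} "
                          "extra trailing column(s)")
            warned_extra = True
        try:
            values = [float(p) for p in parts[:n_expected]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        kwargs = {}
        for name, v in zip(TABLE_COLUMNS, values):
            if name in ("tag", "x", "y", "z", "class_id", "tomogram_id", "half_set"):
                kwargs[name] = int(round(v))
            else:
                kwargs[name] = v
        rec = ParticleRecord(**kwargs)
        if rec.tag in seen_tags:
            raise FormatError(f"{path}:{lineno}: duplicate tag {rec.tag}")
        seen_tags.add(rec.tag)
        records.append(rec)
    return records


def records_to_array(records: Sequence[ParticleRecord]) -> np.ndarray:
    """Tables as a dense (n, 14) float array in TABLE_COLUMNS order."""
    return np.array([[float(getattr(r, c)) for c in TABLE_COLUMNS] for r in records],
                    dtype=float).reshape(len(records), len(TABLE_COLUMNS))


def array_to_records(arr: np.ndarray) -> list[ParticleRecord]:
    out = []
    for row in np.atleast_2d(arr):
        kwargs = {}
        for name, v in zip(TABLE_COLUMNS, row):
            if name in ("tag", "x", "y", "z", "class_id", "tomogram_id", "half_set"):
                kwargs[name] = int(round(float(v)))
            else:
                kwargs[name] = float(v)
        out.append(ParticleRecord(**kwargs))
    return out


# ---------------------------------------------------------------------------
# STAR export
# ---------------------------------------------------------------------------

_PARTICLE_LOOP = (
    "_tomoParticleTag", "_tomoName", "_coordinateX", "_coordinateY", "_coordinateZ",
    "_angleRot", "_angleTilt", "_anglePsi", "_crossCorrelation", "_classNumber",
    "_halfSet",
)
_TOMO_LOOP = ("_tomoName", "_tiltIndex", "_tiltAngle", "_preExposure")


def _zxz_to_zyz(tdrot: float, tilt: float, narot: float) -> tuple[float, float, float]:
    """Map the internal ZXZ Euler triplet to the export ZYZ (rot, tilt, psi) triplet."""
    from .geometry import Orientation, euler_to_matrix
    from scipy.spatial.transform import Rotation

    mat = euler_to_matrix(Orientation(tdrot, tilt, narot))
    with warnings.catch_warnings():
        # zero-tilt gimbal degeneracy is fine; any equivalent triplet exports
        warnings.simplefilter("ignore", UserWarning)
        rot, t, psi = Rotation.from_matrix(mat).as_euler("ZYZ", degrees=True)
    return float(rot), float(t), float(psi)


def export_star(records: Sequence[ParticleRecord],
                tomogram_descriptions: dict[int, str],
                dose_table: dict[int, Sequence[tuple[float, float]]],
                path: str | Path) -> Path:
    """Write a two-block STAR file: particles plus per-tomogram tilt/dose rows.

    ``tomogram_descriptions`` maps tomogram_id -> tomogram name;
    ``dose_table`` maps tomogram_id -> sequence of (tilt_angle_deg,
    pre_exposure_e_per_A2) in on-disk tilt order.  Pre-exposure is the dose
    accumulated *before* each image was taken, so uneven schemes (a high-dose
    zero-tilt image) are represented faithfully.
    """
    path = Path(path)
    for rec in records:
        if rec.tomogram_id not in tomogram_descriptions:
            raise FormatError(f"particle {rec.tag}: no description for tomogram "
                              f"{rec.tomogram_id}")
    lines = ["# tomopipe STAR export", "", "data_particles", "", "loop_"]
    lines += [f"{name} #{i + 1}" for i, name in enumerate(_PARTICLE_LOOP)]
    for rec in records:
        rot, t, psi = _zxz_to_zyz(rec.tdrot, rec.tilt, rec.narot)
        name = tomogram_descriptions[rec.tomogram_id]
        lines.append(
            f"{rec.tag} {name} {rec.x - 1 + rec.dx:.6f} {rec.y - 1 + rec.dy:.6f} "
            f"{rec.z - 1 + rec.dz:.6f} {rot:.6f} {t:.6f} {psi:.6f} "
            f"{rec.cc:.6f} {rec.class_id} {rec.half_set}")
    lines += ["", "data_tomograms", "", "loop_"]
    lines += [f"{name} #{i + 1}" for i, name in enumerate(_TOMO_LOOP)]
    for tomo_id, name in tomogram_descriptions.items():
        for idx, (angle, pre_exposure) in enumerate(dose_table.get(tomo_id, [])):
            lines.append(f"{name} {idx} {angle:.3f} {pre_exposure:.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_star(path: str | Path) -> dict[str, list[dict[str, str]]]:
    """Minimal STAR reader: returns {block_name: [row dicts]} for loop_ blocks."""
    blocks: dict[str, list[dict[str, str]]] = {}
    block = None
    columns: list[str] = []
    in_loop_header = False
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_"):
            block = stripped[len("data_"):]
            blocks[block] = []
            columns = []
            in_loop_header = False
        elif stripped == "loop_":
            in_loop_header = True
            columns = []
        elif stripped.startswith("_"):
            if in_loop_header:
                columns.append(stripped.split()[0])
        else:
            in_loop_header = False
            if block is None or not columns:
                raise FormatError(f"{path}: data row outside a loop_ block")
            parts = stripped.split()
            if len(parts) != len(columns):
                raise FormatError(f"{path}: row has {len(parts)} fields, "
                                  f"expected {len(columns)}")
            blocks[block].append(dict(zip(columns, parts)))
    return blocks


# ---------------------------------------------------------------------------
# JSON configuration with defaults merging
# ---------------------------------------------------------------------------

_DEFAULTS_PATH = Path(__file__).with_name("defaults.json")


def load_defaults() -> dict:
    return json.loads(_DEFAULTS_PATH.read_text())


@dataclass
class EffectiveConfig:
    """Fully merged configuration: ``general`` plus ordered module sections.

    ``provenance`` records for every resolved key whether it came from the
    defaults file or the user config (``"default"`` / ``"user"``).
    """

    general: dict
    modules: list[tuple[str, dict]]
    provenance: dict[str, str] = field(default_factory=dict)

    def to_user_dict(self) -> dict:
        """Re-serialize as a user-config document (for idempotent re-merging)."""
        return {"general": dict(self.general),
                "modules": [{"name": name, "params": dict(params)}
                            for name, params in self.modules]}


def _type_compatible(default_value, user_value) -> bool:
    if isinstance(default_value, bool) or isinstance(user_value, bool):
        return isinstance(default_value, bool) == isinstance(user_value, bool)
    if isinstance(default_value, (int, float)):
        return isinstance(user_value, (int, float))
    return isinstance(user_value, type(default_value))


def merge_config(defaults: dict, user: dict) -> EffectiveConfig:
    """Validate + deep-merge a user config against the defaults document.

    The defaults document has the shape ``{"general": {...}, "modules":
    {module_name: {param: default}}}``; the user document has an ordered
    ``modules`` list of ``{"name": ..., "params": {...}}`` entries.  User values
    win; unknown module names and unknown per-module keys fail fast.
    """
    if "general" not in user:
        raise ConfigError("user configuration is missing the 'general' section")
    if "modules" not in user or not isinstance(user["modules"], list):
        raise ConfigError("user configuration needs an ordered 'modules' list")

    known_modules = defaults.get("modules", {})
    general = dict(defaults.get("general", {}))
    provenance = {f"general.{k}": "default" for k in general}
    for key, value in user["general"].items():
        if key in general and not _type_compatible(general[key], value):
            raise ConfigError(f"general.{key}: type mismatch "
                              f"({type(value).__name__} vs "
                              f"{type(general[key]).__name__} in defaults)")
        general[key] = value
        provenance[f"general.{key}"] = "user"
    if "pixel_size" in general and not float(general["pixel_size"]) > 0:
        raise ConfigError("general.pixel_size must be > 0")

    modules: list[tuple[str, dict]] = []
    for entry in user["modules"]:
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError(f"malformed module entry {entry!r}: needs a 'name'")
        name = entry["name"]
        if name not in known_modules:
            raise ConfigError(f"unknown module '{name}' (known: "
                              f"{', '.join(sorted(known_modules))})")
        params = dict(known_modules[name])
        for key in params:
            provenance[f"{name}.{key}"] = "default"
        user_params = entry.get("params", {})
        for key, value in user_params.items():
            if key not in params:
                raise ConfigError(f"module '{name}': unknown key '{key}'")
            if params[key] is not None and not _type_compatible(params[key], value):
                raise ConfigError(f"module '{name}': key '{key}' type mismatch "
                                  f"({type(value).__name__} vs "
                                  f"{type(params[key]).__name__} in defaults)")
            params[key] = value
            provenance[f"{name}.{key}"] = "user"
        unresolved = [k for k, v in params.items() if v is None]
        if unresolved:
            raise ConfigError(f"module '{name}': required key(s) without value: "
                              f"{', '.join(unresolved)}")
        modules.append((name, params))
    return EffectiveConfig(general=general, modules=modules, provenance=provenance)
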