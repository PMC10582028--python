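"""Resumable workflow engine: file sorting, ordered module execution with
SUCCESS-file semantics, selective re-execution, live reconstruction, cleanup.

Layout: one module-named folder per configured step (``01_simulate``,
``02_reconstruct``, ...), one item subfolder per tilt-series/tomogram
(zero-padded id).  A per-item ``SUCCESS`` marker means the item is done and is
skipped on re-runs; a module-level ``SUCCESS`` marker means every item
finished.  Deleting a marker re-executes exactly that scope.  Marker writes are
atomic (write-then-rename), so an interrupted run never leaves a marker for
unfinished work.  Items are independent by contract: one item's failure never
blocks its siblings.
"""

from __future__ import annotations

import json
import logging
import os
import re
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PipelineError, TomopipeError
from .formats_io import EffectiveConfig, write_mrc, read_mrc, write_table, read_table
from . import simulator as sim
from .ctf import CtfParams, estimate_defocus
from .reconstruction import wbp_reconstruct, fourier_crop, nad_denoise
from .geometry import generate_grid, WedgeSpec
from .template_matching import (prepare_template, match_template, postprocess_cc,
                                extract_peaks, taper_edges)

logger = logging.getLogger(__name__)

__all__ = [
    "sort_files",
    "run_pipeline",
    "run_live",
    "cleanup",
    "MODULE_REGISTRY",
]

SUCCESS = "SUCCESS"


def _write_marker(path: Path) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(time.strftime("%Y-%m-%d %H:%M:%S\n"))
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# File sorting
# ---------------------------------------------------------------------------

def _pattern_to_regex(name_pattern: str) -> re.Pattern:
    """Token pattern -> regex: ``{series}`` (int), ``{angle}`` (signed float),
    ``{order}`` (int, optional)."""
    out = ""
    i = 0
    tokens = {"series": r"(?P<series>\d+)",
              "angle": r"(?P<angle>[-+]?\d+(?:\.\d+)?)",
              "order": r"(?P<order>\d+)"}
    while i < len(name_pattern):
        ch = name_pattern[i]
        if ch == "{":
            j = name_pattern.index("}", i)
            token = name_pattern[i + 1:j]
            if token not in tokens:
                raise PipelineError(f"unknown pattern token '{{{token}}}'")
            out += tokens[token]
            i = j + 1
        else:
            out += re.escape(ch)
            i += 1
    return re.compile(out + r"$")


def sort_files(input_dir: str | Path, name_pattern: str = "TS_{series}_{angle}.mrc"
               ) -> dict:
    """Group files into tilt series by a token pattern, ordered by tilt angle.

    Returns ``{"series": {id: [(angle, path), ...]}, "unassigned": [...],
    "flagged": {...}}``.  Duplicate (series, angle) pairs raise; files matching
    no pattern are reported, not fatal.
    """
    input_dir = Path(input_dir)
    regex = _pattern_to_regex(name_pattern)
    series: dict[int, list[tuple[float, Path]]] = {}
    unassigned: list[str] = []
    seen: dict[tuple[int, float], Path] = {}
    for path in sorted(input_dir.iterdir()):
        if not path.is_file():
            continue
        m = regex.match(path.name)
        if not m:
            unassigned.append(path.name)
            continue
        sid = int(m.group("series"))
        angle = float(m.group("angle"))
        if (sid, angle) in seen:
            raise PipelineError(f"duplicate (series {sid}, angle {angle}): "
                                f"{seen[(sid, angle)].name} and {path.name}")
        seen[(sid, angle)] = path
        series.setdefault(sid, []).append((angle, path))
    if not series:
        logger.warning("no files matched pattern '%s' in %s", name_pattern, input_dir)
    flagged = {}
    for sid in series:
        series[sid].sort(key=lambda t: t[0])
        angles = np.array([a for a, _ in series[sid]])
        if len(angles) > 2:
            steps = np.diff(angles)
            if steps.max() > 1.5 * np.median(steps):
                flagged[sid] = "missing tilt angle(s)"
    return {"series": series, "unassigned": unassigned, "flagged": flagged,
            "counts": {sid: len(v) for sid, v in series.items()}}


# ---------------------------------------------------------------------------
# Pipeline modules
# ---------------------------------------------------------------------------

@dataclass
class PipelineContext:
    root: Path
    general: dict
    seed: int
    items: list[str] = field(default_factory=list)

    def item_seed(self, item_id: str, salt: int = 0) -> int:
        return (self.seed * 100003 + int(item_id) * 7919 + salt) % (2 ** 31)

    def save_items(self) -> None:
        (self.root / "items.json").write_text(json.dumps(self.items))

    def load_items(self) -> list[str]:
        path = self.root / "items.json"
        if path.exists():
            self.items = json.loads(path.read_text())
        return self.items


def _mod_simulate(ctx: PipelineContext, item: str, folder: Path, params: dict) -> None:
    """Generate one synthetic tilt series (phantom field + projections)."""
    rng_seed = ctx.item_seed(item)
    box = int(params["volume_xy"])
    thickness = int(params["thickness"])
    phantom = sim.make_phantom(params["phantom"], int(params["phantom_box"]))
    truth = sim.place_particles((box, box, thickness), int(params["n_particles"]),
                                float(params["min_dist"]),
                                float(params["border"]), rng_seed)
    specimen = sim.render_specimen(truth, phantom, (box, box, thickness))
    scheme = sim.TiltScheme(float(params["tilt_start"]), float(params["tilt_stop"]),
                            float(params["tilt_step"]),
                            dose_per_tilt=float(params["dose_per_tilt"]))
    ctf = CtfParams(defocus=float(params["defocus"]),
                    pixel_size=float(ctx.general.get("pixel_size", 1.0)))
    series = sim.simulate_tilt_series(specimen, scheme, ctf_params=ctf,
                                      noise_sigma=0.0, seed=rng_seed)
    if float(params["snr"]) > 0:
        series.images = sim.degrade_to_snr(series.images, float(params["snr"]),
                                           seed=rng_seed + 1)
    series.write(folder / "stack.mrc")
    truth.write_table(folder / "ground_truth.tbl")


def _mod_estimate_ctf(ctx: PipelineContext, item: str, folder: Path,
                      params: dict) -> None:
    series = sim.TiltSeries.read(_prev_file(ctx, folder, item, "stack.mrc"))
    base = CtfParams(pixel_size=series.pixel_size)
    results = []
    for i in range(len(series)):
        fit = estimate_defocus(series.images[i], base,
                               float(params["search_min"]),
                               float(params["search_max"]), float(params["step"]))
        results.append({"tilt_index": i, "defocus": fit["defocus"],
                        "score": fit["score"], "reliable": fit["reliable"]})
    (folder / "defocus.json").write_text(json.dumps(results, indent=1))
    with open(folder / "defocus.txt", "w") as fh:
        for r in results:
            fh.write(f"{r['tilt_index']} {r['defocus']:.4f}\n")


def _mod_reconstruct(ctx: PipelineContext, item: str, folder: Path,
                     params: dict) -> None:
    series = sim.TiltSeries.read(_prev_file(ctx, folder, item, "stack.mrc"))
    binning = int(params["binning"])
    if binning > 1:
        series.images = fourier_crop(series.images, binning, stack=True)
        series.pixel_size *= binning
    tomo = wbp_reconstruct(series, int(params["thickness"]) // binning,
                           params["filter"])
    if int(params["nad_iterations"]) > 0:
        tomo.volume = nad_denoise(tomo.volume, kappa=float(tomo.volume.std()),
                                  n_iterations=int(params["nad_iterations"])
                                  ).astype(np.float32)
    write_mrc(tomo.volume, folder / "tomogram.mrc", voxel_size=tomo.voxel_size)


def _mod_template_match(ctx: PipelineContext, item: str, folder: Path,
                        params: dict) -> None:
    volume, header = read_mrc(_prev_file(ctx, folder, item, "tomogram.mrc"))
    phantom = sim.make_phantom(params["template_phantom"],
                               int(params["template_box"]))
    template, mask = prepare_template(phantom, header.voxel_size,
                                      header.voxel_size,
                                      float(params["lowpass"]))
    grid = generate_grid(float(params["cone_sampling"]),
                         float(params["cone_range"]),
                         float(params["inplane_sampling"]),
                         float(params["inplane_range"]), params["symmetry"])
    wedge = WedgeSpec.from_range(float(params["tilt_start"]),
                                 float(params["tilt_stop"]),
                                 float(params["tilt_step"]))
    volume = taper_edges(volume, int(params["taper"]))
    result = match_template(volume, template, mask, grid, wedge_spec=wedge,
                            chunk_size=params["chunk_size"] or None)
    cc = postprocess_cc(result.cc_map, float(params["island_max_size"]))
    result.cc_map = cc
    write_mrc(result.cc_map, folder / "cc_map.mrc", voxel_size=header.voxel_size)
    write_mrc(result.orient_map.astype(np.float32), folder / "orient_map.mrc",
              voxel_size=header.voxel_size)
    records = extract_peaks(result,
                            threshold_sigma=float(params["threshold_sigma"]),
                            max_particles=int(params["max_particles"]),
                            exclusion_radius=float(params["exclusion_radius"]),
                            tomogram_id=int(item))
    write_table(records, folder / "particles.tbl")


MODULE_REGISTRY = {
    "simulate": _mod_simulate,
    "estimate_ctf": _mod_estimate_ctf,
    "reconstruct": _mod_reconstruct,
    "template_match": _mod_template_match,
}


def _prev_file(ctx: PipelineContext, folder: Path, item: str, name: str) -> Path:
    """Locate ``name`` for this item in the nearest preceding module folder."""
    module_dirs = sorted(ctx.root.glob("[0-9][0-9]_*"), reverse=True)
    me = folder.parent.name
    for mdir in module_dirs:
        if mdir.name >= me:
            continue
        cand = mdir / item / name
        if cand.exists():
            return cand
    raise PipelineError(f"no upstream '{name}' found for item {item}")


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(config: EffectiveConfig, root: str | Path,
                 selection: list[str] | None = None, seed: int = 0) -> dict:
    """Execute the configured modules in order with resume semantics.

    Items with an existing SUCCESS marker are skipped; a module with a global
    SUCCESS marker is skipped entirely.  One item's failure does not abort its
    siblings; the report carries per-module per-item status and timings and a
    ``"status"`` of ``ok`` / ``partial`` / ``failed``.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for name, _ in config.modules:
        if name not in MODULE_REGISTRY and name != "cleanup":
            raise PipelineError(f"module '{name}' has no registered implementation")
    ctx = PipelineContext(root=root, general=config.general, seed=seed)
    n_items = int(config.general.get("n_items", 1))
    ctx.items = [f"{i + 1:03d}" for i in range(n_items)]
    ctx.save_items()
    report: dict = {"modules": [], "status": "ok"}
    any_failed = False
    for index, (name, params) in enumerate(config.modules):
        folder = root / f"{index + 1:02d}_{name}"
        folder.mkdir(exist_ok=True)
        entry = {"module": name, "items": {}, "skipped_module": False}
        report["modules"].append(entry)
        has_global = (folder / SUCCESS).exists()
        markers = {i: (folder / i / SUCCESS).exists() for i in ctx.items}
        if has_global and all(markers.values()):
            entry["skipped_module"] = True
            for item in ctx.items:
                entry["items"][item] = {"status": "skipped", "seconds": 0.0}
            continue
        if not has_global and markers and all(markers.values()):
            # deliberate global-marker deletion: re-execute the whole module
            for item in ctx.items:
                (folder / item / SUCCESS).unlink(missing_ok=True)
        run_items = ctx.items if selection is None else \
            [i for i in ctx.items if i in selection]
        all_ok = True
        for item in ctx.items:
            item_dir = folder / item
            if item not in run_items:
                entry["items"][item] = {"status": "skipped", "seconds": 0.0}
                all_ok = all_ok and (item_dir / SUCCESS).exists()
                continue
            item_dir.mkdir(exist_ok=True)
            if (item_dir / SUCCESS).exists():
                entry["items"][item] = {"status": "skipped", "seconds": 0.0}
                continue
            t0 = time.time()
            try:
                MODULE_REGISTRY[name](ctx, item, item_dir, params)
                _write_marker(item_dir / SUCCESS)
                entry["items"][item] = {"status": "done",
                                        "seconds": round(time.time() - t0, 3)}
            except Exception as exc:  # noqa: BLE001 - item isolation by design
                logger.error("module %s item %s failed: %s", name, item, exc)
                entry["items"][item] = {"status": "failed",
                                        "seconds": round(time.time() - t0, 3),
                                        "reason": str(exc)}
                all_ok = False
                any_failed = True
        if all_ok and all((folder / i / SUCCESS).exists() for i in ctx.items):
            _write_marker(folder / SUCCESS)
    report["status"] = "partial" if any_failed else "ok"
    (root / "execution_report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# Live mode
# ---------------------------------------------------------------------------

def run_live(watch_dir: str | Path, out_dir: str | Path,
             expected_images_per_series: int, listen_timeout_s: float,
             name_pattern: str = "TS_{series}_{angle}.mrc",
             binning: int = 8, thickness: int | None = None,
             poll_interval_s: float = 0.2) -> dict:
    """Watch a directory and reconstruct each tilt series as it completes.

    A series closes when it reaches the expected image count or when no new
    file for it arrives within the per-series inactivity timeout; it is then
    Fourier-crop binned and reconstructed through the simplified path (no
    motion/CTF steps).  The loop ends when the timeout elapses with no open
    series and no new files.
    """
    watch_dir = Path(watch_dir)
    if not watch_dir.is_dir():
        raise PipelineError(f"watch directory {watch_dir} does not exist")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if expected_images_per_series < 1 or listen_timeout_s <= 0:
        raise PipelineError("bad live-mode parameters")
    regex = _pattern_to_regex(name_pattern)
    seen: set[str] = set()
    open_series: dict[int, dict] = {}
    report = {"tomograms": [], "incomplete": []}
    last_activity = time.time()
    while True:
        new_files = False
        for path in sorted(watch_dir.iterdir()):
            if path.name in seen or not path.is_file():
                continue
            m = regex.match(path.name)
            if not m:
                seen.add(path.name)
                continue
            sid = int(m.group("series"))
            entry = open_series.setdefault(
                sid, {"files": [], "last_new": time.time()})
            entry["files"].append((float(m.group("angle")), path))
            entry["last_new"] = time.time()
            seen.add(path.name)
            new_files = True
        if new_files:
            last_activity = time.time()
        now = time.time()
        for sid in list(open_series):
            entry = open_series[sid]
            complete = len(entry["files"]) >= expected_images_per_series
            stale = now - entry["last_new"] > listen_timeout_s
            if complete or stale:
                if not complete:
                    report["incomplete"].append(sid)
                _live_reconstruct(sid, entry["files"], out_dir, binning,
                                  thickness, report,
                                  complete=complete)
                del open_series[sid]
                last_activity = time.time()
        if not open_series and time.time() - last_activity > listen_timeout_s:
            break
        time.sleep(poll_interval_s)
    return report


def _live_reconstruct(sid: int, files: list, out_dir: Path, binning: int,
                      thickness: int | None, report: dict,
                      complete: bool = True) -> None:
    files = sorted(files, key=lambda t: t[0])
    angles = np.array([a for a, _ in files])
    images = []
    for _, path in files:
        vol, header = read_mrc(path)
        images.append(vol[:, :, 0])
    stack = np.stack(images)
    if binning > 1:
        stack = fourier_crop(stack, binning, stack=True)
    series = sim.TiltSeries(images=stack.astype(np.float32), tilt_angles=angles,
                            acquisition_index=np.arange(len(angles)),
                            accumulated_dose=np.zeros(len(angles)),
                            defocus=np.zeros(len(angles)),
                            pixel_size=header.voxel_size * binning)
    nz = thickness if thickness is not None else stack.shape[1] // 2
    tomo = wbp_reconstruct(series, nz)
    out = out_dir / f"tomogram_{sid:03d}_bin{binning}.mrc"
    write_mrc(tomo.volume, out, voxel_size=tomo.voxel_size)
    report["tomograms"].append({"series": sid, "path": str(out),
                                "n_images": len(angles),
                                "complete": complete})
    logger.info("live: reconstructed series %d (%d images)", sid, len(angles))


# ---------------------------------------------------------------------------
# Cleanup
# ---------------------------------------------------------------------------

#: categories of declared-temporary artifacts, as glob patterns under root
CLEANUP_CATEGORIES = {
    "cc_maps": ["[0-9][0-9]_*/[0-9]*/cc_map.mrc",
                "[0-9][0-9]_*/[0-9]*/orient_map.mrc"],
    "stacks": ["[0-9][0-9]_*/[0-9]*/stack.mrc"],
    "scratch": ["**/scratch"],
}
#: never removable, whatever the configuration says
PROTECTED_CATEGORIES = ("tables", "success_markers", "final_maps")


def cleanup(root: str | Path, stages: list[str], dry_run: bool = False) -> dict:
    """Remove declared-temporary artifacts of the given categories.

    SUCCESS markers, particle tables and final maps are never candidates; a
    protected or unknown category raises a configuration error.  ``dry_run``
    lists removals without deleting.
    """
    root = Path(root)
    removed: list[str] = []
    for stage in stages:
        if stage in PROTECTED_CATEGORIES:
            raise PipelineError(f"category '{stage}' is protected and cannot be "
                                "declared temporary")
        if stage not in CLEANUP_CATEGORIES:
            raise PipelineError(f"unknown cleanup category '{stage}' (known: "
                                f"{', '.join(CLEANUP_CATEGORIES)})")
        for pattern in CLEANUP_CATEGORIES[stage]:
            for path in sorted(root.glob(pattern)):
                if path.name == SUCCESS or path.suffix == ".tbl":
                    continue
                removed.append(str(path.relative_to(root)))
                if not dry_run:
                    if path.is_dir():
                        shutil.rmtree(path)
                    else:
                        path.unlink()
    return {"removed": removed, "dry_run": dry_run}
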