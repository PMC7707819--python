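"""Readers and writers: session manifests, TIFF stacks, analysis outputs.

A session on disk is a directory with one multi-page 32-bit float TIFF per
condition (pages ordered trial-major: trial 0 frames, trial 1 frames, …), a
``manifest.json`` sidecar carrying the acquisition metadata and condition
table, and — for simulated sessions — a ``ground_truth.json`` plus mask
TIFFs with the planted architecture.

Coordinates are row-major 0-based pixel indices; physical positions are in
mm from the top-left pixel center; frame labels in metadata are 1-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stimuli import StimulusSpec
from .synth import CorticalModel, ImagingSession

__all__ = [
    "write_session",
    "read_session",
    "write_outputs",
    "write_ground_truth",
    "SessionValidationError",
]

MANIFEST_NAME = "manifest.json"


class SessionValidationError(ValueError):
    """Manifest inconsistent with the files on disk."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_session(session: ImagingSession, out_dir) -> dict:
    """Write per-condition TIFF stacks plus a JSON manifest; returns the
    manifest dict.  Ground truth, when attached, is serialized alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_tr, n_fr = session.n_trials, session.n_frames
    h, w = session.frame_shape
    conditions = {}
    for ci, cid in enumerate(session.condition_ids):
        fname = f"cond_{cid}.tif"
        stack = session.data[ci].reshape(n_tr * n_fr, h, w).astype(np.float32)
        tifffile.imwrite(out / fname, stack, photometric='minisblack')
        conditions[cid] = {
            "path": fname,
            "n_trials": n_tr,
            "n_frames": n_fr,
            "spec": session.condition_table[cid].to_dict(),
            "sha256": _sha256(out / fname),
        }
    manifest = {
        "format": "curvmap-session/1",
        "conditions": conditions,
        "condition_order": list(session.condition_ids),
        "frame_rate_hz": session.frame_rate_hz,
        "n_prestim_frames": session.n_prestim_frames,
        "stim_duration_s": session.stim_duration_s,
        "pixel_size_mm": session.pixel_size_mm,
        "shape": [h, w],
        "seed": session.seed,
    }
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if session.ground_truth is not None:
        write_ground_truth(session.ground_truth, out)
    return manifest


def read_session(manifest_path) -> ImagingSession:
    """Load a session directory back; validates shapes and frame counts,
    naming the offending file on mismatch."""
    path = Path(manifest_path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    with open(path) as fh:
        manifest = json.load(fh)
    root = path.parent
    h, w = manifest["shape"]
    order = manifest["condition_order"]
    table = {}
    stacks = []
    for cid in order:
        entry = manifest["conditions"][cid]
        f = root / entry["path"]
        if not f.exists():
            raise SessionValidationError(f"missing condition stack: {f}")
        data = tifffile.imread(f)
        expected = (entry["n_trials"] * entry["n_frames"], h, w)
        if data.shape != expected:
            raise SessionValidationError(
                f"{f}: shape {data.shape}, expected {expected}")
        stacks.append(data.reshape(entry["n_trials"], entry["n_frames"], h, w))
        table[cid] = StimulusSpec.from_dict(entry["spec"])
    return ImagingSession(
        data=np.stack(stacks, axis=0),
        condition_ids=list(order),
        condition_table=table,
        frame_rate_hz=manifest["frame_rate_hz"],
        n_prestim_frames=manifest["n_prestim_frames"],
        stim_duration_s=manifest["stim_duration_s"],
        pixel_size_mm=manifest["pixel_size_mm"],
        seed=manifest.get("seed"),
    )


def write_ground_truth(model: CorticalModel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = {
        "pixel_size_mm": model.pixel_size_mm,
        "shape": list(model.shape),
        "seed": model.seed,
        "pinwheel_centers": model.pinwheel_centers.tolist(),
        "domains": [
            {"id": d.id, "kind": d.kind, "center_px": list(d.center_px),
             "radius_px": d.radius_px, "ratio": d.ratio, "phi_deg": d.phi_deg,
             "theta_deg": d.theta_deg, "progression_id": d.progression_id}
            for d in model.domains
        ],
        "progressions": [
            {"straight_centroid_mm": list(p.straight_centroid_mm),
             "ratios": list(p.ratios),
             "centroids_mm": [list(c) for c in p.centroids_mm],
             "phi_deg": p.phi_deg, "theta_deg": p.theta_deg}
            for p in model.planted_progressions
        ],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
    tifffile.imwrite(out / "curvature_domain_mask.tif",
                     model.curvature_domain_mask.astype(np.uint8))
    tifffile.imwrite(out / "band_map.tif", model.band_map.astype(np.uint8))
    tifffile.imwrite(out / "orientation_angle_map.tif",
                     model.orientation_angle_map.astype(np.float32))


def write_outputs(maps: dict | None = None,
                  label_images: dict | None = None,
                  tables: dict | None = None,
                  out_dir=".",
                  params: dict | None = None) -> dict:
    """Write analysis outputs with deterministic names and a run manifest.

    ``maps`` → 32-bit float TIFFs, ``label_images`` → 16-bit label TIFFs,
    ``tables`` (DataFrames) → CSV; the returned (and saved) manifest lists
    every file with its sha256 checksum plus the parameter echo.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in sorted(maps or {}):
        arr = np.asarray(getattr(maps[name], "values", maps[name]), dtype=np.float32)
        fname = f"{name}.tif"
        tifffile.imwrite(out / fname, arr, photometric='minisblack')
        files[fname] = _sha256(out / fname)
    for name in sorted(label_images or {}):
        src = label_images[name]
        arr = np.asarray(getattr(src, "label_image", src))
        fname = f"{name}_labels.tif"
        tifffile.imwrite(out / fname, arr.astype(np.uint16))
        files[fname] = _sha256(out / fname)
        if hasattr(src, "domains"):
            tname = f"{name}_domains.csv"
            src.domains.to_csv(out / tname, index=False)
            files[tname] = _sha256(out / tname)
    for name in sorted(tables or {}):
        fname = f"{name}.csv"
        tbl = tables[name]
        if not isinstance(tbl, pd.DataFrame):
            tbl = pd.DataFrame(tbl)
        tbl.to_csv(out / fname, index=False)
        files[fname] = _sha256(out / fname)
    manifest = {"format": "curvmap-outputs/1", "files": files,
                "params": params or {}}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
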