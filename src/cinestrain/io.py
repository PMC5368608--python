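"""File I/O: NIfTI cine stacks, JSON/CSV contours, run manifests."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from cinestrain.core import CineSequence, ContourPair, GridSpec
from cinestrain.phantom import BandContour


def save_cine(cine: CineSequence, path: str | Path) -> None:
    """One slice x T frames as NIfTI: data (cols, rows, 1, T), spacing in mm,
    frame period (s) in the time zoom."""
    data = np.transpose(cine.frames, (2, 1, 0))[:, :, None, :].astype(np.float32)
    sx, sy = cine.grid.spacing
    dt = float(np.median(np.diff(cine.frame_times))) / 1000.0 if cine.n_frames > 1 else 1.0
    affine = np.diag([sx, sy, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, 1.0, dt))
    img.header["descrip"] = cine.view.encode()[:79]
    nib.save(img, str(path))


def load_cine(path: str | Path, view: str | None = None) -> CineSequence:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError(f"expected a (X, Y, 1, T) cine NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    grid = GridSpec(frames.shape[1:], (float(zooms[0]), float(zooms[1])))
    dt_ms = float(zooms[3]) * 1000.0 if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if view is None:
        view = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "sax-mid"
    return CineSequence(
        frames=frames,
        grid=grid,
        frame_times=np.arange(frames.shape[0]) * dt_ms,
        view=view,
    )


def save_contours(contours: ContourPair | BandContour, path: str | Path) -> None:
    if isinstance(contours, BandContour):
        payload = {
            "view": contours.view,
            "midline": np.asarray(contours.midline).tolist(),
            "thickness": contours.thickness,
        }
    else:
        payload = {
            "view": contours.view,
            "slice": contours.slice_index,
            "slice_thickness": contours.slice_thickness,
            "slice_gap": contours.slice_gap,
            "endo": np.asarray(contours.endo).tolist(),
            "epi": np.asarray(contours.epi).tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_contours(path: str | Path) -> ContourPair | BandContour:
    payload = json.loads(Path(path).read_text())
    if "midline" in payload:
        return BandContour(
            midline=np.asarray(payload["midline"], dtype=float),
            thickness=float(payload["thickness"]),
            view=payload.get("view", "lax-4ch"),
        )
    return ContourPair(
        endo=np.asarray(payload["endo"], dtype=float),
        epi=np.asarray(payload["epi"], dtype=float),
        view=payload.get("view", "sax-mid"),
        slice_index=int(payload.get("slice", 0)),
        slice_thickness=float(payload.get("slice_thickness", 8.0)),
        slice_gap=float(payload.get("slice_gap", 0.0)),
    )


def write_manifest(out_dir: str | Path, config: dict, seeds: dict | None = None) -> Path:
    """Reproducibility manifest: package version, config, its hash, seeds."""
    from cinestrain import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "cinestrain_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
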