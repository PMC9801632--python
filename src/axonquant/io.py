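"""File formats: multi-page TIFF stacks, JSON ROIs and ground truth, CSV
manifests and tables.

The ROI interchange schema is a minimal JSON polygon —
``{"region": ..., "bregma_um": ..., "vertices_px": [[x, y], ...]}`` —
chosen over proprietary ROI containers because it is bit-reproducible and
diff-able. All tables are plain RFC-4180 CSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .core import GroundTruth, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_roi",
    "read_roi",
    "write_ground_truth",
    "read_ground_truth",
    "write_cohort",
]

PathLike = Union[str, Path]


def write_stack(path: PathLike, stack: ImageStack) -> None:
    """Write an ImageStack as a multi-page float32 TIFF with µm calibration
    recorded in the resolution tags."""
    path = Path(path)
    res = 1.0 / stack.pixel_size_um  # pixels per µm
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        resolution=(res, res),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path: PathLike, pixel_size_um: float | None = None,
               z_step_um: float = 1.0) -> ImageStack:
    """Read a (multi-page) TIFF into an ImageStack.

    Calibration is taken from the TIFF resolution tag when present, unless
    overridden. Malformed or truncated files raise an error naming the file.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if pixel_size_um is None:
                page = tf.pages[0]
                xres = page.tags.get("XResolution")
                if xres is not None and xres.value[0]:
                    pixel_size_um = xres.value[1] / xres.value[0]
                else:
                    pixel_size_um = 1.0
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    return ImageStack(np.asarray(data, dtype=np.float64), float(pixel_size_um), z_step_um)


def write_roi(path: PathLike, vertices_px: np.ndarray, region: str = "other",
              bregma_um: float = 0.0) -> None:
    payload = {
        "region": region,
        "bregma_um": float(bregma_um),
        "vertices_px": np.asarray(vertices_px, dtype=float).reshape(-1, 2).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi(path: PathLike) -> dict:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        verts = np.asarray(payload["vertices_px"], dtype=float).reshape(-1, 2)
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise ValueError(f"malformed ROI JSON {path}: {exc}") from exc
    payload["vertices_px"] = verts
    return payload


def write_ground_truth(path: PathLike, truth: GroundTruth) -> None:
    payload = {
        "region_label": truth.region_label,
        "total_axon_length_um": truth.total_axon_length_um,
        "axon_paths": [np.asarray(p).tolist() for p in truth.axon_paths],
        "bouton_centers_um": truth.bouton_centers_um.tolist(),
        "soma_centers_um": truth.soma_centers_um.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: PathLike) -> GroundTruth:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return GroundTruth(
            axon_paths=[np.asarray(p, dtype=float) for p in payload["axon_paths"]],
            total_axon_length_um=float(payload["total_axon_length_um"]),
            bouton_centers_um=np.asarray(payload["bouton_centers_um"], dtype=float).reshape(-1, 2),
            soma_centers_um=np.asarray(payload["soma_centers_um"], dtype=float).reshape(-1, 3),
            region_label=payload["region_label"],
        )
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise ValueError(f"malformed ground-truth JSON {path}: {exc}") from exc


def write_cohort(cohort, outdir: PathLike) -> pd.DataFrame:
    """Persist a simulated cohort: per-section TIFF pairs, ROI and
    ground-truth JSON sidecars, and a manifest CSV with file paths.

    Returns the manifest (also written to ``manifest.csv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.sections:
        stem = f"{s.mouse_id}_{s.region}_{s.section_index:03d}"
        red_path = outdir / f"{stem}_red.tif"
        green_path = outdir / f"{stem}_green.tif"
        roi_path = outdir / f"{stem}_roi.json"
        write_stack(red_path, s.red)
        write_stack(green_path, s.green)
        write_roi(roi_path, s.roi_px, region=s.region, bregma_um=s.bregma_um)
        row = dict(
            mouse_id=s.mouse_id, sex=s.sex, estrous_stage=s.estrous_stage,
            region=s.region, section_index=s.section_index, bregma_um=s.bregma_um,
            red_path=red_path.name, green_path=green_path.name, roi_path=roi_path.name,
        )
        if s.truth is not None:
            truth_path = outdir / f"{stem}_truth.json"
            write_ground_truth(truth_path, s.truth)
            row["truth_path"] = truth_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
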