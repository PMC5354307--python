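"""Artifact serialization: TIFF slides, CSV tables, NRRD volumes, JSON logs.

Regional slides travel as 3-plane 16-bit TIFFs (category, theta x 10, count
x 10) with a JSON sidecar carrying slide number and pitch; the nuclei table
rides alongside as CSV so registration stages can re-derive the planes.
Volumes (directions, weights, masks) are written as NRRD via SimpleITK.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .regions import RegionalSlide

__all__ = ["save_slide", "load_slide", "save_volume", "load_volume",
           "save_json", "load_json", "JsonlLogger"]

_THETA_NAN = 65535


def save_slide(slide: RegionalSlide, path) -> None:
    """RegionalSlide -> <path>.tif + <path>.json + <path>.nuclei.csv."""
    path = Path(path)
    th = slide.theta * 10.0
    th = np.where(np.isnan(th), _THETA_NAN, th)
    planes = np.stack([
        slide.category.astype(np.uint16),
        np.clip(th, 0, _THETA_NAN).astype(np.uint16),
        np.clip(slide.count * 10.0, 0, 65534).astype(np.uint16),
    ])
    tifffile.imwrite(path.with_suffix(".tif"), planes)
    meta = {"slide_number": int(slide.slide_number),
            "pitch_um": float(slide.pitch_um),
            "source_slides": [int(s) for s in slide.source_slides],
            "flags": {k: v for k, v in slide.flags.items()
                      if isinstance(v, (bool, int, float, str))}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    slide.nuclei.to_csv(path.with_suffix(".nuclei.csv"), index=False)


def load_slide(path) -> RegionalSlide:
    path = Path(path)
    planes = tifffile.imread(path.with_suffix(".tif"))
    meta = json.loads(path.with_suffix(".json").read_text())
    nuclei = pd.read_csv(path.with_suffix(".nuclei.csv"))
    theta = planes[1].astype(np.float64) / 10.0
    theta[planes[1] == _THETA_NAN] = np.nan
    from .regions import grid_from_nuclei  # counts re-derived for full precision
    planes_full = grid_from_nuclei(
        nuclei, planes[0].shape,
        classify=not meta.get("flags", {}).get("counts_only", False))
    return RegionalSlide(nuclei=nuclei, slide_number=meta["slide_number"],
                         pitch_um=meta["pitch_um"],
                         source_slides=tuple(meta.get("source_slides", ())),
                         flags=dict(meta.get("flags", {})), **planes_full)


def save_volume(arr: np.ndarray, path, pitch_um: float = 1.0) -> None:
    """(Z, H, W) or (Z, H, W, C) array -> NRRD with isotropic spacing."""
    arr = np.asarray(arr)
    img = sitk.GetImageFromArray(arr.astype(np.float32),
                                 isVector=arr.ndim == 4)
    img.SetSpacing((pitch_um,) * 3)
    sitk.WriteImage(img, str(Path(path).with_suffix(".nrrd")))


def load_volume(path) -> np.ndarray:
    return sitk.GetArrayFromImage(sitk.ReadImage(str(path)))


def save_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def load_json(path):
    return json.loads(Path(path).read_text())


class JsonlLogger:
    """Structured JSON-lines logging for pipeline stages."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None

    def log(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        line = json.dumps(rec, default=str)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
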