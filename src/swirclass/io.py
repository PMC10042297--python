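"""File formats of the pipeline.

* Raw acquisitions: one 16-bit grayscale TIFF per (filter, exposure) frame
  plus a sidecar ``manifest.csv`` (``filename,filter_cutoff_nm,exposure_s,
  role``) per acquisition directory.
* Assembled cubes: multi-page float32 TIFF (one page per channel, ascending
  cut-off) with a JSON metadata sidecar (cut-offs, chosen exposures,
  exposure factor).
* ROI masks: single-channel integer TIFF/PNG with the 0-3 class coding.
* Label maps: indexed PNG with a fixed 4-color palette.
* Phantom configs: YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .cube import ImageCube, RawFrame
from .preprocess import RoiSet

__all__ = [
    "write_frames",
    "read_manifest",
    "save_cube",
    "load_cube",
    "save_mask",
    "load_mask",
    "save_label_map",
    "save_study",
    "load_acquisition",
    "config_to_yaml",
    "config_from_yaml",
]

#: RGBA-free palette: unlabeled (black), tumor (red), non-tumor (blue),
#: background (gray).
LABEL_PALETTE = [(0, 0, 0), (214, 39, 40), (31, 119, 180), (140, 140, 140)]


def write_frames(frames, darks, out_dir) -> Path:
    """Write raw frames + darks as TIFFs with a manifest.csv sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, frame in enumerate([*frames, *darks]):
        name = (f"{frame.role}_f{frame.filter_cutoff_nm:.0f}nm_"
                f"t{frame.exposure_s:g}s_{i:03d}.tif")
        px = frame.pixels
        px = px.astype(np.uint16) if np.issubdtype(px.dtype, np.integer) \
            else px.astype(np.float32)
        tifffile.imwrite(out_dir / name, px)
        rows.append({"filename": name, "filter_cutoff_nm": frame.filter_cutoff_nm,
                     "exposure_s": frame.exposure_s, "role": frame.role})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_manifest(manifest_path) -> tuple[list, list]:
    """Load (signal frames, dark frames) listed by a CSV or YAML manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    if manifest_path.suffix in (".yml", ".yaml"):
        entries = yaml.safe_load(manifest_path.read_text())
    else:
        entries = pd.read_csv(manifest_path).to_dict("records")
    frames, darks = [], []
    for e in entries:
        px = tifffile.imread(manifest_path.parent / e["filename"])
        frame = RawFrame(px, float(e["exposure_s"]), float(e["filter_cutoff_nm"]),
                         role=str(e["role"]))
        (darks if frame.role == "dark" else frames).append(frame)
    return frames, darks


def save_cube(cube: ImageCube, path) -> None:
    """Multi-page float32 TIFF (one page per channel) + JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.data.astype(np.float32), -1, 0)
    tifffile.imwrite(path, pages)
    meta = {"filter_cutoffs_nm": list(cube.filter_cutoffs_nm),
            "exposure_factor": cube.exposure_factor,
            "provenance": _jsonable(cube.provenance)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_cube(path) -> ImageCube:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageCube(np.moveaxis(pages.astype(float), 0, -1),
                     tuple(meta["filter_cutoffs_nm"]),
                     exposure_factor=float(meta.get("exposure_factor", 1.0)),
                     provenance=meta.get("provenance", {}))


def save_mask(rois: RoiSet, path) -> None:
    path = Path(path)
    if path.suffix == ".png":
        Image.fromarray(rois.masks.astype(np.uint8), mode="L").save(path)
    else:
        tifffile.imwrite(path, rois.masks.astype(np.uint8))


def load_mask(path) -> RoiSet:
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        arr = tifffile.imread(path)
    return RoiSet(arr.astype(np.int64))


def save_label_map(label_map: np.ndarray, path) -> None:
    """Indexed PNG with the fixed 4-color class palette."""
    img = Image.fromarray(label_map.astype(np.uint8), mode="P")
    palette = [v for rgb in LABEL_PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def config_to_yaml(config, path) -> None:
    payload = _jsonable(dataclasses.asdict(config))
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def config_from_yaml(path, config_cls):
    from .phantom import EllipseSpec  # local import to avoid a cycle

    payload = yaml.safe_load(Path(path).read_text())
    fields = {f.name: f for f in dataclasses.fields(config_cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(value, dict) and set(value) == {"center", "axes"}:
            value = EllipseSpec(tuple(value["center"]), tuple(value["axes"]))
        elif key == "offtarget_sites":
            value = tuple(EllipseSpec(tuple(v["center"]), tuple(v["axes"]))
                          for v in value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return config_cls(**kwargs)


def save_study(outputs, out_dir) -> Path:
    """Materialize a simulated study: per-individual TIFFs, masks, config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for out in outputs:
        sub = out_dir / out.cube_id
        write_frames(out.frames, out.darks, sub)
        save_mask(out.rois, sub / "mask.tif")
    config_to_yaml(outputs[0].config, out_dir / "config.yaml")
    return out_dir


def load_acquisition(acq_dir) -> tuple[list, list, RoiSet | None]:
    """Frames, darks and (if present) the ROI mask of one acquisition dir."""
    acq_dir = Path(acq_dir)
    frames, darks = read_manifest(acq_dir / "manifest.csv")
    mask_path = acq_dir / "mask.tif"
    rois = load_mask(mask_path) if mask_path.exists() else None
    return frames, darks, rois
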