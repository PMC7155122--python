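"""Plate-layout I/O, configuration, and run manifests.

On disk a plate is ``root/<condition>/<well>/<field>_<channel>.tif``
(16-bit grayscale TIFF, one file per channel) with the generator's
ground truth beside the images as ``<field>_truth.json``. All tabular
outputs are CSV with floats rendered at fixed precision so repeated
runs are bit-identical. One YAML file holds every parameter of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import AcquisitionModel
from .field_image import FieldImage
from .synthgen import (
    FieldTruth,
    GroundTruthSet,
    LengthLaw,
    PlateDesign,
    ReleaseModel,
    SiteAreaLaw,
)
from .wpb_segmentation import AnalysisParams

logger = logging.getLogger(__name__)

CHANNELS = ("nuclear", "vwf")
FLOAT_FORMAT = "%.9g"


# --------------------------------------------------------------------------
# TIFF plates
# --------------------------------------------------------------------------

def field_paths(root: Path, image: FieldImage) -> dict:
    base = Path(root) / image.condition / image.well
    return {ch: base / f"{image.field_id}_{ch}.tif" for ch in CHANNELS}


def write_field(image: FieldImage, root: Path) -> None:
    paths = field_paths(root, image)
    paths["nuclear"].parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(paths["nuclear"], image.nuclear)
    tifffile.imwrite(paths["vwf"], image.vwf)


def write_truth(truth: FieldTruth, root: Path) -> None:
    base = Path(root) / truth.condition / truth.well
    base.mkdir(parents=True, exist_ok=True)
    path = base / f"{truth.field_id}_truth.json"
    path.write_text(json.dumps(truth.to_dict(), sort_keys=True))


def load_truth(root: Path) -> GroundTruthSet:
    fields = []
    for path in sorted(Path(root).glob("*/*/*_truth.json")):
        fields.append(FieldTruth.from_dict(json.loads(path.read_text())))
    return GroundTruthSet(fields)


def _read_channel(path: Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale TIFF")
    if img.dtype == np.uint8:
        logger.info("%s: 8-bit input widened to 16-bit", path)
        img = img.astype(np.uint16)
    elif img.dtype != np.uint16:
        raise ValueError(f"{path}: unsupported dtype {img.dtype}")
    return img


def _load_layout_overrides(root: Path) -> dict:
    """Optional sidecar ``layout.csv`` remapping directory-encoded
    metadata: columns condition, well, field_id plus any of
    new_condition / new_well."""
    path = Path(root) / "layout.csv"
    if not path.exists():
        return {}
    table = pd.read_csv(path, dtype=str)
    overrides = {}
    for row in table.itertuples():
        key = (row.condition, row.well, row.field_id)
        overrides[key] = (getattr(row, "new_condition", None) or row.condition,
                          getattr(row, "new_well", None) or row.well)
    return overrides


def load_plate(root: Path, pixel_size: float) -> tuple:
    """Load every complete field under ``root``.

    Returns ``(field_images, problems)`` where problems is a list of
    per-field error strings (missing channel, unreadable file). Raises
    only if nothing at all could be loaded. A sidecar ``layout.csv``
    can remap the condition/well labels encoded in the directory names.
    """
    root = Path(root)
    overrides = _load_layout_overrides(root)
    stems = {}
    for path in sorted(root.glob("*/*/*.tif")):
        name = path.stem
        for ch in CHANNELS:
            suffix = f"_{ch}"
            if name.endswith(suffix):
                key = (path.parent.parent.name, path.parent.name,
                       name[: -len(suffix)])
                stems.setdefault(key, {})[ch] = path
    if not stems:
        raise FileNotFoundError(f"no TIFF fields under {root}")
    images, problems = [], []
    for (condition, well, field_id), chans in sorted(stems.items()):
        missing = [ch for ch in CHANNELS if ch not in chans]
        if missing:
            problems.append(f"{condition}/{well}/{field_id}: missing {missing}")
            continue
        condition, well = overrides.get((condition, well, field_id),
                                        (condition, well))
        try:
            images.append(FieldImage(
                nuclear=_read_channel(chans["nuclear"]),
                vwf=_read_channel(chans["vwf"]),
                pixel_size=pixel_size,
                condition=condition, well=well, field_id=field_id))
        except Exception as exc:  # collect, keep loading
            problems.append(f"{condition}/{well}/{field_id}: {exc}")
    if not images:
        raise RuntimeError(f"all fields failed to load: {problems}")
    for p in problems:
        logger.warning("%s", p)
    return images, problems


def write_csv(df: pd.DataFrame, path: Path) -> None:
    """CSV writer with fixed float precision (deterministic output)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "design": {
        "conditions": ["Unstimulated", "Stimulated"],
        "wells_per_condition": 8,
        "fields_per_well": 9,
        "cells_per_field": [10, 20],
        "granules_per_cell": [15, 40],
    },
    "acquisition": {},          # AcquisitionModel defaults
    "length_law": {"p": 0.5, "max_quanta": 12},
    "release": {
        "Stimulated": {"p_base": 0.2, "p_max": 0.35,
                       "midpoint_length": 2.0, "steepness": 0.3},
    },
    "analysis": {},             # AnalysisParams defaults
    "site_area_law": {},        # SiteAreaLaw defaults
    "control": "Unstimulated",
    "noise": True,
    "alpha": 0.05,
    "n_mc": 100000,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Path | None = None, overrides: list | None = None) -> dict:
    """Merge the defaults with a YAML file and ``key.sub=value`` overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    for item in overrides or []:
        key, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} must look like key=value")
        value = yaml.safe_load(raw)
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def design_from_config(cfg: dict) -> PlateDesign:
    d = cfg.get("design", {})
    return PlateDesign(
        conditions=tuple(d.get("conditions", ["Unstimulated"])),
        wells_per_condition=int(d.get("wells_per_condition", 8)),
        fields_per_well=int(d.get("fields_per_well", 9)),
        cells_per_field=tuple(d.get("cells_per_field", (10, 20))),
        granules_per_cell=tuple(d.get("granules_per_cell", (15, 40))),
    )


def acquisition_from_config(cfg: dict) -> AcquisitionModel:
    a = dict(cfg.get("acquisition", {}))
    if "field_shape" in a:
        a["field_shape"] = tuple(a["field_shape"])
    return AcquisitionModel(**a)


def length_law_from_config(cfg: dict) -> LengthLaw:
    law = cfg.get("length_law", {})
    if "pmf" in law:
        return LengthLaw(pmf=tuple(law["pmf"]))
    return LengthLaw.truncated_geometric(
        p=float(law.get("p", 0.5)), max_quanta=int(law.get("max_quanta", 12)))


def release_models_from_config(cfg: dict) -> dict:
    return {cond: ReleaseModel(**params)
            for cond, params in (cfg.get("release") or {}).items()}


def params_from_config(cfg: dict) -> AnalysisParams:
    return AnalysisParams(**(cfg.get("analysis") or {}))


def site_area_law_from_config(cfg: dict) -> SiteAreaLaw:
    return SiteAreaLaw(**(cfg.get("site_area_law") or {}))


# --------------------------------------------------------------------------
# Run manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    config: dict,
    seed: int,
    outputs: list,
    name: str = "manifest.json",
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(Path(p).relative_to(out_dir)): _sha256(p)
                    for p in outputs},
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
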