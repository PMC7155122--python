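"""End-to-end experiment driver: generate -> segment -> summarize -> compare.

Each stage is also usable on its own (and from the CLI); this module
wires them together deterministically so a fixed (config, seed) pair
reproduces every CSV bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import plate_io, size_stats, synthgen, validation, wpb_segmentation
from .acquisition import AcquisitionModel
from .field_image import FieldImage
from .wpb_segmentation import AnalysisParams

logger = logging.getLogger(__name__)


def generate_plate(cfg: dict, out_dir: Path, seed: int) -> list:
    """Sample a plate per the config, apply per-condition release, render
    every field and write TIFFs plus ground-truth JSON under ``out_dir``.

    Returns the list of written FieldImage objects.
    """
    design = plate_io.design_from_config(cfg)
    acq = plate_io.acquisition_from_config(cfg)
    law = plate_io.length_law_from_config(cfg)
    models = plate_io.release_models_from_config(cfg)
    truth = synthgen.sample_granule_population(design, law, acq, seed=seed)
    truth = synthgen.apply_release_by_condition(truth, models, seed=seed + 1)
    images = []
    for f, img in synthgen.render_plate(truth, acq, seed=seed + 2,
                                        noise=bool(cfg.get("noise", True))):
        plate_io.write_field(img, out_dir)
        plate_io.write_truth(f, out_dir)
        images.append(img)
    logger.info("generated %d fields under %s", len(images), out_dir)
    return images


def segment_plate(
    images: list,
    acq: AcquisitionModel,
    params: AnalysisParams | None = None,
) -> tuple:
    """Segment WPBs and count nuclei on every field.

    Returns ``(objects, image_summaries)`` DataFrames.
    """
    params = params or AnalysisParams()
    records_all = []
    summaries = []
    for img in images:
        _, records = wpb_segmentation.segment_wpbs(
            img.vwf, acq, params, image_id=img.image_id)
        n_nuclei = wpb_segmentation.count_nuclei(img.nuclear, acq, params)
        records_all.extend(records)
        summaries.append(wpb_segmentation.summarize_image(
            records, n_nuclei, params, image_id=img.image_id,
            condition=img.condition, well=img.well))
    return (wpb_segmentation.records_to_dataframe(records_all),
            wpb_segmentation.summaries_to_dataframe(summaries))


def run_experiment(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Full pipeline on a synthetic plate; returns output paths."""
    out_dir = Path(out_dir)
    plate_dir = out_dir / "plate"
    results_dir = out_dir / "results"
    acq = plate_io.acquisition_from_config(cfg)
    params = plate_io.params_from_config(cfg)
    generate_plate(cfg, plate_dir, seed)
    images, _ = plate_io.load_plate(plate_dir, acq.pixel_size)
    objects, image_summaries = segment_plate(images, acq, params)
    wells = size_stats.aggregate_wells(image_summaries)
    verdicts = size_stats.detect_size_selection(
        wells, control=str(cfg.get("control", "Unstimulated")),
        alpha=float(cfg.get("alpha", 0.05)),
        n_mc=int(cfg.get("n_mc", 100000)), seed=seed + 3)
    truth = plate_io.load_truth(plate_dir)
    reference = validation.truth_to_reference(list(truth))
    report = validation.match_objects(objects, reference)
    paths = {
        "objects": results_dir / "objects.csv",
        "images": results_dir / "images.csv",
        "wells": results_dir / "wells.csv",
        "comparisons": results_dir / "comparisons.csv",
        "validation": results_dir / "validation.csv",
    }
    plate_io.write_csv(objects, paths["objects"])
    plate_io.write_csv(image_summaries, paths["images"])
    plate_io.write_csv(wells, paths["wells"])
    plate_io.write_csv(verdicts, paths["comparisons"])
    plate_io.write_csv(pd.DataFrame([report.to_dict()]), paths["validation"])
    plate_io.write_manifest(out_dir, cfg, seed, list(paths.values()))
    return {k: str(v) for k, v in paths.items()}
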