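"""Segmentation of extracellular vWF exocytic sites.

Pipeline: light Gaussian denoise (sigma below the PSF, so resolution is
untouched), global moment-preserving (Tsai) threshold, marker-based
watershed to split touching sites, then per-image and per-well area
summaries including the proportion of sites larger than 2 um^2
normalized to a control condition.

Tsai's threshold picks the binarization whose two-level image preserves
the first three raw moments of the gray-level histogram: with moments
m1..m3, the representative levels z0 < z1 are the roots of
z^2 + c1 z + c0 = 0 where

    c0 = (m1 m3 - m2^2) / (m2 - m1^2)
    c1 = (m1 m2 - m3)   / (m2 - m1^2)

and the below-class mass is p0 = (z1 - m1) / (z1 - z0). The threshold is
the gray level whose cumulative histogram fraction comes closest to p0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .acquisition import AcquisitionModel
from .wpb_segmentation import AnalysisParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of moment-preserving thresholding.

    ``threshold`` is None for degenerate (constant) histograms.
    """

    threshold: float | None
    p0: float
    z0: float
    z1: float

    @property
    def degenerate(self) -> bool:
        return self.threshold is None


@dataclass
class ExoSiteRecord:
    """One segmented exocytic site."""

    image_id: str
    label: int
    area: float      # um^2
    centroid: tuple  # (x, y) um

    def to_dict(self) -> dict:
        return {"image_id": self.image_id, "label": self.label,
                "area_um2": self.area,
                "x_um": self.centroid[0], "y_um": self.centroid[1]}


# --------------------------------------------------------------------------
# Tsai threshold
# --------------------------------------------------------------------------

def tsai_threshold(levels: np.ndarray, counts: np.ndarray) -> ThresholdResult:
    """Moment-preserving threshold of a gray-level histogram.

    Parameters are the occupied gray levels (ascending) and their pixel
    counts. Degenerate histograms (a single occupied level, or zero
    variance) yield ``threshold=None``; a numerically complex root pair
    falls back to the median split (p0 = 0.5) with a logged warning.
    """
    levels = np.asarray(levels, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if levels.size == 0 or counts.sum() <= 0:
        raise ValueError("empty histogram")
    order = np.argsort(levels)
    levels, counts = levels[order], counts[order]
    p = counts / counts.sum()
    m1 = float(np.dot(p, levels))
    m2 = float(np.dot(p, levels**2))
    m3 = float(np.dot(p, levels**3))
    var = m2 - m1 * m1
    if np.count_nonzero(counts) < 2 or var <= 1e-12 * max(m2, 1.0):
        return ThresholdResult(threshold=None, p0=1.0, z0=m1, z1=m1)
    c0 = (m1 * m3 - m2 * m2) / var
    c1 = (m1 * m2 - m3) / var
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        logger.warning("complex moment roots; falling back to median split")
        p0 = 0.5
        z0 = z1 = m1
    else:
        root = math.sqrt(disc)
        z0 = (-c1 - root) / 2.0
        z1 = (-c1 + root) / 2.0
        p0 = (z1 - m1) / (z1 - z0)
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    # gray level whose below-class mass best matches p0; ties -> lowest level
    idx = int(np.argmin(np.abs(cum - p0)))
    return ThresholdResult(threshold=float(levels[idx]), p0=p0,
                           z0=float(z0), z1=float(z1))


def tsai_threshold_image(image: np.ndarray) -> ThresholdResult:
    """Tsai threshold of an integer-valued image."""
    levels, counts = np.unique(np.rint(image).astype(np.int64),
                               return_counts=True)
    return tsai_threshold(levels, counts)


# --------------------------------------------------------------------------
# Watershed splitting
# --------------------------------------------------------------------------

def split_touching(
    mask: np.ndarray,
    min_separation: int = 2,
    h: float = 0.5,
) -> np.ndarray:
    """Split touching foreground blobs with a marker-based watershed.

    Markers are regional maxima of the Euclidean distance transform
    (minimum pixel separation ``min_separation``) after h-maxima
    suppression: maxima less than ``h`` pixels above their surrounding
    saddle are merged, which removes the spurious ridge maxima the
    discrete distance transform produces between heavily overlapping
    blobs. The flood assigns every foreground pixel to exactly one
    marker, so the labels partition the mask exactly.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=int)
    dist = ndimage.distance_transform_edt(mask)
    seeds = morphology.h_maxima(dist, h)
    # enforce the minimum marker separation: maxima closer than this
    # merge into one marker
    if min_separation > 1:
        seeds = ndimage.binary_closing(
            seeds, structure=np.ones((3, 3)), iterations=min_separation // 2 + 1)
        seeds &= mask
    markers, _ = ndimage.label(seeds, structure=np.ones((3, 3), dtype=int))
    labels = segmentation.watershed(-dist, markers=markers, mask=mask)
    # a component whose maxima were all suppressed still gets one label
    orphans = mask & (labels == 0)
    if orphans.any():
        extra, _ = ndimage.label(orphans,
                                       structure=np.ones((3, 3), dtype=int))
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return labels


# --------------------------------------------------------------------------
# Site segmentation
# --------------------------------------------------------------------------

def segment_exosites(
    vwf_channel: np.ndarray,
    acq: AcquisitionModel,
    params: AnalysisParams | None = None,
    image_id: str = "",
) -> tuple:
    """Segment exocytic sites from an extracellular-vWF image.

    Returns ``(labels, records)``. Empty foreground yields an empty
    record list, never an error.
    """
    params = params or AnalysisParams()
    if vwf_channel.ndim != 2:
        raise ValueError("expected a 2-D raster")
    sigma_px = params.resolved_blur_sigma(acq) / acq.pixel_size
    blurred = ndimage.gaussian_filter(vwf_channel.astype(float), sigma_px)
    result = tsai_threshold_image(blurred)
    if result.degenerate:
        return np.zeros(vwf_channel.shape, dtype=int), []
    mask = np.rint(blurred).astype(np.int64) > result.threshold
    labels = split_touching(mask, params.marker_min_separation)
    px_area = acq.pixel_size**2
    records = []
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid
        records.append(ExoSiteRecord(
            image_id=image_id, label=int(rp.label),
            area=float(rp.area) * px_area,
            centroid=(cx * acq.pixel_size, cy * acq.pixel_size)))
    return labels, records


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

def site_records_to_dataframe(records: list) -> pd.DataFrame:
    cols = ["image_id", "label", "area_um2", "x_um", "y_um"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_dict() for r in records])[cols]


def summarize_exosites(
    sites: pd.DataFrame,
    control_condition: str,
    params: AnalysisParams | None = None,
) -> tuple:
    """Per-image and per-well exocytic-site summaries.

    ``sites`` needs columns image_id, condition, well, area_um2 (one row
    per site; images with no sites may appear with NaN area). Per image:
    site count and the proportion of sites larger than
    ``large_site_threshold``. Per well: means over the well's images,
    plus that proportion normalized to the mean over control-condition
    wells, which therefore normalizes to 1 by construction.
    """
    params = params or AnalysisParams()
    if control_condition not in set(sites["condition"]):
        raise ValueError(
            f"control condition {control_condition!r} absent from data")
    thr = params.large_site_threshold

    def _image_stats(g: pd.DataFrame) -> pd.Series:
        areas = g["area_um2"].dropna()
        return pd.Series({
            "n_sites": int(areas.size),
            "prop_large": (float((areas > thr).mean())
                           if areas.size else np.nan),
        })

    per_image = (sites.groupby(["condition", "well", "image_id"], sort=True)
                 .apply(_image_stats, include_groups=False).reset_index())
    per_well = (per_image.groupby(["condition", "well"], sort=True)
                .agg(n_images=("image_id", "size"),
                     mean_site_count=("n_sites", "mean"),
                     mean_prop_large=("prop_large", "mean"))
                .reset_index())
    control_mean = per_well.loc[
        per_well["condition"] == control_condition, "mean_prop_large"].mean()
    per_well["norm_prop_large"] = per_well["mean_prop_large"] / control_mean
    return per_image, per_well
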