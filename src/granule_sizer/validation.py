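"""Object-level validation of segmentation against reference annotations.

References may be manual annotations or the synthetic generator's ground
truth. Detected and reference objects are matched one-to-one by greedy
nearest-centroid pairing within a distance gate; unmatched detections
are false positives, unmatched references false negatives. Length
statistics (bias, RMSE) are computed over matched pairs when both sides
carry lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ValidationReport:
    """Object-level agreement between detected and reference records."""

    n_reference: int
    n_detected: int
    true_positives: int
    precision: float
    recall: float
    f1: float
    length_bias: float = math.nan   # mean(detected - reference), um
    length_rmse: float = math.nan   # um
    per_image: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"n_reference": self.n_reference,
                "n_detected": self.n_detected,
                "true_positives": self.true_positives,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "length_bias": self.length_bias,
                "length_rmse": self.length_rmse}


def _greedy_match(
    det_xy: np.ndarray,
    ref_xy: np.ndarray,
    max_dist: float,
) -> list:
    """Greedy one-to-one matching by ascending centroid distance.

    Returns list of (det_index, ref_index) pairs.
    """
    if len(det_xy) == 0 or len(ref_xy) == 0:
        return []
    diff = det_xy[:, None, :] - ref_xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    di, ri = np.nonzero(dist <= max_dist)
    order = np.argsort(dist[di, ri], kind="stable")
    used_d = np.zeros(len(det_xy), bool)
    used_r = np.zeros(len(ref_xy), bool)
    pairs = []
    for k in order:
        d, r = di[k], ri[k]
        if not used_d[d] and not used_r[r]:
            used_d[d] = used_r[r] = True
            pairs.append((int(d), int(r)))
    return pairs


def match_objects(
    detected: pd.DataFrame,
    reference: pd.DataFrame,
    max_centroid_dist: float = 0.5,
) -> ValidationReport:
    """Score detected against reference records, image by image.

    Both frames need columns image_id, x_um, y_um and optionally
    length_um. Matching never crosses images; a detected set whose
    image_ids are disjoint from the reference's is an error (it means
    the wrong results were paired with the wrong truth).
    """
    for name, df in (("detected", detected), ("reference", reference)):
        missing = {"image_id", "x_um", "y_um"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} records missing columns {sorted(missing)}")
    det_ids = set(detected["image_id"])
    ref_ids = set(reference["image_id"])
    if det_ids and ref_ids and not det_ids & ref_ids:
        raise ValueError("detected and reference share no image ids")
    have_lengths = ("length_um" in detected.columns
                    and "length_um" in reference.columns)
    tp = 0
    diffs = []
    rows = []
    for image_id in sorted(det_ids | ref_ids):
        det = detected[detected["image_id"] == image_id].reset_index(drop=True)
        ref = reference[reference["image_id"] == image_id].reset_index(drop=True)
        pairs = _greedy_match(det[["x_um", "y_um"]].to_numpy(float),
                              ref[["x_um", "y_um"]].to_numpy(float),
                              max_centroid_dist)
        tp += len(pairs)
        if have_lengths:
            for d, r in pairs:
                diffs.append(det.loc[d, "length_um"] - ref.loc[r, "length_um"])
        n_d, n_r, n_tp = len(det), len(ref), len(pairs)
        rows.append({"image_id": image_id, "n_reference": n_r,
                     "n_detected": n_d, "true_positives": n_tp,
                     "precision": n_tp / n_d if n_d else math.nan,
                     "recall": n_tp / n_r if n_r else math.nan})
    n_det, n_ref = len(detected), len(reference)
    precision = tp / n_det if n_det else math.nan
    recall = tp / n_ref if n_ref else math.nan
    f1 = (2 * precision * recall / (precision + recall)
          if n_det and n_ref and (precision + recall) > 0 else math.nan)
    diffs = np.asarray(diffs, float)
    return ValidationReport(
        n_reference=n_ref, n_detected=n_det, true_positives=tp,
        precision=precision, recall=recall, f1=f1,
        length_bias=float(diffs.mean()) if diffs.size else math.nan,
        length_rmse=float(np.sqrt(np.mean(diffs**2))) if diffs.size else math.nan,
        per_image=pd.DataFrame(rows))


def truth_to_reference(truth_fields: list) -> pd.DataFrame:
    """Flatten generator FieldTruth objects into a reference frame of the
    retained (unreleased) granules."""
    rows = []
    for f in truth_fields:
        for g in f.retained_granules():
            rows.append({"image_id": f.image_id, "x_um": g.centroid[0],
                         "y_um": g.centroid[1], "length_um": g.length})
    return pd.DataFrame(rows, columns=["image_id", "x_um", "y_um", "length_um"])
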