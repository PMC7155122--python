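"""Synthetic two-channel fluorescence fields with known ground truth.

Weibel-Palade bodies (WPBs) are rod-shaped secretory granules whose
length is quantized in 0.5-um steps (linear co-packaging of half-micron
vWF quanta) and whose width is uniform and below the diffraction limit.
This module samples granule populations from a quantal length law,
simulates agonist stimulation as stochastic, optionally length-biased
removal, and renders fields through a Gaussian-PSF + Poisson + read-noise
forward model so the segmentation and statistics stages can be scored
against exact ground truth.

Everything is a pure function of (inputs, seed): replaying a seed
reproduces images bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .acquisition import AcquisitionModel
from .field_image import FieldImage

QUANTUM_LENGTH = 0.5
"""Length of one vWF quantum in um; all granule lengths are multiples."""

DEFAULT_GRANULE_WIDTH = 0.2
"""Uniform sub-diffraction rod width in um."""

LONG_LENGTH_THRESHOLD = 2.0
"""A granule is 'long' if its length exceeds this (um)."""


def rod_area(length, width: float = DEFAULT_GRANULE_WIDTH):
    """Footprint area of a rounded-cap rod: L*W + pi*(W/2)^2, in um^2."""
    return np.asarray(length, float) * width + math.pi * (width / 2.0) ** 2


# --------------------------------------------------------------------------
# Length law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthLaw:
    """Distribution of granule length over quantum counts 1..len(pmf).

    ``pmf[k-1]`` is P(n_quanta = k); lengths are ``k * QUANTUM_LENGTH``.
    """

    pmf: tuple
    quantum_length: float = QUANTUM_LENGTH

    def __post_init__(self) -> None:
        p = np.asarray(self.pmf, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("pmf must be a non-empty 1-D sequence")
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("pmf must be non-negative and sum to 1")

    @classmethod
    def truncated_geometric(cls, p: float = 0.5, max_quanta: int = 12) -> "LengthLaw":
        """Geometric(p) over n_quanta, truncated (renormalized) at max_quanta.

        The default (p=0.5, truncation 12) gives a long-tailed,
        non-normal length distribution spanning 0.5-6 um with a
        population long-area fraction near 0.19.
        """
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        k = np.arange(1, max_quanta + 1)
        w = (1 - p) ** (k - 1) * p
        return cls(pmf=tuple(w / w.sum()))

    @classmethod
    def point_mass(cls, n_quanta: int) -> "LengthLaw":
        pmf = np.zeros(n_quanta)
        pmf[-1] = 1.0
        return cls(pmf=tuple(pmf))

    @property
    def quanta(self) -> np.ndarray:
        return np.arange(1, len(self.pmf) + 1)

    @property
    def lengths(self) -> np.ndarray:
        return self.quanta * self.quantum_length

    def mean_quanta(self) -> float:
        return float(np.dot(self.quanta, self.pmf))

    def mean_length(self) -> float:
        return self.mean_quanta() * self.quantum_length

    def var_length(self) -> float:
        m = self.mean_length()
        return float(np.dot(self.lengths**2, self.pmf) - m * m)

    def long_area_fraction(
        self,
        threshold: float = LONG_LENGTH_THRESHOLD,
        width: float = DEFAULT_GRANULE_WIDTH,
    ) -> float:
        """Expected fraction of total WPB area carried by granules longer
        than ``threshold``. Rod footprints are stadium-shaped at uniform
        width: a(L) = L*width + pi*(width/2)^2."""
        a = rod_area(self.lengths, width) * np.asarray(self.pmf)
        return float(a[self.lengths > threshold].sum() / a.sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.quanta, size=n, p=np.asarray(self.pmf))


# --------------------------------------------------------------------------
# Release model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseModel:
    """Length-dependent exocytosis probability.

    p(L) = p_base + p_max / (1 + exp(-(L - midpoint_length) / steepness))

    The logistic family nests both study scenarios: ``p_max = 0`` (or
    ``steepness = inf``) is length-independent "random selection";
    positive ``p_max`` with finite steepness releases long granules
    preferentially.
    """

    p_base: float = 0.0
    p_max: float = 0.0
    midpoint_length: float = LONG_LENGTH_THRESHOLD
    steepness: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_base <= self.p_base + self.p_max <= 1.0:
            raise ValueError("require 0 <= p_base <= p_base + p_max <= 1")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive (may be inf)")

    @classmethod
    def random_release(cls, p: float) -> "ReleaseModel":
        """Length-independent release with probability p."""
        return cls(p_base=p, p_max=0.0, steepness=math.inf)

    def probability(self, length) -> np.ndarray:
        """Release probability for granule length(s) in um."""
        length = np.asarray(length, dtype=float)
        if math.isinf(self.steepness):
            logistic = np.full(length.shape, 0.5)
        else:
            from scipy.special import expit
            logistic = expit((length - self.midpoint_length) / self.steepness)
        return self.p_base + self.p_max * logistic


def expected_retained_long_area_fraction(
    law: LengthLaw,
    model: ReleaseModel,
    threshold: float = LONG_LENGTH_THRESHOLD,
) -> float:
    """Closed-form long-area fraction of the retained population.

    Sum_k P(k) a_k (1 - p(L_k)) [L_k > thr] / Sum_k P(k) a_k (1 - p(L_k)),
    with area a_k proportional to length.
    """
    lengths = law.lengths
    keep = (np.asarray(law.pmf) * rod_area(lengths)
            * (1.0 - model.probability(lengths)))
    total = keep.sum()
    if total <= 0:
        raise ValueError("release model removes the entire population")
    return float(keep[lengths > threshold].sum() / total)


def calibrate_release_model(
    law: LengthLaw,
    relative_fall: float,
    p_base: float = 0.2,
    midpoint_length: float = LONG_LENGTH_THRESHOLD,
    steepness: float = 0.3,
) -> ReleaseModel:
    """Find p_max so the retained long-area fraction falls by
    ``relative_fall`` (e.g. 0.15 for a 15% relative fall) versus the
    unreleased population, holding the other parameters fixed."""
    base = law.long_area_fraction()
    target = base * (1.0 - relative_fall)

    def gap(p_max: float) -> float:
        m = ReleaseModel(p_base=p_base, p_max=p_max,
                         midpoint_length=midpoint_length, steepness=steepness)
        return expected_retained_long_area_fraction(law, m) - target

    hi = 1.0 - p_base
    if gap(hi) > 0:
        raise ValueError("relative_fall unreachable at this p_base")
    p_max = optimize.brentq(gap, 0.0, hi, xtol=1e-10)
    return ReleaseModel(p_base=p_base, p_max=p_max,
                        midpoint_length=midpoint_length, steepness=steepness)


# --------------------------------------------------------------------------
# Ground-truth containers
# --------------------------------------------------------------------------

@dataclass
class GranuleTruth:
    id: int
    centroid: tuple          # (x, y) um from top-left pixel center
    orientation: float       # radians
    n_quanta: int
    width: float = DEFAULT_GRANULE_WIDTH
    amplitude: float = 1.0
    released: bool = False

    @property
    def length(self) -> float:
        return self.n_quanta * QUANTUM_LENGTH

    @property
    def area(self) -> float:
        """Nominal footprint area in um^2 (rod with rounded caps)."""
        return float(rod_area(self.length, self.width))

    def to_dict(self) -> dict:
        return {
            "id": self.id, "x_um": self.centroid[0], "y_um": self.centroid[1],
            "orientation": self.orientation, "n_quanta": int(self.n_quanta),
            "length_um": self.length, "width_um": self.width,
            "amplitude": self.amplitude, "released": bool(self.released),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GranuleTruth":
        return cls(id=d["id"], centroid=(d["x_um"], d["y_um"]),
                   orientation=d["orientation"], n_quanta=d["n_quanta"],
                   width=d["width_um"], amplitude=d["amplitude"],
                   released=d["released"])


@dataclass
class NucleusTruth:
    centroid: tuple
    major_axis: float   # semi-axis, um
    minor_axis: float   # semi-axis, um
    orientation: float

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        dx, dy = x - self.centroid[0], y - self.centroid[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u, v = c * dx + s * dy, -s * dx + c * dy
        a, b = self.major_axis + margin, self.minor_axis + margin
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {"x_um": self.centroid[0], "y_um": self.centroid[1],
                "major_um": self.major_axis, "minor_um": self.minor_axis,
                "orientation": self.orientation}

    @classmethod
    def from_dict(cls, d: dict) -> "NucleusTruth":
        return cls(centroid=(d["x_um"], d["y_um"]), major_axis=d["major_um"],
                   minor_axis=d["minor_um"], orientation=d["orientation"])


@dataclass
class SiteTruth:
    centroid: tuple
    area: float       # um^2
    amplitude: float = 1.0

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)

    def to_dict(self) -> dict:
        return {"x_um": self.centroid[0], "y_um": self.centroid[1],
                "area_um2": self.area, "amplitude": self.amplitude}

    @classmethod
    def from_dict(cls, d: dict) -> "SiteTruth":
        return cls(centroid=(d["x_um"], d["y_um"]), area=d["area_um2"],
                   amplitude=d["amplitude"])


@dataclass
class FieldTruth:
    """Ground truth for one field: granules, nuclei and/or exocytic sites."""
    condition: str
    well: str
    field_id: str
    granules: list = field(default_factory=list)
    nuclei: list = field(default_factory=list)
    sites: list = field(default_factory=list)

    @property
    def image_id(self) -> str:
        return f"{self.condition}/{self.well}/{self.field_id}"

    def retained_granules(self) -> list:
        return [g for g in self.granules if not g.released]

    def long_area_fraction(self, threshold: float = LONG_LENGTH_THRESHOLD):
        """Long-area fraction of the retained granules; None if empty."""
        kept = self.retained_granules()
        if not kept:
            return None
        areas = np.array([g.area for g in kept])
        lengths = np.array([g.length for g in kept])
        return float(areas[lengths > threshold].sum() / areas.sum())

    def to_dict(self) -> dict:
        return {
            "condition": self.condition, "well": self.well,
            "field_id": self.field_id,
            "granules": [g.to_dict() for g in self.granules],
            "nuclei": [n.to_dict() for n in self.nuclei],
            "sites": [s.to_dict() for s in self.sites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldTruth":
        return cls(
            condition=d["condition"], well=d["well"], field_id=d["field_id"],
            granules=[GranuleTruth.from_dict(g) for g in d["granules"]],
            nuclei=[NucleusTruth.from_dict(n) for n in d["nuclei"]],
            sites=[SiteTruth.from_dict(s) for s in d["sites"]],
        )


@dataclass
class GroundTruthSet:
    """All ground truth for one generated plate."""
    fields: list

    def __iter__(self):
        return iter(self.fields)

    def __len__(self) -> int:
        return len(self.fields)

    def by_condition(self, condition: str) -> list:
        return [f for f in self.fields if f.condition == condition]

    def all_granules(self) -> list:
        return [g for f in self.fields for g in f.granules]


# --------------------------------------------------------------------------
# Plate design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateDesign:
    """Layout of a synthetic experiment.

    Defaults mirror a high-content screen acquiring nine fields per well
    with at least eight wells per condition.
    """

    conditions: tuple = ("Unstimulated",)
    wells_per_condition: int = 8
    fields_per_well: int = 9
    cells_per_field: tuple = (10, 20)
    granules_per_cell: tuple = (15, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_condition < 1 or self.fields_per_well < 1:
            raise ValueError("wells/fields per condition must be >= 1")
        for lo, hi in (self.cells_per_field, self.granules_per_cell):
            if not 1 <= lo <= hi:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")

    def well_labels(self, condition_index: int) -> list:
        return [f"W{condition_index:02d}{w:02d}"
                for w in range(self.wells_per_condition)]

    def n_fields(self) -> int:
        return len(self.conditions) * self.wells_per_condition * self.fields_per_well


# --------------------------------------------------------------------------
# Population sampling
# --------------------------------------------------------------------------

def _field_rng(seed: int, ci: int, wi: int, fi: int) -> np.random.Generator:
    """Deterministic per-field generator independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(ci, wi, fi)))


def _place_nuclei(rng: np.random.Generator, n: int, extent: tuple) -> list:
    """Rejection-sample non-overlapping ellipses inside the field."""
    h, w = extent
    nuclei: list = []
    for _ in range(n):
        for _attempt in range(200):
            a = rng.uniform(4.0, 6.0)          # semi-major, um
            b = rng.uniform(3.0, 4.5)          # semi-minor, um
            theta = rng.uniform(0, math.pi)
            x = rng.uniform(a, w - a)
            y = rng.uniform(a, h - a)
            ok = all(
                math.hypot(x - m.centroid[0], y - m.centroid[1])
                > a + m.major_axis
                for m in nuclei
            )
            if ok:
                nuclei.append(NucleusTruth((x, y), a, b, theta))
                break
    return nuclei


def sample_field_granules(
    rng: np.random.Generator,
    n_granules: int,
    law: LengthLaw,
    nuclei: Sequence[NucleusTruth],
    acq: AcquisitionModel,
    width: float = DEFAULT_GRANULE_WIDTH,
) -> list:
    """Sample granules with lengths from ``law``, placed uniformly in the
    field, avoiding nucleus interiors and the field border (a granule that
    would extend beyond the field is re-placed, never clipped)."""
    h, w = acq.field_extent
    edge = 3.0 * acq.psf_sigma + width
    quanta = law.sample(rng, n_granules)
    granules = []
    for i, k in enumerate(quanta):
        length = float(k) * law.quantum_length
        half = length / 2 + width / 2
        for _attempt in range(500):
            theta = rng.uniform(0, math.pi)
            x = rng.uniform(half + edge, w - half - edge)
            y = rng.uniform(half + edge, h - half - edge)
            dx, dy = half * math.cos(theta), half * math.sin(theta)
            ends_ok = all(
                edge <= x + s * dx <= w - edge and edge <= y + s * dy <= h - edge
                for s in (-1, 1)
            )
            in_nucleus = any(nu.contains(x, y, margin=half) for nu in nuclei)
            if ends_ok and not in_nucleus:
                granules.append(GranuleTruth(
                    id=i, centroid=(x, y), orientation=theta,
                    n_quanta=int(k), width=width))
                break
        else:
            raise RuntimeError("could not place granule; field too crowded")
    return granules


def sample_granule_population(
    design: PlateDesign,
    law: LengthLaw | None = None,
    acq: AcquisitionModel | None = None,
    seed: int | None = None,
) -> GroundTruthSet:
    """Sample every field of the plate: nuclei plus unreleased granules.

    Raises if ``law`` puts no mass above 4 quanta (> 2 um): the population
    would contain no long granules and the headline long-area-fraction
    statistic would be degenerate.
    """
    law = law or LengthLaw.truncated_geometric()
    acq = acq or AcquisitionModel()
    seed = design.seed if seed is None else seed
    if float(np.sum(np.asarray(law.pmf)[4:])) <= 0.0:
        raise ValueError(
            "length law has zero mass above 4 quanta (2 um): "
            "no long granules possible")
    fields = []
    for ci, cond in enumerate(design.conditions):
        for wi, well in enumerate(design.well_labels(ci)):
            for fi in range(design.fields_per_well):
                rng = _field_rng(seed, ci, wi, fi)
                n_cells = int(rng.integers(design.cells_per_field[0],
                                           design.cells_per_field[1] + 1))
                nuclei = _place_nuclei(rng, n_cells, acq.field_extent)
                per_cell = rng.integers(design.granules_per_cell[0],
                                        design.granules_per_cell[1] + 1,
                                        size=len(nuclei))
                granules = sample_field_granules(
                    rng, int(per_cell.sum()), law, nuclei, acq)
                fields.append(FieldTruth(
                    condition=cond, well=well, field_id=f"F{fi:02d}",
                    granules=granules, nuclei=nuclei))
    return GroundTruthSet(fields=fields)


def apply_release(
    truth: GroundTruthSet,
    model: ReleaseModel,
    seed: int,
) -> GroundTruthSet:
    """Flag each granule released with probability p(length), independently.

    Returns a new GroundTruthSet; released granules stay in the record
    (flagged) but are skipped by the renderer. Input must be unreleased.
    """
    if any(g.released for f in truth for g in f.granules):
        raise ValueError("population already has released granules")
    rng = np.random.default_rng(seed)
    fields = []
    for f in truth:
        lengths = np.array([g.length for g in f.granules])
        flips = (rng.random(len(f.granules)) < model.probability(lengths)
                 if len(f.granules) else np.zeros(0, bool))
        granules = [replace(g, released=bool(r))
                    for g, r in zip(f.granules, flips)]
        fields.append(FieldTruth(condition=f.condition, well=f.well,
                                 field_id=f.field_id, granules=granules,
                                 nuclei=list(f.nuclei), sites=list(f.sites)))
    return GroundTruthSet(fields=fields)


def apply_release_by_condition(
    truth: GroundTruthSet,
    models: dict,
    seed: int,
) -> GroundTruthSet:
    """Apply a per-condition release model (missing conditions: no release)."""
    out = []
    for ci, cond in enumerate(sorted({f.condition for f in truth})):
        sub = GroundTruthSet(truth.by_condition(cond))
        model = models.get(cond)
        if model is None:
            out.extend(sub.fields)
        else:
            out.extend(apply_release(sub, model, seed + 7919 * ci).fields)
    return GroundTruthSet(out)


# --------------------------------------------------------------------------
# Exocytic-site sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteAreaLaw:
    """Two-component log-normal mixture of site areas (um^2): small
    puncta (single fusion events) versus large spreads (actin-ring
    assisted release), so the > 2 um^2 classification is exercised."""

    small_log_mean: float = math.log(0.5)
    small_log_sd: float = 0.45
    large_log_mean: float = math.log(3.5)
    large_log_sd: float = 0.35
    large_prevalence: float = 0.3

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        big = rng.random(n) < self.large_prevalence
        areas = np.where(
            big,
            rng.lognormal(self.large_log_mean, self.large_log_sd, n),
            rng.lognormal(self.small_log_mean, self.small_log_sd, n),
        )
        return areas

    def expected_large_proportion(self, threshold: float = 2.0,
                                  n: int = 200_000, seed: int = 0) -> float:
        areas = self.sample(np.random.default_rng(seed), n)
        return float(np.mean(areas > threshold))


def sample_exosite_field(
    rng: np.random.Generator,
    n_sites: int,
    area_law: SiteAreaLaw,
    acq: AcquisitionModel,
    fusion_fraction: float = 0.0,
) -> list:
    """Place ``n_sites`` disk-shaped sites. A ``fusion_fraction`` of sites
    is placed touching the previous site (center gap 0.75 x sum of radii)
    to exercise watershed splitting; the rest are pairwise disjoint."""
    h, w = acq.field_extent
    edge = 3.0 * acq.psf_sigma
    areas = area_law.sample(rng, n_sites)
    sites: list = []
    for area in areas:
        r = math.sqrt(area / math.pi)
        fuse = sites and rng.random() < fusion_fraction
        for _attempt in range(500):
            if fuse:
                prev = sites[-1]
                phi = rng.uniform(0, 2 * math.pi)
                d = 0.75 * (r + prev.radius)
                x = prev.centroid[0] + d * math.cos(phi)
                y = prev.centroid[1] + d * math.sin(phi)
                others = sites[:-1]
            else:
                x = rng.uniform(r + edge, w - r - edge)
                y = rng.uniform(r + edge, h - r - edge)
                others = sites
            if not (r + edge <= x <= w - r - edge
                    and r + edge <= y <= h - r - edge):
                continue
            clear = all(
                math.hypot(x - s.centroid[0], y - s.centroid[1])
                > 1.3 * (r + s.radius)
                for s in others
            )
            if clear:
                sites.append(SiteTruth((x, y), float(area)))
                break
        else:
            raise RuntimeError("could not place exocytic site")
    return sites


def sample_exosite_population(
    design: PlateDesign,
    area_law: SiteAreaLaw | None = None,
    sites_per_field: tuple = (25, 45),
    fusion_fraction: float = 0.15,
    acq: AcquisitionModel | None = None,
    seed: int | None = None,
    area_laws: dict | None = None,
) -> GroundTruthSet:
    """Sample exocytic-site fields for every well of the plate.

    ``area_laws`` optionally maps condition -> SiteAreaLaw, so treatments
    that shift the large-site prevalence can be simulated per condition.
    """
    acq = acq or AcquisitionModel()
    seed = design.seed if seed is None else seed
    default_law = area_law or SiteAreaLaw()
    fields = []
    for ci, cond in enumerate(design.conditions):
        law = (area_laws or {}).get(cond, default_law)
        for wi, well in enumerate(design.well_labels(ci)):
            for fi in range(design.fields_per_well):
                rng = _field_rng(seed + 104729, ci, wi, fi)
                n = int(rng.integers(sites_per_field[0], sites_per_field[1] + 1))
                n_cells = int(rng.integers(design.cells_per_field[0],
                                           design.cells_per_field[1] + 1))
                nuclei = _place_nuclei(rng, n_cells, acq.field_extent)
                sites = sample_exosite_field(rng, n, law, acq, fusion_fraction)
                fields.append(FieldTruth(
                    condition=cond, well=well, field_id=f"F{fi:02d}",
                    nuclei=nuclei, sites=sites))
    return GroundTruthSet(fields=fields)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_SUPERSAMPLE = 4  # subpixels per pixel per axis for anti-aliased drawing


def _subpixel_grid(acq: AcquisitionModel):
    ss = _SUPERSAMPLE
    h, w = acq.field_shape
    return (h * ss, w * ss)


def _draw_rod(density: np.ndarray, g: GranuleTruth, acq: AcquisitionModel) -> None:
    """Accumulate an anti-aliased thick segment (rounded caps) into the
    supersampled density raster."""
    ss = _SUPERSAMPLE
    sub = acq.pixel_size / ss
    half = g.length / 2.0
    dx, dy = half * math.cos(g.orientation), half * math.sin(g.orientation)
    ax, ay = g.centroid[0] - dx, g.centroid[1] - dy
    bx, by = g.centroid[0] + dx, g.centroid[1] + dy
    r = g.width / 2.0
    # bounding box in subpixel indices (+0.5 px pad for anti-aliasing)
    pad = r + 2 * sub
    x0 = max(int((min(ax, bx) - pad) / sub + 0.5 * ss), 0)
    x1 = min(int((max(ax, bx) + pad) / sub + 0.5 * ss) + 1, density.shape[1])
    y0 = max(int((min(ay, by) - pad) / sub + 0.5 * ss), 0)
    y1 = min(int((max(ay, by) + pad) / sub + 0.5 * ss) + 1, density.shape[0])
    if (min(ax, bx) - pad < -0.5 * acq.pixel_size
            or min(ay, by) - pad < -0.5 * acq.pixel_size
            or max(ax, bx) + pad > acq.field_extent[1] - 0.5 * acq.pixel_size + acq.pixel_size
            or max(ay, by) + pad > acq.field_extent[0] - 0.5 * acq.pixel_size + acq.pixel_size):
        raise ValueError("granule extends beyond the field; re-place, do not clip")
    xs = (np.arange(x0, x1) + 0.5) * sub - 0.5 * acq.pixel_size
    ys = (np.arange(y0, y1) + 0.5) * sub - 0.5 * acq.pixel_size
    px, py = np.meshgrid(xs, ys)
    ex, ey = bx - ax, by - ay
    seg2 = ex * ex + ey * ey
    if seg2 == 0:
        d = np.hypot(px - ax, py - ay)
    else:
        t = np.clip(((px - ax) * ex + (py - ay) * ey) / seg2, 0.0, 1.0)
        d = np.hypot(px - (ax + t * ex), py - (ay + t * ey))
    cover = np.clip(0.5 + (r - d) / sub, 0.0, 1.0)
    density[y0:y1, x0:x1] += g.amplitude * cover


def _draw_disk(density: np.ndarray, s: SiteTruth, acq: AcquisitionModel) -> None:
    ss = _SUPERSAMPLE
    sub = acq.pixel_size / ss
    r = s.radius
    cx, cy = s.centroid
    pad = r + 2 * sub
    x0 = max(int((cx - pad) / sub + 0.5 * ss), 0)
    x1 = min(int((cx + pad) / sub + 0.5 * ss) + 1, density.shape[1])
    y0 = max(int((cy - pad) / sub + 0.5 * ss), 0)
    y1 = min(int((cy + pad) / sub + 0.5 * ss) + 1, density.shape[0])
    xs = (np.arange(x0, x1) + 0.5) * sub - 0.5 * acq.pixel_size
    ys = (np.arange(y0, y1) + 0.5) * sub - 0.5 * acq.pixel_size
    px, py = np.meshgrid(xs, ys)
    d = np.hypot(px - cx, py - cy)
    cover = np.clip(0.5 + (r - d) / sub, 0.0, 1.0)
    density[y0:y1, x0:x1] += s.amplitude * cover


def _draw_nucleus(density: np.ndarray, n: NucleusTruth, acq: AcquisitionModel,
                  amplitude: float) -> None:
    """Ellipse with a smooth center-weighted profile."""
    ss = _SUPERSAMPLE
    sub = acq.pixel_size / ss
    cx, cy = n.centroid
    a, b = n.major_axis, n.minor_axis
    pad = a + 2 * sub
    x0 = max(int((cx - pad) / sub + 0.5 * ss), 0)
    x1 = min(int((cx + pad) / sub + 0.5 * ss) + 1, density.shape[1])
    y0 = max(int((cy - pad) / sub + 0.5 * ss), 0)
    y1 = min(int((cy + pad) / sub + 0.5 * ss) + 1, density.shape[0])
    xs = (np.arange(x0, x1) + 0.5) * sub - 0.5 * acq.pixel_size
    ys = (np.arange(y0, y1) + 0.5) * sub - 0.5 * acq.pixel_size
    px, py = np.meshgrid(xs - cx, ys - cy)
    c, s = math.cos(n.orientation), math.sin(n.orientation)
    u = c * px + s * py
    v = -s * px + c * py
    rho2 = (u / a) ** 2 + (v / b) ** 2
    profile = np.clip(1.0 - rho2, 0.0, 1.0) * (0.6 + 0.4 * np.clip(1 - rho2, 0, 1))
    density[y0:y1, x0:x1] += amplitude * profile


def _develop(
    density: np.ndarray,
    acq: AcquisitionModel,
    rng: np.random.Generator,
    noise: bool,
) -> np.ndarray:
    """Blur with the PSF, integrate to camera pixels, apply Poisson shot
    noise, read noise, background, and quantize to the camera bit depth."""
    ss = _SUPERSAMPLE
    sigma_sub = acq.psf_sigma / (acq.pixel_size / ss)
    blurred = ndimage.gaussian_filter(density, sigma_sub, mode="reflect")
    h, w = acq.field_shape
    photons = blurred.reshape(h, ss, w, ss).mean(axis=(1, 3)) * acq.photon_scale
    if noise:
        img = rng.poisson(np.clip(photons, 0, None)).astype(float)
        img += rng.normal(0.0, acq.read_noise_sd, img.shape)
    else:
        img = photons
    img = img + acq.background_level
    return np.clip(np.rint(img), 0, acq.max_gray).astype(np.uint16)


NUCLEUS_AMPLITUDE = 1.5  # fluorophore density of the nuclear stain


def render_field(
    truth: FieldTruth,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    noise: bool = True,
) -> FieldImage:
    """Render one field: nuclei into channel 1, retained granules into
    channel 2, through the full optical + noise forward model.

    The same (truth, acq, seed) always yields a bit-identical image.
    """
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(seed)
    shape = _subpixel_grid(acq)
    nuc = np.zeros(shape)
    for n in truth.nuclei:
        _draw_nucleus(nuc, n, acq, NUCLEUS_AMPLITUDE)
    vwf = np.zeros(shape)
    for g in truth.retained_granules():
        _draw_rod(vwf, g, acq)
    return FieldImage(
        nuclear=_develop(nuc, acq, rng, noise),
        vwf=_develop(vwf, acq, rng, noise),
        pixel_size=acq.pixel_size,
        condition=truth.condition, well=truth.well, field_id=truth.field_id,
    )


def render_exosite_field(
    truth: FieldTruth,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    noise: bool = True,
) -> FieldImage:
    """Render an exocytic-site field: extracellular vWF patches as disks,
    nuclei in channel 1, same noise model as :func:`render_field`."""
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(seed)
    shape = _subpixel_grid(acq)
    nuc = np.zeros(shape)
    for n in truth.nuclei:
        _draw_nucleus(nuc, n, acq, NUCLEUS_AMPLITUDE)
    vwf = np.zeros(shape)
    for s in truth.sites:
        _draw_disk(vwf, s, acq)
    return FieldImage(
        nuclear=_develop(nuc, acq, rng, noise),
        vwf=_develop(vwf, acq, rng, noise),
        pixel_size=acq.pixel_size,
        condition=truth.condition, well=truth.well, field_id=truth.field_id,
    )


def render_plate(
    truth: GroundTruthSet,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    noise: bool = True,
    sites: bool = False,
):
    """Yield (FieldTruth, FieldImage) for every field of the plate, each
    rendered with a seed derived deterministically from its position."""
    acq = acq or AcquisitionModel()
    render = render_exosite_field if sites else render_field
    for i, f in enumerate(truth):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(31, i))
        yield f, render(f, acq, seed=int(child.generate_state(1)[0] >> 33), noise=noise)


# --------------------------------------------------------------------------
# Image-free simulation of the headline statistics
# --------------------------------------------------------------------------

def simulate_truth_statistics(
    design: PlateDesign,
    law: LengthLaw | None = None,
    release_models: dict | None = None,
    seed: int = 0,
    threshold: float = LONG_LENGTH_THRESHOLD,
) -> pd.DataFrame:
    """Per-image WPB statistics computed directly from sampled ground
    truth, skipping spatial placement and rendering.

    Used for replicate-scale statistical simulations (type-I error and
    power of the size-selection test) where image formation would add
    nothing but runtime. Returns one row per image with columns
    condition, well, field, n_wpb, n_nuclei, wpb_per_cell,
    long_area_fraction.
    """
    law = law or LengthLaw.truncated_geometric()
    release_models = release_models or {}
    rows = []
    for ci, cond in enumerate(design.conditions):
        model = release_models.get(cond)
        for wi, well in enumerate(design.well_labels(ci)):
            for fi in range(design.fields_per_well):
                rng = _field_rng(seed, ci, wi, fi)
                n_cells = int(rng.integers(design.cells_per_field[0],
                                           design.cells_per_field[1] + 1))
                per_cell = rng.integers(design.granules_per_cell[0],
                                        design.granules_per_cell[1] + 1,
                                        size=n_cells)
                n = int(per_cell.sum())
                quanta = law.sample(rng, n)
                lengths = quanta * law.quantum_length
                if model is not None:
                    keep = rng.random(n) >= model.probability(lengths)
                    lengths = lengths[keep]
                areas = rod_area(lengths)
                total = areas.sum()
                frac = (float(areas[lengths > threshold].sum() / total)
                        if total > 0 else np.nan)
                rows.append({
                    "condition": cond, "well": well, "field_id": f"F{fi:02d}",
                    "n_wpb": int(lengths.size), "n_nuclei": n_cells,
                    "wpb_per_cell": lengths.size / n_cells,
                    "long_area_fraction": frac,
                })
    return pd.DataFrame(rows)
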