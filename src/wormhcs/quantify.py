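"""Fluorescent readout quantification.

Per-object and whole-well spot metrics (count / total area / total
intensity), diffuse-signal threshold calibration for autophagy puncta,
red-head animal counting, per-animal normalization, labeled-neuron
counting, and live/dead scoring from dye-stained bodies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import CalibrationError, DataError


@dataclass
class SpotMetrics:
    """Aggregate fluorescent-spot readouts for one region (object or well)."""

    spot_count: int
    total_spot_area: float  # px^2
    total_spot_intensity: float  # summed pixel values over spot pixels

    def __post_init__(self):
        if self.spot_count == 0 and (self.total_spot_area or self.total_spot_intensity):
            raise DataError("zero spots must have zero area and intensity")


@dataclass
class HeadGate:
    """Conjunctive gate for counting pharyngeal head spots as animals.

    A fluorescent spot counts as one animal iff its area is at least
    ``min_spot_area`` AND its mean intensity is at least
    ``min_mean_intensity``; larval heads fall below the area bound.
    """

    min_spot_area: float
    min_mean_intensity: float

    def __post_init__(self):
        if self.min_spot_area < 0 or self.min_mean_intensity < 0:
            raise DataError("head gate bounds must be non-negative")


@dataclass
class PerAnimalMetrics:
    spot_count: float
    spot_area: float
    spot_intensity: float
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class WellMeasurement:
    """Aggregated readouts for one well."""

    plate: str
    well: str
    head_count: int = 0
    spot_count: int = 0
    spot_area: float = 0.0
    spot_intensity: float = 0.0
    per_animal_spot_count: float = float("nan")
    per_animal_spot_area: float = float("nan")
    per_animal_spot_intensity: float = float("nan")
    percent_dead: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""


def detect_spots(image: np.ndarray, intensity_threshold: float,
                 region: np.ndarray | None = None,
                 min_spot_px: int = 1) -> tuple[SpotMetrics, pd.DataFrame]:
    """Find bright spots above an intensity threshold within a region.

    Spots are 8-connected components of pixels strictly above
    ``intensity_threshold`` inside ``region`` (whole image when None), each
    at least ``min_spot_px`` pixels.  Returns aggregate metrics and a
    per-spot table (label, area, total/mean intensity, centroid).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DataError("detect_spots expects a 2-D image")
    mask = image > intensity_threshold
    if region is not None:
        mask &= region.astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    rows = []
    for lab in range(1, n + 1):
        m = labels == lab
        area = int(m.sum())
        if area < min_spot_px:
            continue
        vals = image[m]
        rr, cc = np.nonzero(m)
        rows.append(dict(label=len(rows) + 1, area=area,
                         total_intensity=float(vals.sum()),
                         mean_intensity=float(vals.mean()),
                         row=float(rr.mean()), col=float(cc.mean())))
    table = pd.DataFrame(rows, columns=["label", "area", "total_intensity",
                                        "mean_intensity", "row", "col"])
    metrics = SpotMetrics(
        spot_count=len(table),
        total_spot_area=float(table["area"].sum()) if len(table) else 0.0,
        total_spot_intensity=float(table["total_intensity"].sum()) if len(table) else 0.0,
    )
    return metrics, table


def calibrate_puncta_threshold(reference_images, reference_masks,
                               k: float = 3.0) -> float:
    """Intensity threshold from the diffuse signal of reference animals.

    Pools in-worm pixel intensities over the reference (well-fed, diffuse
    only) wells and returns mean + k * SD; spots above this threshold are
    counted as high-intensity puncta.
    """
    pixels = []
    for img, mask in zip(reference_images, reference_masks):
        vals = np.asarray(img, dtype=float)[np.asarray(mask, dtype=bool)]
        if vals.size:
            pixels.append(vals)
    if not pixels:
        raise CalibrationError("no in-worm pixels in the reference wells")
    pooled = np.concatenate(pixels)
    return float(pooled.mean() + k * pooled.std())


def count_heads(tritc_image: np.ndarray, gate: HeadGate,
                intensity_threshold: float | None = None,
                min_spot_px: int = 3) -> tuple[int, pd.DataFrame]:
    """Count animals by their fluorescent pharyngeal head spots.

    Operates in whole-well mode: no brightfield objects are required.  The
    pixel threshold defaults to Otsu on the image.  Each detected spot
    passing the conjunctive head gate counts as one animal; because heads
    are small relative to bodies, the count tolerates body overlap.
    """
    img = np.asarray(tritc_image, dtype=float)
    if intensity_threshold is None:
        if np.ptp(img) == 0:
            return 0, pd.DataFrame(columns=["label", "area", "total_intensity",
                                            "mean_intensity", "row", "col", "passes"])
        intensity_threshold = float(threshold_otsu(img))
    _, table = detect_spots(img, intensity_threshold, min_spot_px=min_spot_px)
    if len(table) == 0:
        table["passes"] = pd.Series(dtype=bool)
        return 0, table
    table["passes"] = ((table["area"] >= gate.min_spot_area)
                       & (table["mean_intensity"] >= gate.min_mean_intensity))
    return int(table["passes"].sum()), table


def calibrate_head_gate(reference_tritc_images, intensity_threshold: float | None = None,
                        min_spot_px: int = 3, area_quantile: float = 0.05,
                        pad: float = 0.35) -> HeadGate:
    """Calibrate a head gate from reference wells of target-stage animals only.

    The area bound is the ``area_quantile`` quantile of reference head-spot
    areas relaxed by the fractional ``pad``; the mean-intensity bound is
    derived the same way.  Larval heads, being far smaller, fall below the
    area bound.
    """
    areas, intens = [], []
    for img in reference_tritc_images:
        img = np.asarray(img, dtype=float)
        thr = intensity_threshold if intensity_threshold is not None else float(threshold_otsu(img))
        _, table = detect_spots(img, thr, min_spot_px=min_spot_px)
        areas.extend(table["area"].tolist())
        intens.extend(table["mean_intensity"].tolist())
    if not areas:
        raise CalibrationError("no head spots found in the reference wells")
    min_area = float(np.quantile(areas, area_quantile) * (1.0 - pad))
    min_int = float(np.quantile(intens, area_quantile) * (1.0 - pad))
    return HeadGate(min_spot_area=max(min_area, 0.0), min_mean_intensity=max(min_int, 0.0))


def per_animal_metrics(gfp: SpotMetrics, head_count: int) -> PerAnimalMetrics:
    """Normalize whole-well spot metrics by the animal (head) count.

    A well with zero heads is flagged excluded rather than raising — there
    is nothing to normalize by.
    """
    if head_count < 0:
        raise DataError("head_count must be >= 0")
    if head_count == 0:
        return PerAnimalMetrics(float("nan"), float("nan"), float("nan"),
                                excluded=True, exclusion_reason="zero heads")
    return PerAnimalMetrics(
        spot_count=gfp.spot_count / head_count,
        spot_area=gfp.total_spot_area / head_count,
        spot_intensity=gfp.total_spot_intensity / head_count,
    )


@dataclass
class NeuronSpotParams:
    """Spot gate for compact neuronal somata (small max-area bound
    distinguishes somata from diffuse or body-wide signal)."""

    intensity_threshold: float
    min_spot_px: int = 2
    max_spot_px: int = 60


def count_neurons(gfp_image: np.ndarray, objects,
                  params: NeuronSpotParams) -> list[int]:
    """Per-object count of compact high-intensity spots (labeled neurons).

    ``objects`` are :class:`~wormhcs.detect.DetectedObject` items carrying
    bbox-local masks from brightfield segmentation.
    """
    img = np.asarray(gfp_image, dtype=float)
    counts = []
    for obj in objects:
        region = np.zeros(img.shape, dtype=bool)
        r0, c0, r1, c1 = obj.bbox
        if obj.mask is not None:
            region[r0:r1, c0:c1] = obj.mask
        else:
            region[r0:r1, c0:c1] = True
        _, table = detect_spots(img, params.intensity_threshold, region=region,
                                min_spot_px=params.min_spot_px)
        if len(table):
            table = table[table["area"] <= params.max_spot_px]
        counts.append(int(len(table)))
    return counts


def count_green_bodies(gfp_image: np.ndarray, intensity_threshold: float | None = None,
                       min_body_px: int = 60,
                       typical_body_area: float | None = None) -> int:
    """Count dye-stained dead bodies in the green channel.

    Components smaller than ``min_body_px`` (about one worm-body
    cross-section) are treated as debris.  When ``typical_body_area`` is
    given, each component contributes ``max(1, round(area /
    typical_body_area))`` bodies, so clumps of adjacent dead animals are
    apportioned by area rather than counted once.
    """
    img = np.asarray(gfp_image, dtype=float)
    if intensity_threshold is None:
        if np.ptp(img) == 0:
            return 0
        intensity_threshold = float(threshold_otsu(img))
    _, table = detect_spots(img, intensity_threshold, min_spot_px=min_body_px)
    if len(table) == 0:
        return 0
    if typical_body_area is None:
        return int(len(table))
    return int(sum(max(1, round(a / typical_body_area)) for a in table["area"]))


def percent_dead(green_body_count: int, head_count: int) -> float:
    """100 * dead bodies / total animals, clipped to [0, 100].

    Merged dead bodies can double-count, so counts above the head count are
    clipped with a warning.  A zero head count leaves the quantity
    undefined (NaN); the caller should exclude the well.
    """
    if green_body_count < 0:
        raise DataError("green_body_count must be >= 0")
    if head_count == 0:
        return float("nan")
    pct = 100.0 * green_body_count / head_count
    if pct > 100.0:
        warnings.warn(f"percent dead {pct:.1f} > 100 clipped (merged bodies?)")
        pct = 100.0
    return float(np.clip(pct, 0.0, 100.0))


def flag_autofluorescent_wells(background_levels: pd.Series,
                               quantile: float = 0.99) -> pd.Series:
    """Flag wells whose out-of-worm background exceeds the plate quantile.

    ``background_levels`` holds one out-of-object background estimate per
    well (e.g. median GFP intensity outside all detected spots); wells above
    the given quantile of the plate distribution are nuisance candidates
    (autofluorescent compounds) to be excluded from hit statistics.
    """
    cut = background_levels.quantile(quantile)
    return background_levels > cut


def measurements_to_frame(measurements: list[WellMeasurement]) -> pd.DataFrame:
    """Flat per-well table for CSV export."""
    return pd.DataFrame([vars(m) for m in measurements])
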