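"""Brightfield worm detection and size gating.

Animals appear as dark elongated objects on a bright background.  Detection
is plain connected-component segmentation below an automatic (Otsu) or
fixed threshold; morphology (area, skeleton length, width from the
distance transform) is measured per object and a six-bound size window
selects valid animals of the target developmental stage.  Overlapping
animals merge into one component and are not untangled — the resulting
undercount at high densities is an accepted limitation of whole-body
counting, and the reason the fluorescent head-marker counting mode exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import CalibrationError, DataError

STATUSES = ("valid", "rejected_small", "rejected_large", "rejected_border")


@dataclass
class DetectedObject:
    """One segmented candidate animal (or merged clump)."""

    label: int
    area: int
    length: float  # geodesic length of the skeleton's longest path, px
    width: float  # mean of 2 x distance-transform value along the skeleton, px
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive
    touches_border: bool
    status: str = "valid"
    mask: np.ndarray | None = None  # bbox-local boolean mask


@dataclass
class SizeGate:
    """Inclusive morphology window; objects inside all six bounds are valid."""

    min_area: float
    max_area: float
    min_length: float
    max_length: float
    min_width: float
    max_width: float

    def __post_init__(self):
        for lo, hi in ((self.min_area, self.max_area),
                       (self.min_length, self.max_length),
                       (self.min_width, self.max_width)):
            if lo > hi:
                raise DataError(f"gate bound min {lo} exceeds max {hi}")


def _skeleton_length(mask: np.ndarray) -> float:
    """Longest geodesic path through the object's skeleton (8-connected)."""
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    n = len(coords)
    if n == 0:
        return float(max(mask.shape))
    if n == 1:
        return 1.0
    index = {tuple(p): i for i, p in enumerate(coords)}
    rows, cols, data = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    w = 1.0 if dr == 0 or dc == 0 else np.sqrt(2.0)
                    rows.append(i)
                    cols.append(j)
                    data.append(w)
    g = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    g = g + g.T
    # double-sweep: farthest node from an arbitrary endpoint, then farthest from it
    d0 = dijkstra(g, indices=0)
    a = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    d1 = dijkstra(g, indices=a)
    d1 = np.where(np.isinf(d1), np.nan, d1)
    return float(np.nanmax(d1)) + 1.0  # + 1 px for the two endpoint half-pixels


def _measure(mask: np.ndarray) -> tuple[float, float]:
    """(length, width) of one object from its bbox-local mask."""
    padded = np.pad(mask, 1)
    length = _skeleton_length(padded)
    edt = ndimage.distance_transform_edt(padded)
    skel = skeletonize(padded)
    if skel.any():
        width = float(2.0 * edt[skel].mean())
    else:
        width = float(2.0 * edt.max())
    return length, width


def segment_brightfield(image: np.ndarray, threshold_method: str = "otsu",
                        fixed_threshold: float | None = None,
                        min_component_px: int = 20) -> list[DetectedObject]:
    """Segment dark objects on a bright background into candidate animals.

    Objects are 8-connected components of pixels strictly darker than the
    threshold, after removal of components smaller than
    ``min_component_px``.  Labels are assigned in raster-scan order of the
    bounding-box top-left corner, so they are stable across runs.  A
    constant image yields no objects.  Objects touching the image border
    are marked ``rejected_border`` immediately (partial animals).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DataError("segment_brightfield expects a 2-D single-channel image")
    if np.ptp(image) == 0:
        return []
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise DataError("fixed threshold_method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        thr = float(threshold_otsu(image))
    else:
        raise DataError(f"unknown threshold_method {threshold_method!r}")

    fg = image < thr
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        return []
    objects: list[DetectedObject] = []
    slices = ndimage.find_objects(labels)
    items = []
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = labels[sl] == lab
        area = int(local.sum())
        if area < min_component_px:
            continue
        items.append((sl[0].start, sl[1].start, sl, local, area))
    items.sort(key=lambda t: (t[0], t[1]))

    for new_label, (r0, c0, sl, local, area) in enumerate(items, start=1):
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        touches = (bbox[0] == 0 or bbox[1] == 0
                   or bbox[2] == image.shape[0] or bbox[3] == image.shape[1])
        length, width = _measure(local)
        objects.append(DetectedObject(
            label=new_label, area=area, length=length, width=width, bbox=bbox,
            touches_border=touches,
            status="rejected_border" if touches else "valid", mask=local))
    return objects


def gate_objects(objects: list[DetectedObject], gate: SizeGate) -> list[DetectedObject]:
    """Set each object's status against an inclusive size window.

    Border-touching objects are always ``rejected_border``.  Otherwise an
    object is ``valid`` iff area, length and width all lie inside their
    inclusive bounds; ``rejected_large`` if any measure exceeds its max,
    else ``rejected_small``.  Objects are returned unchanged in order, so
    gating is idempotent and order-independent.
    """
    out = []
    for obj in objects:
        if obj.touches_border:
            status = "rejected_border"
        else:
            over = (obj.area > gate.max_area or obj.length > gate.max_length
                    or obj.width > gate.max_width)
            under = (obj.area < gate.min_area or obj.length < gate.min_length
                     or obj.width < gate.min_width)
            status = "rejected_large" if over else ("rejected_small" if under else "valid")
        out.append(replace(obj, status=status))
    return out


def calibrate_gate(reference_objects: list[DetectedObject],
                   quantile: float = 0.01, quantile_pad: float = 0.10) -> SizeGate:
    """Build a size gate from measured reference animals of the target stage.

    Bounds are the [quantile, 1 - quantile] quantiles of area, length and
    width, widened by the fractional ``quantile_pad`` on each side.  At
    least 10 reference objects are required.
    """
    if len(reference_objects) < 10:
        raise CalibrationError("calibrate_gate needs >= 10 reference objects")
    bounds = {}
    for name in ("area", "length", "width"):
        vals = np.array([getattr(o, name) for o in reference_objects], dtype=float)
        lo, hi = np.quantile(vals, [quantile, 1.0 - quantile])
        span = max(hi - lo, abs(hi), 1.0)
        bounds[name] = (lo - quantile_pad * span, hi + quantile_pad * span)
    return SizeGate(min_area=bounds["area"][0], max_area=bounds["area"][1],
                    min_length=bounds["length"][0], max_length=bounds["length"][1],
                    min_width=bounds["width"][0], max_width=bounds["width"][1])


def objects_to_frame(objects: list[DetectedObject], plate: str = "",
                     well: str = "") -> pd.DataFrame:
    """Flat per-object table for CSV export."""
    return pd.DataFrame([
        dict(plate=plate, well=well, label=o.label, area=o.area,
             length=o.length, width=o.width, status=o.status,
             touches_border=o.touches_border)
        for o in objects
    ])
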