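"""Synthetic data generation for whole-organism high-content screening.

Two layers are provided:

* an image layer that renders multi-channel well rasters containing
  worm-shaped objects (brightfield bodies, fluorescent pharyngeal "red
  heads", intestinal GFP inclusions, autophagy puncta, labeled
  mechanosensory neurons and dye-stained dead bodies) together with a
  pixel-level ground-truth label mask, and
* a measurement layer that simulates per-well readout tables for whole
  plates directly (control wells, planted hits, row/column gradients,
  day-to-day drift, autofluorescent nuisance wells), bypassing images, so
  the plate-statistics stage can be tested at scale.

Every function takes an explicit :class:`numpy.random.Generator` (or a seed);
no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .stats import PlateData

# ---------------------------------------------------------------------------
# Worm geometry
# ---------------------------------------------------------------------------

STAGE_ORDER = ("L1", "L2", "L3", "L4", "adult")

#: Mean body length in pixels per developmental stage at the default
#: 2.5x-equivalent scale.  Adults are ~70 px; each earlier stage is ~0.65x
#: the next.  Configurable via ``length_scale`` in the scene builders.
STAGE_LENGTH = {"adult": 70.0, "L4": 45.5, "L3": 29.6, "L2": 19.2, "L1": 12.5}

#: Mean body width (widest point) in pixels per stage.
STAGE_WIDTH = {"adult": 6.0, "L4": 4.0, "L3": 2.8, "L2": 2.0, "L1": 1.4}

#: Fraction of body area occupied by the fluorescent pharyngeal head marker.
HEAD_AREA_RATIO = 0.12

MAX_NEURONS = 6  # the six mechanosensory neurons


@dataclass
class WormSpec:
    """Ground-truth description of a single rendered animal."""

    stage: str
    body_length: float
    body_width: float
    centerline: np.ndarray  # (n, 2) float array of (row, col) points
    has_red_head: bool = True
    head_area: float = 0.0
    gfp_inclusion_count: int = 0
    puncta_count: int = 0
    labeled_neuron_count: int = 0
    is_dead: bool = False
    mask: np.ndarray | None = None  # full-frame boolean body mask (set by scene builder)

    def __post_init__(self):
        if self.stage not in STAGE_ORDER:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if not self.has_red_head:
            self.head_area = 0.0
        if not (0 <= self.labeled_neuron_count <= MAX_NEURONS):
            raise ConfigurationError("labeled_neuron_count must be in [0, 6]")


@dataclass
class SceneTruth:
    """Ground truth for one well: the animals and their interactions."""

    worms: list[WormSpec]
    frame: tuple[int, int]
    adult_count: int = 0
    dead_count: int = 0
    overlap_events: int = 0

    def __post_init__(self):
        self.adult_count = sum(1 for w in self.worms if w.stage == "adult")
        self.dead_count = sum(1 for w in self.worms if w.is_dead)

    def to_frame(self) -> pd.DataFrame:
        """One row per worm, suitable for writing as a truth CSV."""
        rows = []
        for i, w in enumerate(self.worms):
            rows.append(
                dict(
                    worm=i + 1,
                    stage=w.stage,
                    body_length=w.body_length,
                    body_width=w.body_width,
                    has_red_head=w.has_red_head,
                    head_area=w.head_area,
                    gfp_inclusion_count=w.gfp_inclusion_count,
                    puncta_count=w.puncta_count,
                    labeled_neuron_count=w.labeled_neuron_count,
                    is_dead=w.is_dead,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class NoiseModel:
    """Additive Gaussian pixel noise plus per-well illumination offset.

    Background levels are in arbitrary 16-bit camera units.
    """

    brightfield_bg: float = 3000.0
    brightfield_worm: float = 1200.0
    tritc_bg: float = 150.0
    gfp_bg: float = 120.0
    read_noise_sd: float = 25.0
    brightfield_noise_sd: float = 60.0
    illumination_offset_sd: float = 0.0  # per-well constant offset


@dataclass
class WellImageSet:
    """Raster stack for one well plus pixel geometry and ground truth."""

    channels: dict[str, np.ndarray]
    label_mask: np.ndarray
    scene: SceneTruth
    pixel_size_um: float = 6.45  # camera pixel at 2.5x with 0.63x coupler, nominal


KNOWN_CHANNELS = ("brightfield", "tritc", "gfp")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _sample_centerline(length: float, frame: tuple[int, int], rng, margin: float = 4.0,
                       step: float = 1.5, bend_sd: float = 0.22) -> np.ndarray:
    """Smooth correlated-random-walk centerline fitting inside the frame."""
    n_steps = max(int(round(length / step)), 2)
    for _ in range(200):
        start = np.array([
            rng.uniform(margin, frame[0] - margin),
            rng.uniform(margin, frame[1] - margin),
        ])
        heading = rng.uniform(0, 2 * math.pi)
        pts = [start]
        ok = True
        pos = start.copy()
        for _ in range(n_steps):
            heading += rng.normal(0.0, bend_sd)
            pos = pos + step * np.array([math.sin(heading), math.cos(heading)])
            if not (margin <= pos[0] < frame[0] - margin and margin <= pos[1] < frame[1] - margin):
                ok = False
                break
            pts.append(pos.copy())
        if ok:
            return np.asarray(pts)
    # fall back: straight segment clamped inside the frame
    start = np.array([frame[0] / 2.0, max(margin, frame[1] / 2.0 - length / 2.0)])
    t = np.linspace(0.0, 1.0, n_steps + 1)
    return np.stack([np.full_like(t, start[0]), start[1] + t * length], axis=1)


def _densify(centerline: np.ndarray, spacing: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~`spacing` px; returns points and arclength fractions."""
    seg = np.diff(centerline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total <= 0:
        return centerline[:1], np.zeros(1)
    n = max(int(total / spacing), 2)
    si = np.linspace(0.0, total, n)
    rows = np.interp(si, s, centerline[:, 0])
    cols = np.interp(si, s, centerline[:, 1])
    return np.stack([rows, cols], axis=1), si / total


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr * dr + dc * dc <= radius * radius
    return np.stack([dr[keep], dc[keep]], axis=1)


def rasterize_worm(worm: WormSpec, frame: tuple[int, int]) -> np.ndarray:
    """Boolean body mask: the centerline dilated to a tapering width profile."""
    mask = np.zeros(frame, dtype=bool)
    pts, frac = _densify(worm.centerline)
    half = worm.body_width / 2.0
    for (r, c), t in zip(pts, frac):
        # elliptical taper toward both ends, floor so thin worms stay connected
        radius = max(half * math.sqrt(max(1.0 - (2.0 * t - 1.0) ** 2, 0.04)), 0.75)
        offs = _disk_offsets(radius)
        rr = np.clip(np.round(offs[:, 0] + r).astype(int), 0, frame[0] - 1)
        cc = np.clip(np.round(offs[:, 1] + c).astype(int), 0, frame[1] - 1)
        mask[rr, cc] = True
    return mask


def _head_mask(worm: WormSpec, frame: tuple[int, int]) -> np.ndarray:
    """Pixels of the body mask nearest the head tip, ~head_area in total."""
    if worm.mask is None or worm.head_area <= 0:
        return np.zeros(frame, dtype=bool)
    tip = worm.centerline[0]
    rows, cols = np.nonzero(worm.mask)
    d2 = (rows - tip[0]) ** 2 + (cols - tip[1]) ** 2
    order = np.argsort(d2)
    n = min(int(round(worm.head_area)), rows.size)
    out = np.zeros(frame, dtype=bool)
    out[rows[order[:n]], cols[order[:n]]] = True
    return out


def count_overlap_events(worms: list[WormSpec]) -> int:
    """Number of pixel-adjacent worm pairs (masks touching within 1 px)."""
    from scipy.ndimage import binary_dilation

    events = 0
    dilated = [binary_dilation(w.mask, np.ones((3, 3), bool)) for w in worms]
    for i in range(len(worms)):
        for j in range(i + 1, len(worms)):
            if np.any(dilated[i] & worms[j].mask):
                events += 1
    return events


def make_worm(stage: str, frame: tuple[int, int], rng, *, length_scale: float = 1.0,
              has_red_head: bool = True, gfp_inclusion_count: int = 0,
              puncta_count: int = 0, labeled_neuron_count: int = 0,
              is_dead: bool = False, length_cv: float = 0.07) -> WormSpec:
    """Sample one worm of the given stage with stage-dependent size."""
    rng = _rng(rng)
    length = STAGE_LENGTH[stage] * length_scale * max(rng.normal(1.0, length_cv), 0.5)
    width = STAGE_WIDTH[stage] * max(rng.normal(1.0, length_cv), 0.5)
    centerline = _sample_centerline(length, frame, rng)
    body_area = 0.8 * length * width  # tapering ends shave ~20% off the rectangle
    head_area = 0.0
    if has_red_head:
        head_area = HEAD_AREA_RATIO * body_area * max(rng.normal(1.0, 0.10), 0.5)
    return WormSpec(
        stage=stage, body_length=length, body_width=width, centerline=centerline,
        has_red_head=has_red_head, head_area=head_area,
        gfp_inclusion_count=gfp_inclusion_count, puncta_count=puncta_count,
        labeled_neuron_count=labeled_neuron_count, is_dead=is_dead,
    )


def make_scene(n_worms: int, frame: tuple[int, int] = (256, 256), *,
               adult_fraction: float = 1.0,
               larval_stages: tuple[str, ...] = ("L1", "L2", "L3"),
               dead_fraction: float = 0.0,
               has_red_head: bool = True,
               gfp_inclusions: tuple[int, int] | None = None,
               puncta: tuple[int, int] | None = None,
               neurons: tuple[float, float] | None = None,
               avoid_overlap: bool = False,
               min_head_separation: float = 9.0,
               rng=None) -> SceneTruth:
    """Build a well scene of ``n_worms`` animals.

    Parameters
    ----------
    adult_fraction
        Fraction of animals at the adult stage; the remainder are drawn
        uniformly from ``larval_stages`` (the stages a size gate should
        reject).
    dead_fraction
        Fraction of animals marked dead (dye-stained bodies in the GFP
        channel).  Rounded to a whole number of animals.
    gfp_inclusions, puncta
        ``(low, high)`` inclusive ranges for per-animal counts of bright
        intestinal inclusions / autophagy puncta.
    neurons
        ``(mean, sd)`` for labeled mechanosensory neuron counts, clipped to
        [0, 6].
    avoid_overlap
        Re-draw each worm's placement (up to 60 attempts) until its body
        does not touch any previously placed worm; overlaps that survive
        the retries are kept and counted.
    min_head_separation
        Minimum distance in px between head tips of red-headed animals.
        Bodies may cross (worms crawl over one another) but two pharynges
        cannot occupy the same space; without this constraint independent
        placement lets rendered heads coincide, which has no physical
        counterpart.  Set to 0 to disable.
    """
    rng = _rng(rng)
    n_adult = int(round(n_worms * adult_fraction))
    stages = ["adult"] * n_adult + [
        str(rng.choice(larval_stages)) for _ in range(n_worms - n_adult)
    ]
    rng.shuffle(stages)
    n_dead = int(round(n_worms * dead_fraction))
    dead_flags = np.zeros(n_worms, dtype=bool)
    if n_dead:
        dead_flags[rng.choice(n_worms, size=n_dead, replace=False)] = True

    worms: list[WormSpec] = []
    occupied = np.zeros(frame, dtype=bool)
    from scipy.ndimage import binary_dilation

    for stage, dead in zip(stages, dead_flags):
        inc = int(rng.integers(gfp_inclusions[0], gfp_inclusions[1] + 1)) if gfp_inclusions else 0
        pun = int(rng.integers(puncta[0], puncta[1] + 1)) if puncta else 0
        neu = 0
        if neurons is not None:
            neu = int(np.clip(round(rng.normal(*neurons)), 0, MAX_NEURONS))
        attempts = 60 if (avoid_overlap or (has_red_head and min_head_separation > 0)) else 1
        worm = mask = None
        head_tips = [w.centerline[0] for w in worms if w.has_red_head]
        for _ in range(attempts):
            worm = make_worm(stage, frame, rng, gfp_inclusion_count=inc,
                             puncta_count=pun, labeled_neuron_count=neu,
                             has_red_head=has_red_head, is_dead=bool(dead))
            if (has_red_head and min_head_separation > 0 and any(
                    np.hypot(*(worm.centerline[0] - t)) < min_head_separation
                    for t in head_tips)):
                continue
            mask = rasterize_worm(worm, frame)
            if not avoid_overlap:
                break
            if not np.any(binary_dilation(mask, np.ones((3, 3), bool)) & occupied):
                break
        if mask is None:
            mask = rasterize_worm(worm, frame)
        worm.mask = mask
        occupied |= mask
        worms.append(worm)

    scene = SceneTruth(worms=worms, frame=frame)
    scene.overlap_events = count_overlap_events(worms)
    return scene


# ---------------------------------------------------------------------------
# Channel rendering
# ---------------------------------------------------------------------------

def _place_spots_in_mask(mask: np.ndarray, n: int, radius_range, rng,
                         min_separation: float = 3.0) -> list[tuple[int, int, float]]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or n == 0:
        return []
    spots: list[tuple[int, int, float]] = []
    for _ in range(n):
        for _attempt in range(50):
            k = int(rng.integers(rows.size))
            r, c = int(rows[k]), int(cols[k])
            if all((r - sr) ** 2 + (c - sc) ** 2 >= min_separation ** 2 for sr, sc, _ in spots):
                break
        spots.append((r, c, float(rng.uniform(*radius_range))))
    return spots


def _stamp(img: np.ndarray, r: int, c: int, radius: float, value: float) -> None:
    offs = _disk_offsets(radius)
    rr = np.clip(offs[:, 0] + r, 0, img.shape[0] - 1)
    cc = np.clip(offs[:, 1] + c, 0, img.shape[1] - 1)
    img[rr, cc] = np.maximum(img[rr, cc], value)


@dataclass
class FluorLevels:
    """Signal amplitudes (camera units) for rendered fluorophores."""

    head: float = 2500.0
    inclusion: float = 2200.0
    puncta: float = 1600.0
    neuron: float = 3000.0
    dead_body: float = 1800.0
    diffuse: float = 0.0  # in-worm diffuse GFP baseline (well-fed LGG-1 strains)


def render_well(scene: SceneTruth, channels=("brightfield", "tritc", "gfp"),
                noise_model: NoiseModel | None = None,
                levels: FluorLevels | None = None, rng=None) -> WellImageSet:
    """Render one well into per-channel rasters plus a ground-truth label mask.

    Brightfield shows dark worm bodies on a bright background; TRITC carries
    the pharyngeal red-head marker; GFP carries inclusions, puncta, labeled
    neurons, the diffuse baseline, and dye-stained dead bodies.  Additive
    Gaussian noise per the noise model is applied to every channel.
    """
    rng = _rng(rng)
    noise = noise_model or NoiseModel()
    levels = levels or FluorLevels()
    frame = scene.frame
    for ch in channels:
        if ch not in KNOWN_CHANNELS:
            raise ConfigurationError(f"unknown channel {ch!r}; known: {KNOWN_CHANNELS}")

    # ensure masks exist (scenes built by hand may lack them)
    for w in scene.worms:
        if w.mask is None:
            w.mask = rasterize_worm(w, frame)
    scene.overlap_events = count_overlap_events(scene.worms)

    label_mask = np.zeros(frame, dtype=np.int32)
    for i, w in enumerate(scene.worms):
        label_mask[w.mask] = i + 1

    illum = rng.normal(0.0, noise.illumination_offset_sd) if noise.illumination_offset_sd else 0.0
    out: dict[str, np.ndarray] = {}

    if "brightfield" in channels:
        img = np.full(frame, noise.brightfield_bg + illum, dtype=np.float64)
        img[label_mask > 0] = noise.brightfield_worm + illum
        img += rng.normal(0.0, noise.brightfield_noise_sd, frame)
        out["brightfield"] = np.clip(img, 0, 65535)

    if "tritc" in channels:
        img = np.full(frame, noise.tritc_bg + illum, dtype=np.float64)
        for w in scene.worms:
            if w.has_red_head:
                hm = _head_mask(w, frame)
                img[hm] = np.maximum(img[hm], levels.head * rng.normal(1.0, 0.05))
        img += rng.normal(0.0, noise.read_noise_sd, frame)
        out["tritc"] = np.clip(img, 0, 65535)

    if "gfp" in channels:
        img = np.full(frame, noise.gfp_bg + illum, dtype=np.float64)
        for w in scene.worms:
            if levels.diffuse > 0:
                img[w.mask] = np.maximum(img[w.mask], noise.gfp_bg + levels.diffuse)
            if w.is_dead:
                img[w.mask] = np.maximum(img[w.mask], levels.dead_body * rng.normal(1.0, 0.05))
            for r, c, rad in _place_spots_in_mask(w.mask, w.gfp_inclusion_count,
                                                  (1.4, 2.4), rng):
                _stamp(img, r, c, rad, levels.inclusion * rng.normal(1.0, 0.08))
            for r, c, rad in _place_spots_in_mask(w.mask, w.puncta_count,
                                                  (0.9, 1.5), rng):
                _stamp(img, r, c, rad, levels.puncta * rng.normal(1.0, 0.08))
            if w.labeled_neuron_count:
                pts, _ = _densify(w.centerline, spacing=1.0)
                idx = np.linspace(2, len(pts) - 3, w.labeled_neuron_count).astype(int)
                for r, c in pts[idx]:
                    _stamp(img, int(round(r)), int(round(c)), 1.6,
                           levels.neuron * rng.normal(1.0, 0.08))
        img += rng.normal(0.0, noise.read_noise_sd, frame)
        out["gfp"] = np.clip(img, 0, 65535)

    return WellImageSet(channels=out, label_mask=label_mask, scene=scene)


# ---------------------------------------------------------------------------
# Measurement-table simulation (statistics layer)
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Study conditions for a simulated plate screen.

    Defaults mirror the assay this pipeline models: 384-well plates, 35
    animals per well, ATM-like negative controls in the first two columns
    and ATZ-like positive controls in the last two, with control readout
    (total GFP spot area per animal) distributions 1.3 +/- 1.5 (negative)
    and 98.1 +/- 9.0 (positive).  Sample wells contain ATZ-like animals, so
    non-hit samples follow the positive-control distribution.
    """

    n_plates: int = 4
    wells_per_plate: int = 384
    animals_per_well: int = 35
    negative_columns: tuple[int, ...] = (0, 1)
    positive_columns: tuple[int, ...] = (22, 23)
    mu_n: float = 1.3
    sigma_n: float = 1.5
    mu_p: float = 98.1
    sigma_p: float = 9.0
    hit_fraction_down: float = 0.025
    hit_fraction_up: float = 0.012
    effect_size_down: float = 0.25  # multiplicative on the positive-control mean
    effect_size_up: float = 1.6
    row_gradient: float = 0.0  # additive top-to-bottom span
    col_gradient: float = 0.0
    day_drift: float = 0.0  # additive offset per sort day
    plate_days: tuple[int, ...] | None = None  # default: plate 1 on day 0, rest day 1
    autofluorescent_fraction: float = 0.0
    autofluorescent_offset: float = 120.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("hit_fraction_down", "hit_fraction_up", "autofluorescent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.animals_per_well <= 0:
            raise ConfigurationError("animals_per_well must be positive")
        if self.wells_per_plate not in (96, 384):
            raise ConfigurationError("wells_per_plate must be 96 or 384")
        if set(self.negative_columns) & set(self.positive_columns):
            raise ConfigurationError("negative and positive control columns overlap")
        n_cols = self.shape[1]
        for c in (*self.negative_columns, *self.positive_columns):
            if not 0 <= c < n_cols:
                raise ConfigurationError(f"control column {c} outside plate")

    @property
    def shape(self) -> tuple[int, int]:
        return (16, 24) if self.wells_per_plate == 384 else (8, 12)

    @property
    def samples_per_plate(self) -> int:
        n_rows, n_cols = self.shape
        return n_rows * (n_cols - len(self.negative_columns) - len(self.positive_columns))

    @property
    def n_compounds(self) -> int:
        return self.samples_per_plate * self.n_plates


def _compound_truth(config: ScreenSimConfig, rng) -> pd.DataFrame:
    """Assign hit classes to the compound list, shared across screen replicates."""
    n = config.n_compounds
    ids = [f"C{i + 1:04d}" for i in range(n)]
    n_down = int(round(config.hit_fraction_down * n))
    n_up = int(round(config.hit_fraction_up * n))
    perm = rng.permutation(n)
    cls = np.array(["none"] * n, dtype=object)
    cls[perm[:n_down]] = "down"
    cls[perm[n_down:n_down + n_up]] = "up"
    effect = np.ones(n)
    effect[cls == "down"] = config.effect_size_down
    effect[cls == "up"] = config.effect_size_up
    return pd.DataFrame({"compound_id": ids, "hit_class": cls, "effect": effect})


def simulate_measured_plate(config: ScreenSimConfig, plate_index: int = 0,
                            compound_truth: pd.DataFrame | None = None,
                            rng=None) -> tuple[PlateData, pd.DataFrame]:
    """Simulate the measurement table for one plate.

    Returns the :class:`~wormhcs.stats.PlateData` and a per-well ground-truth
    table (role, compound, hit class, autofluorescence flag, true mean).
    """
    rng = _rng(config.rng_seed if rng is None else rng)
    if compound_truth is None:
        compound_truth = _compound_truth(config, rng)
    n_rows, n_cols = config.shape
    sample_cols = [c for c in range(n_cols)
                   if c not in config.negative_columns and c not in config.positive_columns]

    values = np.empty((n_rows, n_cols))
    roles = np.empty((n_rows, n_cols), dtype=object)
    compounds = np.empty((n_rows, n_cols), dtype=object)
    compounds[:] = ""

    days = config.plate_days
    if days is None:
        days = tuple(0 if p == 0 else 1 for p in range(config.n_plates))
    day = days[plate_index] if plate_index < len(days) else days[-1]

    truth_rows = []
    k = plate_index * config.samples_per_plate
    af_mask = rng.random((n_rows, n_cols)) < config.autofluorescent_fraction

    for i in range(n_rows):
        for j in range(n_cols):
            hit_class = ""
            if j in config.negative_columns:
                role, mean = "negative_control", config.mu_n
                sigma = config.sigma_n
            elif j in config.positive_columns:
                role, mean = "positive_control", config.mu_p
                sigma = config.sigma_p
            else:
                role = "sample"
                row_t = compound_truth.iloc[k]
                compounds[i, j] = row_t.compound_id
                hit_class = row_t.hit_class
                mean = config.mu_p * row_t.effect
                sigma = config.sigma_p
                k += 1
            artifact = (config.row_gradient * (i / max(n_rows - 1, 1))
                        + config.col_gradient * (j / max(n_cols - 1, 1))
                        + config.day_drift * day)
            af = bool(af_mask[i, j]) and role == "sample"
            y = rng.normal(mean, sigma) + artifact
            if af:
                y += config.autofluorescent_offset
            values[i, j] = y
            roles[i, j] = role
            truth_rows.append(dict(
                plate=plate_index + 1, row=i, col=j, role=role,
                compound_id=compounds[i, j], hit_class=hit_class,
                autofluorescent=af, true_mean=mean + artifact,
            ))

    plate = PlateData(plate_id=f"plate{plate_index + 1}", values=values,
                      roles=roles, compound_ids=compounds)
    return plate, pd.DataFrame(truth_rows)


def simulate_screen(config: ScreenSimConfig, n_screens: int = 2,
                    rng=None) -> tuple[list[list[PlateData]], pd.DataFrame, pd.DataFrame]:
    """Simulate replicate screens of the full compound set.

    Hit assignments are drawn once and shared by every replicate, as for a
    re-screened library.  Returns ``(screens, compound_truth, well_truth)``
    where ``screens[s]`` is the list of plates of replicate ``s``.
    """
    rng = _rng(config.rng_seed if rng is None else rng)
    truth = _compound_truth(config, rng)
    screens = []
    well_truths = []
    for s in range(n_screens):
        plates = []
        for p in range(config.n_plates):
            plate, wt = simulate_measured_plate(config, p, compound_truth=truth, rng=rng)
            plate.plate_id = f"screen{s + 1}_plate{p + 1}"
            wt.insert(0, "screen", s + 1)
            plates.append(plate)
            well_truths.append(wt)
        screens.append(plates)
    return screens, truth, pd.concat(well_truths, ignore_index=True)


def make_dose_series(compound_effect, concentrations, replicates: int,
                     rng=None, control_mu: float = 98.1,
                     control_sigma: float = 9.0) -> pd.DataFrame:
    """Simulate per-animal readouts across a concentration series.

    ``compound_effect`` maps concentration (uM) to the expected readout;
    concentration 0 is always drawn from the DMSO control distribution
    ``Normal(control_mu, control_sigma)`` regardless of the effect function.
    ``replicates`` is the number of animals measured per concentration.
    """
    concentrations = list(concentrations)
    if any(c < 0 for c in concentrations):
        raise DataError("concentrations must be non-negative")
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    rng = _rng(rng)
    rows = []
    for c in concentrations:
        mean = control_mu if c == 0 else float(compound_effect(c))
        vals = rng.normal(mean, control_sigma, size=replicates)
        rows.append(pd.DataFrame({"concentration": c, "readout": vals}))
    return pd.concat(rows, ignore_index=True)
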