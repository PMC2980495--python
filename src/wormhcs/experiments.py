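"""Self-contained validation experiments on synthetic wells.

Each experiment generates its own calibration wells and test wells, runs
the detection path under test, and regresses detected quantities on ground
truth.  They reproduce, on synthetic data, the benchmark designs used to
validate whole-organism screening instruments: counting adults by their
fluorescent pharyngeal head marker across mixed-stage populations,
counting adults by brightfield whole-body segmentation (which undercounts
when bodies overlap), and scoring percent-dead from dye-stained bodies
across a kill-dose gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .detect import calibrate_gate, gate_objects, segment_brightfield
from .quantify import (calibrate_head_gate, count_green_bodies, count_heads,
                       detect_spots, percent_dead)
from .simulate import make_scene, render_well
from .stats import RegressionResult, agreement_regression


@dataclass
class AgreementExperiment:
    """Result of a detected-vs-truth agreement experiment."""

    regression: RegressionResult
    wells: pd.DataFrame  # per-well detected and true values


def red_head_agreement(seed: int, adult_fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                       replicates: int = 4, n_worms: int = 36,
                       frame=(256, 256)) -> AgreementExperiment:
    """Adult counting by gated red-head spots on mixed-stage wells.

    Calibrates a head gate on adult-only reference wells, then counts heads
    in wells of ``n_worms`` animals spanning the given adult fractions and
    regresses detected adult percentage on the sorted percentage.
    """
    rng = np.random.default_rng(seed)
    refs = []
    for _ in range(3):
        sc = make_scene(20, frame=frame, adult_fraction=1.0, rng=rng)
        refs.append(render_well(sc, channels=("tritc",), rng=rng).channels["tritc"])
    gate = calibrate_head_gate(refs)

    rows = []
    for frac in adult_fractions:
        for rep in range(replicates):
            sc = make_scene(n_worms, frame=frame, adult_fraction=frac, rng=rng)
            img = render_well(sc, channels=("tritc",), rng=rng).channels["tritc"]
            heads, _ = count_heads(img, gate)
            rows.append(dict(adult_fraction=frac, replicate=rep,
                             true_pct=100.0 * sc.adult_count / n_worms,
                             detected_pct=100.0 * heads / n_worms,
                             overlap_events=sc.overlap_events))
    wells = pd.DataFrame(rows)
    reg = agreement_regression(wells["detected_pct"], wells["true_pct"])
    return AgreementExperiment(regression=reg, wells=wells)


def brightfield_adult_agreement(seed: int,
                                adult_fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                                replicates: int = 3, n_worms: int = 36,
                                frame=(256, 256)) -> AgreementExperiment:
    """Adult counting by brightfield segmentation plus an adult size gate.

    Calibrates the size window from isolated reference adults, then counts
    gate-passing objects in mixed-stage wells.  The window's lower bounds
    exclude larvae and debris while the upper bounds are left loose (10x
    the calibrated values), matching how such instruments are configured:
    a clump of overlapping adults segments as one discrete object and is
    counted once, not resolved.  The resulting undercount pulls the
    regression slope below 1 at high densities; at low densities the slope
    approaches 1.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    ref_objects = []
    while len(ref_objects) < 30:
        sc = make_scene(8, frame=frame, adult_fraction=1.0, avoid_overlap=True, rng=rng)
        img = render_well(sc, channels=("brightfield",), rng=rng).channels["brightfield"]
        ref_objects += [o for o in segment_brightfield(img) if o.status == "valid"]
    gate = calibrate_gate(ref_objects)
    gate = dataclasses.replace(gate, max_area=10 * gate.max_area,
                               max_length=10 * gate.max_length,
                               max_width=10 * gate.max_width)

    rows = []
    for frac in adult_fractions:
        for rep in range(replicates):
            sc = make_scene(n_worms, frame=frame, adult_fraction=frac, rng=rng)
            img = render_well(sc, channels=("brightfield",), rng=rng).channels["brightfield"]
            objs = gate_objects(segment_brightfield(img), gate)
            n_valid = sum(1 for o in objs if o.status == "valid")
            rows.append(dict(adult_fraction=frac, replicate=rep,
                             true_pct=100.0 * sc.adult_count / n_worms,
                             detected_pct=100.0 * n_valid / n_worms,
                             overlap_events=sc.overlap_events))
    wells = pd.DataFrame(rows)
    reg = agreement_regression(wells["detected_pct"], wells["true_pct"])
    return AgreementExperiment(regression=reg, wells=wells)


def live_dead_agreement(seed: int,
                        dead_fractions=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                        replicates: int = 2, n_worms: int = 50,
                        frame=(320, 320)) -> AgreementExperiment:
    """Percent-dead scoring from dye-stained bodies across a kill gradient.

    Calibration uses sparse all-dead reference wells to fix the green
    intensity threshold and the typical single-body area (merged clumps of
    adjacent dead animals are apportioned by area), plus adult-only wells
    for the head gate.  Detected percent dead (green bodies / red heads) is
    regressed on the true dead percentage.
    """
    rng = np.random.default_rng(seed)
    areas: list[float] = []
    thresholds: list[float] = []
    for _ in range(3):
        sc = make_scene(6, frame=frame, adult_fraction=1.0, dead_fraction=1.0,
                        avoid_overlap=True, rng=rng)
        gfp = render_well(sc, channels=("gfp",), rng=rng).channels["gfp"]
        t = float(threshold_otsu(gfp))
        thresholds.append(t)
        _, tbl = detect_spots(gfp, t, min_spot_px=60)
        areas.extend(tbl["area"].tolist())
    green_threshold = float(np.mean(thresholds))
    body_area = float(np.median(areas))

    refs = []
    for _ in range(2):
        sc = make_scene(20, frame=frame, adult_fraction=1.0, rng=rng)
        refs.append(render_well(sc, channels=("tritc",), rng=rng).channels["tritc"])
    head_gate = calibrate_head_gate(refs)

    rows = []
    for frac in dead_fractions:
        for rep in range(replicates):
            sc = make_scene(n_worms, frame=frame, adult_fraction=1.0,
                            dead_fraction=frac, rng=rng)
            imgs = render_well(sc, channels=("tritc", "gfp"), rng=rng)
            heads, _ = count_heads(imgs.channels["tritc"], head_gate)
            green = count_green_bodies(imgs.channels["gfp"],
                                       intensity_threshold=green_threshold,
                                       min_body_px=60, typical_body_area=body_area)
            rows.append(dict(dead_fraction=frac, replicate=rep,
                             true_pct=100.0 * sc.dead_count / n_worms,
                             detected_pct=percent_dead(green, heads)))
    wells = pd.DataFrame(rows)
    reg = agreement_regression(wells["detected_pct"], wells["true_pct"])
    return AgreementExperiment(regression=reg, wells=wells)
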