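"""End-to-end screen orchestration: inputs -> well measurements -> screen
statistics -> hit report, with reproducible configuration and a run manifest.

The pipeline stages (simulate, detect, quantify, stats, report) are all
independently callable from Python; the :mod:`wormhcs.cli` module exposes
them as shell subcommands.  Every run writes a machine-readable manifest
(config hash, package versions, calibration values) sufficient to reproduce
it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .io import load_reference_hit_table, write_well_images
from .quantify import WellMeasurement, measurements_to_frame
from .simulate import (ScreenSimConfig, make_dose_series, make_scene,
                       render_well, simulate_screen)
from .stats import (PlateData, call_hits, median_polish, bscore, plate_zscores,
                    rank_scores, zprime)

logger = logging.getLogger("wormhcs")


@dataclass
class RunConfig:
    """Configuration of one screen-analysis run."""

    mode: str = "simulate"  # {simulate, measurements}
    measurements: list[str] = field(default_factory=list)  # CSVs, one per screen replicate
    readout: str = "per_animal_spot_area"
    normalization: str = "both"  # {zscore, bscore, both}
    pool_controls: bool = False
    low_cut: float | None = None  # None -> scaled defaults
    high_cut: float | None = None
    sim: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    n_screens: int = 2
    rng_seed: int = 0
    output_dir: str = "wormhcs_run"

    def __post_init__(self):
        if self.mode not in ("simulate", "measurements"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.normalization not in ("zscore", "bscore", "both"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.mode == "measurements" and not self.measurements:
            raise ConfigurationError("measurements mode requires measurement CSV paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = payload.pop("sim", None)
        cfg = cls(**payload)
        if sim:
            cfg.sim = ScreenSimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                         for k, v in sim.items()})
        return cfg


def analyze_screens(screens: list[list[PlateData]], normalization: str = "both",
                    pool_controls: bool = False, low_cut: float | None = None,
                    high_cut: float | None = None) -> dict[str, pd.DataFrame]:
    """Screen statistics across replicate screens of plates.

    Computes per-plate QC (Z'-factor, row/column effect spans), per-compound
    z-scores and B-scores, cross-screen rank-scores and hit classes.
    Returns ``{"qc": ..., "results": ..., "hits": ...}``.
    """
    qc_rows = []
    per_screen_bscores: list[pd.Series] = []
    per_screen_zscores: list[pd.Series] = []

    for s_idx, plates in enumerate(screens, start=1):
        b_parts, z_parts = {}, {}
        for plate in plates:
            try:
                ctrl = plate.control_stats()
                zp = zprime(ctrl)
            except DataError:
                ctrl, zp = None, float("nan")
            polish = median_polish(plate)
            qc_rows.append(dict(
                screen=s_idx, plate=plate.plate_id, zprime=zp,
                n_samples=int(plate.sample_mask.sum()),
                n_excluded=int((plate.roles == "excluded").sum()),
                row_effect_span=float(np.nanmax(polish.row_effects)
                                      - np.nanmin(polish.row_effects)),
                col_effect_span=float(np.nanmax(polish.col_effects)
                                      - np.nanmin(polish.col_effects)),
                mad=polish.mad, polish_iterations=polish.n_iterations,
            ))
            if normalization in ("bscore", "both"):
                b = bscore(polish)
                for (i, j) in zip(*np.nonzero(plate.sample_mask)):
                    b_parts[plate.compound_ids[i, j]] = b[i, j]
            if normalization in ("zscore", "both"):
                z = plate_zscores(plate, pool_controls=pool_controls)
                for (i, j) in zip(*np.nonzero(plate.sample_mask)):
                    z_parts[plate.compound_ids[i, j]] = z[i, j]
        if b_parts:
            per_screen_bscores.append(pd.Series(b_parts, name=f"screen{s_idx}"))
        if z_parts:
            per_screen_zscores.append(pd.Series(z_parts, name=f"screen{s_idx}"))

    qc = pd.DataFrame(qc_rows)
    score_source = per_screen_bscores if per_screen_bscores else per_screen_zscores
    scores = pd.concat(score_source, axis=1)
    ranks = rank_scores(scores)
    hits = call_hits(ranks["rank_score"], low_cut=low_cut, high_cut=high_cut)

    results = scores.copy()
    results.columns = [f"bscore_{c}" if per_screen_bscores else f"zscore_{c}"
                       for c in results.columns]
    if per_screen_zscores and per_screen_bscores:
        zs = pd.concat(per_screen_zscores, axis=1)
        zs.columns = [f"zscore_{c}" for c in zs.columns]
        results = results.join(zs)
    results = results.join(ranks)
    results["hit_class"] = hits
    results.index.name = "compound_id"

    hit_list = results[results["hit_class"] != "none"].sort_values("rank_score")
    return {"qc": qc, "results": results.reset_index(),
            "hits": hit_list.reset_index()}


def _manifest(config: RunConfig, extras: dict) -> dict:
    cfg = config.to_dict()
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "wormhcs_version": __version__,
        "numpy_version": np.__version__,
        **extras,
    }


def run_screen(config: RunConfig) -> dict[str, Path]:
    """Run the full screen analysis; deterministic given config + seed.

    Writes measurement CSVs (simulate mode), a QC report, the per-compound
    result table, the hit list, and a run manifest.  Returns the output
    paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)

    extras: dict = {}
    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, rng_seed=config.rng_seed)
        screens, truth, well_truth = simulate_screen(sim, n_screens=config.n_screens,
                                                     rng=rng)
        for s_idx, plates in enumerate(screens, start=1):
            frames = pd.concat([p.to_frame() for p in plates], ignore_index=True)
            frames.to_csv(outdir / f"measurements_screen{s_idx}.csv", index=False)
        truth.to_csv(outdir / "compound_truth.csv", index=False)
        extras["simulated"] = True
    else:
        screens = []
        for path in config.measurements:
            # round_trip parsing keeps re-read values bit-identical to what
            # was written, so re-analysis of intermediate CSVs is lossless
            df = pd.read_csv(path, float_precision="round_trip")
            if df.empty:
                raise DataError(f"measurement table {path} contains no wells")
            plates = [PlateData.from_frame(df, plate_id=pid)
                      for pid in df["plate"].unique()]
            screens.append(plates)
        extras["simulated"] = False

    logger.info("analyzing %d screens, normalization=%s", len(screens),
                config.normalization)
    tables = analyze_screens(screens, normalization=config.normalization,
                             pool_controls=config.pool_controls,
                             low_cut=config.low_cut, high_cut=config.high_cut)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    for _, row in tables["qc"].iterrows():
        logger.info("QC screen %s plate %s: Z'=%.3f MAD=%.3f",
                    row["screen"], row["plate"], row["zprime"], row["mad"])

    manifest = _manifest(config, extras)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths


FIXTURE_KINDS = ("toy_images", "null_plate", "spiked_screen", "dose_series")


def make_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write a named synthetic fixture set; identical seed, identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    if kind == "toy_images":
        for w in range(4):
            scene = make_scene(8, frame=(256, 256), adult_fraction=0.5,
                               gfp_inclusions=(0, 4), rng=rng)
            imgs = render_well(scene, rng=rng)
            written += write_well_images(imgs, outdir, "toy", f"w{w + 1}")
    elif kind == "null_plate":
        cfg = ScreenSimConfig(n_plates=1, hit_fraction_down=0.0, hit_fraction_up=0.0,
                              rng_seed=seed)
        plates, truth, _ = simulate_screen(cfg, n_screens=1, rng=rng)
        p = outdir / "null_plate.csv"
        plates[0][0].to_frame().to_csv(p, index=False)
        written.append(p)
    elif kind == "spiked_screen":
        cfg = ScreenSimConfig(n_plates=4, rng_seed=seed, row_gradient=3.0,
                              day_drift=5.0)
        screens, truth, well_truth = simulate_screen(cfg, n_screens=2, rng=rng)
        for s_idx, plates in enumerate(screens, start=1):
            p = outdir / f"spiked_screen{s_idx}.csv"
            pd.concat([pl.to_frame() for pl in plates], ignore_index=True).to_csv(
                p, index=False)
            written.append(p)
        tp = outdir / "spiked_truth.csv"
        truth.to_csv(tp, index=False)
        written.append(tp)
    elif kind == "dose_series":
        df = make_dose_series(lambda c: 98.1 * (1.0 - 0.8 * c / (c + 10.0)),
                              [0, 1, 5, 10, 25, 50, 100], replicates=140, rng=rng)
        p = outdir / "dose_series.csv"
        df.to_csv(p, index=False)
        written.append(p)
    else:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    return written


def published_hit_summary() -> dict:
    """Hit calling applied to the bundled published rank-score table.

    Returns the decreaser/increaser candidate counts at the default
    thresholds and the dose-response verification tallies among the
    compounds that were retested.
    """
    table = load_reference_hit_table()
    classes = call_hits(table.set_index("compound")["rank_score"],
                        low_cut=110.0, high_cut=1225.0)
    table = table.assign(hit_class=classes.to_numpy())
    tested = table[table["dose_tested"]]
    dd = tested[tested["dose_dependent"].astype("boolean").fillna(False)]
    return {
        "n_decreasers": int((table["hit_class"] == "decreaser_candidate").sum()),
        "n_increasers": int((table["hit_class"] == "increaser_candidate").sum()),
        "n_dose_tested_decreasers": int((tested["hit_class"] == "decreaser_candidate").sum()),
        "n_dose_tested_increasers": int((tested["hit_class"] == "increaser_candidate").sum()),
        "n_dose_dependent_decreasers": int((dd["hit_class"] == "decreaser_candidate").sum()),
        "n_dose_dependent_increasers": int((dd["hit_class"] == "increaser_candidate").sum()),
    }
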