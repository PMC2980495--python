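"""File I/O: 16-bit TIFF rasters, YAML gates/configs, bundled reference data."""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import SizeGate
from .quantify import HeadGate
from .simulate import WellImageSet


def write_image(path, image: np.ndarray) -> None:
    """Write a single-channel raster as 16-bit TIFF."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_well_images(well_images: WellImageSet, outdir, plate: str, well: str) -> list[Path]:
    """One TIFF per channel, named ``{plate}_{well}_{channel}.tif``, plus the
    ground-truth label mask and a per-worm truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for channel, image in well_images.channels.items():
        p = outdir / f"{plate}_{well}_{channel}.tif"
        write_image(p, image)
        written.append(p)
    mask_path = outdir / f"{plate}_{well}_labels.tif"
    tifffile.imwrite(str(mask_path), well_images.label_mask.astype(np.uint16))
    written.append(mask_path)
    truth_path = outdir / f"{plate}_{well}_truth.csv"
    well_images.scene.to_frame().to_csv(truth_path, index=False)
    written.append(truth_path)
    return written


def save_gate(gate, path) -> None:
    """Persist a SizeGate or HeadGate as YAML."""
    payload = {"kind": type(gate).__name__, **dataclasses.asdict(gate)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_gate(path):
    payload = yaml.safe_load(Path(path).read_text())
    kind = payload.pop("kind")
    cls = {"SizeGate": SizeGate, "HeadGate": HeadGate}[kind]
    return cls(**payload)


def load_reference_hit_table() -> pd.DataFrame:
    """Bundled published hit table: per-compound rank-scores with the
    dose-response verification outcome for the compounds that were retested."""
    with resources.files("wormhcs").joinpath("data/table1_rank_scores.csv").open() as fh:
        df = pd.read_csv(fh)
    df["dose_tested"] = df["dose_tested"].fillna(False).astype(bool)
    return df
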