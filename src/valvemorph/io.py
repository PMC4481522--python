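"""Plain-text and image I/O for pipeline artifacts.

Images travel as 8-bit grayscale PNG/TIFF with a CSV ground-truth
sidecar; tabular data (density series, volume histograms, feature
tables) as CSV; reports and provenance as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import FeatureTable
from .imageprep import RasterImage
from .morphometry import FEATURE_NAMES
from .popdyn import DensitySeries, VolumeDistribution


def write_image(path: str | Path, img: RasterImage) -> None:
    path = Path(path)
    iio.imwrite(path, np.asarray(img.pixels, np.uint8))
    sidecar = {"pixel_size_um": img.pixel_size_um}
    for k in ("supply", "seed", "label"):
        if k in img.meta:
            sidecar[k] = img.meta[k]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> RasterImage:
    path = Path(path)
    pixels = iio.imread(path)
    if pixels.ndim == 3:
        pixels = pixels[..., 0]
    meta, pixel_size = {}, 1.0
    sc = path.with_suffix(".json")
    if sc.exists():
        meta = json.loads(sc.read_text())
        pixel_size = float(meta.pop("pixel_size_um", 1.0))
    return RasterImage(pixels, pixel_size, meta)


def write_density_series(path: str | Path, s: DensitySeries) -> None:
    df = pd.DataFrame({"time_h": s.times_h, "cells_per_ml": s.density})
    if s.biovolume is not None:
        df["biovolume_um3_per_ml"] = s.biovolume
    df.to_csv(path, index=False)


def read_density_series(path: str | Path) -> DensitySeries:
    df = pd.read_csv(path)
    bio = df["biovolume_um3_per_ml"].values if "biovolume_um3_per_ml" in df else None
    return DensitySeries(df["time_h"].values, df["cells_per_ml"].values, bio)


def write_volume_distributions(path: str | Path, dists: list[VolumeDistribution]) -> None:
    rows = []
    for vd in dists:
        for lo, hi, n in zip(vd.bin_edges_um3[:-1], vd.bin_edges_um3[1:], vd.counts):
            rows.append((vd.time_h, lo, hi, n))
    pd.DataFrame(
        rows, columns=["time_h", "bin_low_um3", "bin_high_um3", "count"]
    ).to_csv(path, index=False)


def read_volume_distributions(
    path: str | Path, dilution_factor: float = 50.0, analyzed_sample_volume_mL: float = 0.1
) -> list[VolumeDistribution]:
    df = pd.read_csv(path)
    out = []
    for t, g in df.groupby("time_h", sort=True):
        edges = np.concatenate([g["bin_low_um3"].values, g["bin_high_um3"].values[-1:]])
        out.append(
            VolumeDistribution(
                float(t), edges, g["count"].values,
                dilution_factor, analyzed_sample_volume_mL,
            )
        )
    return out


def write_feature_table(path: str | Path, t: FeatureTable) -> None:
    df = t.data.copy()
    df["label"] = t.labels
    if t.condition is not None:
        df["condition"] = t.condition
    df.to_csv(path, index_label="image_id")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="image_id")
    labels = df["label"] if "label" in df else None
    condition = df["condition"] if "condition" in df else None
    return FeatureTable(df[FEATURE_NAMES], labels, condition)
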