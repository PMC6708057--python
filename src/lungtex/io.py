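"""Disk formats: 16-bit TIFF images, 8-bit PNG masks, JSON sidecars,
CSV feature tables and histograms."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .core import GrayImage, RoiSet
from .phantom import PhantomSpec
from .preprocess import IntensityHistogram


def write_image(path: str | Path, img: GrayImage) -> None:
    dtype = np.uint16 if img.bit_depth == 16 else np.uint8
    tifffile.imwrite(str(path), img.pixels.astype(dtype))


def read_image(path: str | Path, bit_depth: int = 16) -> GrayImage:
    return GrayImage(tifffile.imread(str(path)), bit_depth=bit_depth)


def write_rois(directory: str | Path, stem: str, rois: RoiSet) -> list[Path]:
    """One 8-bit PNG (0/255) per ROI mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mask in rois.masks.items():
        p = directory / f"{stem}_{name}.png"
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(p)
        paths.append(p)
    return paths


def read_rois(directory: str | Path, stem: str) -> RoiSet:
    directory = Path(directory)
    masks = {}
    for p in sorted(directory.glob(f"{stem}_*.png")):
        name = p.stem[len(stem) + 1 :]
        masks[name] = np.asarray(Image.open(p)) > 127
    if not masks:
        raise FileNotFoundError(f"no masks named {stem}_*.png in {directory}")
    return RoiSet(masks=masks)


def write_sidecar(path: str | Path, spec: PhantomSpec) -> None:
    Path(path).write_text(json.dumps(spec.to_json_dict(), indent=2))


def read_sidecar(path: str | Path) -> PhantomSpec:
    return PhantomSpec.from_json_dict(json.loads(Path(path).read_text()))


def write_histogram(path: str | Path, hist: IntensityHistogram) -> None:
    """Template histogram as CSV (bin_edge, count); the final edge is
    written with an empty count."""
    df = pd.DataFrame(
        {
            "bin_edge": hist.bin_edges,
            "count": np.append(hist.counts, np.nan),
        }
    )
    df.to_csv(path, index=False)


def read_histogram(path: str | Path) -> IntensityHistogram:
    df = pd.read_csv(path)
    return IntensityHistogram(
        bin_edges=df["bin_edge"].to_numpy(),
        counts=df["count"].to_numpy()[:-1].astype(np.int64),
    )


def write_features(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
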