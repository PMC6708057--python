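"""Intensity standardization and ROI set arithmetic.

Projection images vary considerably in contrast across subjects, so before
any texture statistic is computed each image is (1) clipped at extreme
percentiles to remove outlier intensities and (2) histogram-matched to a
single template distribution, after which all images share an identical
grayscale distribution. ROI set arithmetic then derives the lung–heart
overlap and the outside-rib-cage complement used for window labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage, RoiSet


@dataclass
class IntensityHistogram:
    """A binned intensity distribution used as a matching template.

    ``bin_edges`` has one more entry than ``counts`` and spans the full
    bit-depth range of the source image.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_image(cls, img: GrayImage, n_bins: int = 65536) -> "IntensityHistogram":
        """Histogram of an image over its full bit-depth range."""
        edges = np.linspace(0, img.max_value + 1, n_bins + 1)
        counts, _ = np.histogram(img.pixels, bins=edges)
        return cls(bin_edges=edges, counts=counts)

    def quantiles(self, q: np.ndarray) -> np.ndarray:
        """Template values at rank fractions ``q`` (stepwise CDF inversion).

        Each bin is represented by its lower edge, so matching an integer
        image to its own unit-bin histogram reproduces it exactly.
        """
        if self.total <= 0:
            raise ValueError("empty template histogram")
        values = self.bin_edges[:-1]
        nz = self.counts > 0
        if nz.sum() == 1:
            return np.full(np.shape(q), values[nz][0])
        cdf = np.cumsum(self.counts) / self.total
        idx = np.searchsorted(cdf, np.asarray(q), side="left")
        idx = np.clip(idx, 0, values.size - 1)
        return values[idx]


def clip_percentiles(
    img: GrayImage, lo_pct: float = 0.0001, hi_pct: float = 0.999
) -> GrayImage:
    """Threshold outlier intensities at extreme percentiles.

    Pixels below the ``lo_pct`` quantile are raised to it and pixels above
    the ``hi_pct`` quantile lowered to it; everything in between is
    untouched. Defaults clip at the 0.01th and 99.9th percentiles.
    Quantiles use linear interpolation; a constant image passes through
    unchanged.
    """
    if not 0.0 <= lo_pct < hi_pct <= 1.0:
        raise ValueError("require 0 <= lo_pct < hi_pct <= 1")
    lo, hi = np.quantile(img.pixels, [lo_pct, hi_pct])
    clipped = np.clip(img.pixels, lo, hi)
    if np.issubdtype(img.pixels.dtype, np.integer):
        clipped = np.rint(clipped).astype(img.pixels.dtype)
    return GrayImage(clipped, bit_depth=img.bit_depth, pixel_pitch_um=img.pixel_pitch_um)


def histogram_match(img: GrayImage, template: IntensityHistogram) -> GrayImage:
    """Exact rank-based histogram specification.

    Every pixel is replaced by the template quantile at its own rank
    fraction, with ties broken by raster order (stable sort of the
    flattened image). The output's empirical distribution equals the
    template distribution up to bin quantization, the mapping is monotone
    in pixel rank, and matching twice to the same template equals matching
    once.
    """
    if template.total <= 0:
        raise ValueError("template histogram is empty")
    flat = img.pixels.ravel()
    order = np.argsort(flat, kind="stable")  # raster-order tie break
    n = flat.size
    q = (np.arange(n) + 0.5) / n
    values = template.quantiles(q)
    out = np.empty(n, dtype=float)
    out[order] = values
    out = out.reshape(img.pixels.shape)
    if np.issubdtype(img.pixels.dtype, np.integer):
        out = np.rint(out).astype(img.pixels.dtype)
    return GrayImage(out, bit_depth=img.bit_depth, pixel_pitch_um=img.pixel_pitch_um)


def standardize(
    img: GrayImage,
    template: IntensityHistogram,
    lo_pct: float = 0.0001,
    hi_pct: float = 0.999,
) -> GrayImage:
    """Clip outliers then histogram-match to the template."""
    return histogram_match(clip_percentiles(img, lo_pct, hi_pct), template)


def derive_rois(base: RoiSet) -> RoiSet:
    """Add the set-arithmetic products to a base ROI set.

    ``lung_heart_overlap`` is the intersection of the lung union with the
    heart envelope, and ``outside_ribcage`` the complement of the rib
    cage. The heart base mask itself is not used as a training region
    downstream, but remains present so the overlap stays recomputable.
    """
    for name in ("rib_cage", "right_lung", "left_lung", "heart"):
        if name not in base:
            raise ValueError(f"missing base mask {name!r}")
    masks = dict(base.masks)
    lung = base.lung()
    masks["lung_heart_overlap"] = lung & base["heart"]
    masks["outside_ribcage"] = ~base["rib_cage"]
    out = RoiSet(masks=masks)
    return out
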