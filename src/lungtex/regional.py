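"""Post-classification spatial analyses.

Covers the optional cleanup of a predicted lung-window mask (fill holes,
drop small regions), an unsupervised cranial-caudal regionalization of
lung-window locations by k-means, per-region horizontality summaries, and
the rank-correlation check that texture orientation is not a proxy for
local image brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.cluster import KMeans

#: 4-connectivity structuring element on the window lattice. Window strides
#: overlap, so 8-connectivity would over-merge diagonal neighbours.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

REGION_NAMES = ("U", "M", "L")  # upper, middle, lower


@dataclass
class RegionPartition:
    """k-means regions over window centres, ordered cranially to caudally.

    ``labels[i]`` is the region index of ``centers[i]``; region 0 has the
    smallest mean row (upper), region k-1 the largest (lower).
    """

    centers: np.ndarray
    labels: np.ndarray
    k: int

    def region_names(self) -> list[str]:
        if self.k == 3:
            return list(REGION_NAMES)
        return [f"R{i}" for i in range(self.k)]


def postprocess_lung_mask(window_mask: np.ndarray, min_region: int = 5) -> np.ndarray:
    """Clean a binary window-level lung mask.

    Holes enclosed by positive regions are filled, then 4-connected
    positive regions smaller than ``min_region`` windows are removed.
    Mirrors the fill-holes / particle-size exclusion post-processing used
    to tidy a raw per-window segmentation.
    """
    mask = np.asarray(window_mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask, structure=_STRUCT4)
    labels, n = ndimage.label(filled, structure=_STRUCT4)
    if n == 0:
        return filled
    sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_region) + 1
    return np.isin(labels, keep)


def kmeans_regions(centers: np.ndarray, k: int = 3, seed: int = 0,
                   n_init: int = 10) -> RegionPartition:
    """Cluster window locations into k spatial regions.

    Plain k-means on the (row, col) coordinates with multiple seeded
    restarts; clusters are relabeled by ascending mean row so region 0 is
    the most cranial (upper) and region k-1 the most caudal (lower).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("centers must be (n, 2)")
    if centers.shape[0] < k:
        raise ValueError(f"need at least k={k} centers, got {centers.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(centers)
    mean_rows = np.array([centers[raw == i, 0].mean() for i in range(k)])
    order = np.argsort(mean_rows, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return RegionPartition(centers=centers, labels=relabel[raw], k=k)


def regional_horizontality(
    features: pd.DataFrame, partition: RegionPartition,
    column: str = "horizontality", threshold_raw: float = 0.0,
) -> pd.DataFrame:
    """Five-number summaries of (standardized) horizontality per region.

    ``features`` rows must align with ``partition.labels``. Returns one
    row per region (min, q25, median, q75, max, mean, n) plus the
    region name, and attaches the standardized position of the raw
    vertical-horizontal threshold (``threshold_raw``, default h = 0) as
    the ``threshold`` attribute column so box plots can draw it.
    """
    if len(features) != partition.labels.size:
        raise ValueError("feature rows do not align with the partition")
    vals = features[column].to_numpy(dtype=float)
    rows = []
    for i, name in enumerate(partition.region_names()):
        v = vals[partition.labels == i]
        if v.size == 0:
            rows.append({"region": name, "n": 0, "empty": True})
            continue
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "region": name, "n": int(v.size), "empty": False,
                "min": float(v.min()), "q25": float(q25), "median": float(med),
                "q75": float(q75), "max": float(v.max()), "mean": float(v.mean()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = float(threshold_raw)
    return out


def texture_intensity_decorrelation(h: np.ndarray, m: np.ndarray) -> float:
    """Kendall rank correlation (tie-adjusted tau-b) between horizontality
    and the median window intensity.

    A small magnitude indicates the orientation statistic is not merely
    tracking local brightness. Windowed medians tie frequently on
    quantized images, hence the tie-adjusted variant. Raises on constant
    input, where tau is undefined.
    """
    h = np.asarray(h, dtype=float)
    m = np.asarray(m, dtype=float)
    if h.size != m.size or h.size < 2:
        raise ValueError("need two equal-length columns with n >= 2")
    if np.all(h == h[0]) or np.all(m == m[0]):
        raise ValueError("tau undefined for a constant column")
    return float(stats.kendalltau(h, m, variant="b").statistic)
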