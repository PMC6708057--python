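"""End-to-end orchestration: simulate -> standardize -> features ->
classify -> regional summaries.

These drivers tie the modules together for cohort-level experiments and
are what both the command-line interface and the acceptance script call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as cl
from . import features as ft
from . import phantom as ph
from . import preprocess as pp
from .core import GrayImage, RoiSet


def cohort_feature_table(
    cohort: list[tuple[ph.PhantomSpec, GrayImage, RoiSet]],
    side: int = 32,
    stride: int = 16,
    purity: float = 0.95,
    standardize: bool = True,
) -> pd.DataFrame:
    """Standardize a cohort and compute per-window features and labels.

    The first image supplies the template histogram; every image is
    percentile-clipped and histogram-matched to it, so the identity-mode
    range common to all images is the template's range. Each returned row
    carries the 11 predictors, the image's mouse id and pressure, the
    window centre, a segmentation label (``seg_label``: 1 lung, 0
    not-lung, -1 excluded) and per-lung purity flags used by the pressure
    tasks (``right_lung_win``, ``left_lung_win``).
    """
    if not cohort:
        raise ValueError("empty cohort")
    template_img = pp.clip_percentiles(cohort[0][1])
    template = pp.IntensityHistogram.from_image(template_img, n_bins=4096)
    lo = float(template_img.pixels.min())
    hi = float(template_img.pixels.max())
    global_range = (lo, hi) if hi > lo else (0.0, 65535.0)

    frames = []
    for i, (spec, img, rois) in enumerate(cohort):
        if standardize:
            img = pp.standardize(img, template)
        rois = pp.derive_rois(rois)
        grid = ft.make_window_grid(*img.shape, side=side, stride=stride)
        table = ft.build_feature_table(
            img, global_range, grid, mouse_id=spec.mouse_id, pressure=spec.pressure
        )
        table["image_id"] = f"{spec.mouse_id}_p{spec.pressure}_{i}"
        table["seg_label"] = cl.assign_window_labels(
            grid, rois, "segmentation", purity=purity
        )
        for lung in ("right", "left"):
            lab = cl.assign_window_labels(
                grid, rois, "pressure", purity=purity,
                pressure=spec.pressure, lung_region=lung,
            )
            table[f"{lung}_lung_win"] = lab != cl.EXCLUDED
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def segmentation_cv(
    features: pd.DataFrame,
    pressures: list[int] | None = None,
    n_trees: int = 128,
    seed: int = 0,
    return_predictions: bool = False,
):
    """Per-pressure leave-one-mouse-out segmentation cross-validation.

    One binary experiment is run per (pressure, held-out mouse); an
    8-mouse, 4-pressure cohort therefore runs 32 experiments. Returns a
    dict pressure -> CVReport (and pooled per-window predictions when
    requested).
    """
    if pressures is None:
        pressures = sorted(features["pressure"].unique())
    std = cl.zscore_per_mouse(features)
    reports: dict[int, cl.CVReport] = {}
    preds = []
    for j, p in enumerate(sorted(pressures)):
        ds = std[std["pressure"] == p].copy()
        ds["label"] = ds["seg_label"]
        res = cl.lomo_cv(ds, "segmentation", n_trees=n_trees,
                         seed=seed + j, return_predictions=return_predictions)
        if return_predictions:
            reports[p], fr = res
            fr = fr.copy()
            fr["task_pressure"] = p
            preds.append(fr)
        else:
            reports[p] = res
    if return_predictions:
        return reports, pd.concat(preds, ignore_index=True)
    return reports


def pressure_cv(
    features: pd.DataFrame,
    pressures: list[int] | None = None,
    lung_region: str = "both",
    n_trees: int = 128,
    seed: int = 0,
    return_predictions: bool = False,
):
    """Multiclass (or paired) pressure classification, leave-one-mouse-out.

    Windows pure within the chosen lung region(s) are labeled with their
    image's pressure; ``pressures`` restricts to a subset (e.g. a {6, 12}
    pair). Returns the CVReport, plus per-image plurality votes when
    predictions are requested.
    """
    std = cl.zscore_per_mouse(features)
    if lung_region == "both":
        in_lung = std["right_lung_win"] | std["left_lung_win"]
    else:
        in_lung = std[f"{lung_region}_lung_win"]
    ds = std[in_lung].copy()
    if pressures is not None:
        ds = ds[ds["pressure"].isin(pressures)]
    ds["label"] = ds["pressure"]
    res = cl.lomo_cv(ds, "pressure", n_trees=n_trees, seed=seed,
                     return_predictions=return_predictions)
    if return_predictions:
        report, preds = res
        votes = (
            preds.groupby("image_id")
            .apply(
                lambda g: pd.Series(
                    {
                        "true_pressure": g["pressure"].iloc[0],
                        "voted_pressure": cl.plurality_vote(g["predicted"]),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
        return report, preds, votes
    return res
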