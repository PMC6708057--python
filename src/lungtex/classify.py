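"""Window labeling, balancing, standardization and cross-validated
random-forest classification.

Two tasks share the same 11 window predictors. *Segmentation* is a binary
lung/not-lung discrimination: windows at least 95% inside the declared
lung regions are labeled 1, windows at least 95% inside certainly-not-lung
regions (outside the rib cage, or the mediastinal spine band) are labeled
0, and ambiguous windows (e.g. lung overlapping heart or diaphragm in
projection) are excluded from training but can still be scored. *Pressure*
is a 4-class discrimination of the ventilation pressure from lung-window
texture, summarized per image by a plurality vote.

Training always balances class counts exactly, standardizes every
predictor to z-scores per mouse, and validates by leaving one mouse out
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier

from .core import RoiSet
from .features import PREDICTORS, WindowGrid

#: Sentinel label for windows excluded from training by the purity rule.
EXCLUDED = -1


@dataclass
class FoldResult:
    """One leave-one-mouse-out fold."""

    holdout: str
    classes: np.ndarray
    confusion: np.ndarray  # rows = true class, cols = predicted, counts
    n_eval: int

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / max(self.confusion.sum(), 1))


@dataclass
class CVReport:
    """Cross-validation summary: one fold per held-out mouse."""

    task: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def se_accuracy(self) -> float:
        """Standard error of the fold accuracies (sd / sqrt(n_folds))."""
        a = self.accuracies
        return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "mean_accuracy": self.mean_accuracy,
            "se_accuracy": self.se_accuracy,
            "folds": [
                {
                    "holdout": f.holdout,
                    "classes": f.classes.tolist(),
                    "confusion": f.confusion.tolist(),
                    "accuracy": f.accuracy,
                    "n_eval": f.n_eval,
                }
                for f in self.folds
            ],
        }


# ---------------------------------------------------------------------------
# labeling


def _window_fraction(mask: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Fraction of each window's pixels inside ``mask`` (flat, row-major)."""
    return grid.windows(mask.astype(np.float64)).mean(axis=(2, 3)).ravel()


def assign_window_labels(
    grid: WindowGrid,
    rois: RoiSet,
    task: str,
    purity: float = 0.95,
    pressure: int | None = None,
    lung_region: str = "both",
) -> np.ndarray:
    """Assign a training label to every grid window via the purity rule.

    A window enters training only if at least ``purity`` of its pixels
    carry a single region label. For the segmentation task, the declared
    lung is the lung union minus heart and diaphragm overlap, and the
    declared not-lung is the outside-rib-cage region plus the spine band;
    everything else is excluded (label -1). For the pressure task every
    pure lung window receives the image's pressure; ``lung_region``
    restricts to ``"right"``, ``"left"`` or ``"both"`` lungs.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must lie in (0.5, 1]")
    if task == "segmentation":
        lung = rois.lung()
    elif task == "pressure":
        if pressure is None:
            raise ValueError("pressure task requires the image's pressure")
        if lung_region == "both":
            lung = rois.lung()
        else:
            lung = rois[f"{lung_region}_lung"]
    else:
        raise ValueError(f"unknown task {task!r}")

    clear_lung = lung & ~rois["heart"] & ~rois["diaphragm"]
    lung_frac = _window_fraction(clear_lung, grid)

    labels = np.full(grid.n_windows, EXCLUDED, dtype=int)
    if task == "segmentation":
        not_lung = rois["outside_ribcage"].copy()
        if "spine" in rois:
            not_lung |= rois["spine"] & ~rois["heart"] & ~rois["diaphragm"]
        not_frac = _window_fraction(not_lung, grid)
        labels[lung_frac >= purity] = 1
        labels[not_frac >= purity] = 0
    else:
        labels[lung_frac >= purity] = pressure
    return labels


def balance_labels(ds: pd.DataFrame, seed: int, label_col: str = "label") -> pd.DataFrame:
    """Downsample every class to the minority-class count, without
    replacement, deterministically under ``seed``."""
    counts = ds[label_col].value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("balancing requires >= 2 non-empty classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(counts.index):
        idx = ds.index[ds[label_col] == cls].to_numpy()
        take = rng.choice(idx, size=n_min, replace=False)
        parts.append(ds.loc[np.sort(take)])
    return pd.concat(parts)


def zscore_per_mouse(
    ds: pd.DataFrame, predictors: list[str] | None = None
) -> pd.DataFrame:
    """Transform each predictor to z-scores within each mouse's rows.

    Uses the population standard deviation; a zero-variance column within
    a mouse maps to all zeros. Standardization is per mouse, so no
    information crosses mouse boundaries and the held-out mouse of any
    fold is standardized purely from its own windows.
    """
    predictors = predictors or PREDICTORS
    out = ds.copy()
    for _, idx in ds.groupby("mouse_id").indices.items():
        block = ds.iloc[idx][predictors].to_numpy(dtype=float)
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        z = (block - mean) / sd_safe
        z[:, sd == 0] = 0.0
        out.iloc[idx, [out.columns.get_loc(p) for p in predictors]] = z
    return out


# ---------------------------------------------------------------------------
# training and cross-validation


def train_forest(
    ds: pd.DataFrame,
    n_trees: int = 128,
    seed: int = 0,
    predictors: list[str] | None = None,
    label_col: str = "label",
) -> RandomForestClassifier:
    """Fit the random forest (128 trees, standard classification defaults:
    sqrt(p) features per split, unlimited depth), deterministic under
    ``seed``."""
    predictors = predictors or PREDICTORS
    y = ds[label_col].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(ds[predictors].to_numpy(dtype=float), y)
    return clf


def enumerate_experiments(
    mouse_ids: list[str], pressures: list[int]
) -> list[tuple[int, str]]:
    """All (pressure, held-out mouse) segmentation experiments.

    One binary segmentation classifier is trained per pressure and per
    held-out mouse, so an 8-mouse, 4-pressure cohort enumerates 32
    experiments (8 folds per pressure).
    """
    return [(p, m) for p in sorted(set(pressures)) for m in sorted(set(mouse_ids))]


def lomo_cv(
    ds: pd.DataFrame,
    task: str,
    n_trees: int = 128,
    seed: int = 0,
    predictors: list[str] | None = None,
    return_predictions: bool = False,
) -> CVReport | tuple[CVReport, pd.DataFrame]:
    """Leave-one-mouse-out cross-validation on a labeled feature table.

    ``ds`` must carry the predictor columns, ``mouse_id`` and ``label``
    (with excluded windows already dropped or marked -1) and should be
    per-mouse standardized. For each mouse in turn, training pools all
    other mice, balances labels exactly (seeded), fits the forest, and
    scores every labeled held-out window. Folds whose training split
    lacks a class are skipped with a warning. With
    ``return_predictions`` the per-window held-out predictions are also
    returned.
    """
    predictors = predictors or PREDICTORS
    labeled = ds[ds["label"] != EXCLUDED]
    mice = sorted(labeled["mouse_id"].unique())
    if len(mice) < 2:
        raise ValueError("leave-one-mouse-out requires >= 2 mice")
    classes = np.sort(labeled["label"].unique())
    report = CVReport(task=task)
    pred_frames = []
    rng = np.random.default_rng(seed)
    for mouse in mice:
        fold_seed = int(rng.integers(0, 2**31 - 1))
        train = labeled[labeled["mouse_id"] != mouse]
        test = labeled[labeled["mouse_id"] == mouse]
        if np.unique(train["label"]).size < classes.size or test.empty:
            import warnings

            warnings.warn(f"fold {mouse!r} skipped: missing class or empty test")
            continue
        train = balance_labels(train, seed=fold_seed)
        clf = train_forest(train, n_trees=n_trees, seed=fold_seed,
                           predictors=predictors)
        pred = clf.predict(test[predictors].to_numpy(dtype=float))
        truth = test["label"].to_numpy()
        idx = {c: i for i, c in enumerate(classes)}
        confusion = np.zeros((classes.size, classes.size), dtype=int)
        for t, p in zip(truth, pred):
            confusion[idx[t], idx[p]] += 1
        report.folds.append(
            FoldResult(holdout=mouse, classes=classes, confusion=confusion,
                       n_eval=len(test))
        )
        if return_predictions:
            f = test.copy()
            f["predicted"] = pred
            f["holdout"] = mouse
            pred_frames.append(f)
    if return_predictions:
        preds = pd.concat(pred_frames) if pred_frames else pd.DataFrame()
        return report, preds
    return report


def plurality_vote(window_predictions) -> int:
    """Image-level class call: the most frequent per-window prediction,
    ties broken toward the lowest class value."""
    arr = np.asarray(list(window_predictions))
    if arr.size == 0:
        raise ValueError("empty prediction list")
    values, counts = np.unique(arr, return_counts=True)
    return int(values[counts == counts.max()].min())


def confusion_probabilities(report: CVReport) -> np.ndarray:
    """Ensemble-averaged row-normalized confusion probabilities.

    Each fold's confusion matrix is row-normalized (true class rows sum
    to 1) and the matrices averaged over folds; an empty row in a fold is
    excluded from that row's average and yields NaN only if empty in all
    folds.
    """
    if not report.folds:
        raise ValueError("empty report")
    k = report.folds[0].confusion.shape[0]
    acc = np.zeros((k, k))
    cnt = np.zeros(k)
    for f in report.folds:
        sums = f.confusion.sum(axis=1)
        for i in range(k):
            if sums[i] > 0:
                acc[i] += f.confusion[i] / sums[i]
                cnt[i] += 1
    with np.errstate(invalid="ignore"):
        out = acc / cnt[:, None]
    return out


def misclassification_distances(
    predictions: np.ndarray,
    truth: np.ndarray,
    centers: np.ndarray,
    known_lung_centers: np.ndarray,
    seed: int = 0,
    all_centers: np.ndarray | None = None,
) -> dict:
    """Distances from misclassified windows to the nearest known lung.

    Euclidean centre-to-centre distances are computed for every
    misclassified window, together with a matched null drawn uniformly
    (seeded, same count) from all window centres. Gaussian-kernel
    smoothed densities accompany both sets when they contain at least two
    points. Misclassifications concentrated at the lung boundary show a
    median distance well below the null's.
    """
    if known_lung_centers.size == 0:
        raise ValueError("need at least one known lung window")
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    centers = np.asarray(centers, dtype=float)
    tree = cKDTree(known_lung_centers)
    wrong = predictions != truth
    distances = tree.query(centers[wrong])[0] if wrong.any() else np.empty(0)

    pool = centers if all_centers is None else np.asarray(all_centers, dtype=float)
    rng = np.random.default_rng(seed)
    n = distances.size
    null = (
        tree.query(pool[rng.choice(pool.shape[0], size=n, replace=True)])[0]
        if n
        else np.empty(0)
    )

    def _kde(d):
        return gaussian_kde(d) if d.size > 1 and d.std() > 0 else None

    return {
        "distances": distances,
        "null_distances": null,
        "density": _kde(distances),
        "null_density": _kde(null),
        "degenerate": bool(n == 0),
    }
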