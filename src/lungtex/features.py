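"""Windowed texture descriptors: feature modes and per-window statistics.

Four whole-image *feature modes* are derived from a standardized
projection image — identity (range-normalized grayscale), skeleton (local
Otsu binarization thinned to single-pixel width), gradient (magnitude of
the spatial gradient) and Laplacian (5-point Laplacian after a sigma = 1
Gaussian blur). Each mode raster is then summarized over a lattice of
32 x 32-pixel windows in strides of 16 pixels by a location/dispersion
pair (median/IQR or mean/SD, per mode), giving eight window statistics.
Three further predictors per window — a bandpass log-power sum of the
identity-mode Fourier spectrum, and the mode and "horizontality" of a
directional-filter orientation distribution of the Laplacian mode —
complete the 11 predictors used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import skeletonize, footprint_rectangle

from .core import GrayImage

#: Predictor columns of a feature table, in fixed output order.
PREDICTORS = [
    "identity_loc",
    "identity_disp",
    "skeleton_loc",
    "skeleton_disp",
    "gradient_loc",
    "gradient_disp",
    "laplacian_loc",
    "laplacian_disp",
    "power_sum",
    "orientation",
    "horizontality",
]

#: Location/dispersion pair used per mode. The identity and Laplacian modes
#: use median/IQR (robust against rib outliers; the Laplacian window median
#: is the texture-amplitude statistic tracked against pressure), while the
#: skeleton mean measures sparsity of local structure and the gradient mean
#: is an extensive heterogeneity measure, both paired with the SD.
STAT_PAIRS = {
    "identity": "median_iqr",
    "skeleton": "mean_sd",
    "gradient": "mean_sd",
    "laplacian": "median_iqr",
}


@dataclass(frozen=True)
class WindowGrid:
    """The lattice of square analysis windows over one image.

    Windows are half-open ``[r, r+side) x [c, c+side)`` patches with
    0-based top-left origins on a stride lattice; only windows fully
    inside the image are kept. A 1984 x 1984 image with the default
    32-px windows at stride 16 carries 123 x 123 = 15129 windows.
    """

    height: int
    width: int
    side: int = 32
    stride: int = 16

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.side > min(self.height, self.width):
            raise ValueError(
                f"window side {self.side} exceeds image {self.height}x{self.width}"
            )

    @property
    def n_rows(self) -> int:
        return (self.height - self.side) // self.stride + 1

    @property
    def n_cols(self) -> int:
        return (self.width - self.side) // self.stride + 1

    @property
    def n_windows(self) -> int:
        return self.n_rows * self.n_cols

    def origins(self) -> np.ndarray:
        """(n_windows, 2) array of (row, col) top-left corners, row-major."""
        r = np.arange(self.n_rows) * self.stride
        c = np.arange(self.n_cols) * self.stride
        rr, cc = np.meshgrid(r, c, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)

    def centers(self) -> np.ndarray:
        """(n_windows, 2) array of window centre coordinates."""
        return self.origins() + self.side / 2.0

    def windows(self, raster: np.ndarray) -> np.ndarray:
        """View of shape (n_rows, n_cols, side, side) over ``raster``."""
        if raster.shape[:2] != (self.height, self.width):
            raise ValueError("raster shape does not match grid")
        view = sliding_window_view(raster, (self.side, self.side))
        return view[:: self.stride, :: self.stride]


def make_window_grid(
    height: int, width: int, side: int = 32, stride: int = 16
) -> WindowGrid:
    """Build the window lattice for an image of the given shape."""
    return WindowGrid(height=height, width=width, side=side, stride=stride)


# ---------------------------------------------------------------------------
# feature modes


def identity_mode(img: GrayImage, global_range: tuple[float, float]) -> np.ndarray:
    """Affinely rescale intensities from the cohort-common range to [0, 1]."""
    lo, hi = global_range
    if not hi > lo:
        raise ValueError("degenerate global range")
    return (img.astype_float() - lo) / (hi - lo)


def skeleton_mode(identity: np.ndarray, otsu_side: int = 32) -> np.ndarray:
    """Local-Otsu binarization thinned to single-pixel-width structures.

    The identity-mode raster (values in [0, 1]) is quantized to 8 bits,
    thresholded by the Otsu criterion computed in a sliding square window
    of width ``otsu_side``, and the binary result thinned so every
    foreground structure is one pixel wide. A locally flat image yields an
    empty skeleton (flat windows are suppressed rather than binarized on
    quantization noise).
    """
    u8 = np.clip(np.rint(np.asarray(identity) * 255), 0, 255).astype(np.uint8)
    foot = footprint_rectangle((otsu_side, otsu_side))
    thresh = rank.otsu(u8, foot)
    binary = u8 > thresh
    # suppress locally flat regions, where the Otsu split is meaningless
    local_range = rank.maximum(u8, foot).astype(np.int16) - rank.minimum(u8, foot)
    binary &= local_range > 1
    return skeletonize(binary).astype(float)


def gradient_mode(identity: np.ndarray) -> np.ndarray:
    """Magnitude of the spatial gradient of the whole identity raster.

    Central differences with edge-replicated borders; the result is the
    per-pixel Euclidean norm of the row and column derivatives.
    """
    padded = np.pad(np.asarray(identity, dtype=float), 1, mode="edge")
    gr = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gc = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gr, gc)


def laplacian_mode(identity: np.ndarray, blur_sigma: float = 1.0) -> np.ndarray:
    """5-point Laplacian of the Gaussian-blurred identity raster.

    A single-pixel-radius blur (sigma = 1 by default) regularizes the
    second difference so even weak edges are highlighted without
    amplifying shot noise.
    """
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    blurred = ndimage.gaussian_filter(np.asarray(identity, dtype=float), blur_sigma)
    return ndimage.laplace(blurred)


# ---------------------------------------------------------------------------
# window statistics


def window_stats(
    mode_img: np.ndarray, grid: WindowGrid, stat_pair: str
) -> tuple[np.ndarray, np.ndarray]:
    """Location and dispersion of a mode raster in every grid window.

    ``stat_pair`` is ``"median_iqr"`` (linear-interpolation quantiles) or
    ``"mean_sd"`` (population standard deviation). Returns two flat arrays
    of length ``grid.n_windows`` in row-major window order.
    """
    wins = grid.windows(np.asarray(mode_img, dtype=float))
    if stat_pair == "median_iqr":
        q25, q50, q75 = np.percentile(wins, [25, 50, 75], axis=(2, 3))
        return q50.ravel(), (q75 - q25).ravel()
    if stat_pair == "mean_sd":
        return (
            wins.mean(axis=(2, 3)).ravel(),
            wins.std(axis=(2, 3), ddof=0).ravel(),
        )
    raise ValueError(f"unknown stat_pair {stat_pair!r}")


def _bandpass_weight(side: int, sigma_low: float, sigma_high: float) -> np.ndarray:
    """DC-centred difference-of-Gaussians annulus in frequency-bin units."""
    f = np.fft.fftshift(np.fft.fftfreq(side)) * side  # integer bin coordinates
    fy, fx = np.meshgrid(f, f, indexing="ij")
    r2 = fy**2 + fx**2
    w = np.exp(-r2 / (2 * sigma_high**2)) - np.exp(-r2 / (2 * sigma_low**2))
    w = np.clip(w, 0.0, None)
    w[side // 2, side // 2] = 0.0  # DC bin forced to zero
    return w


def power_sum(
    identity_window: np.ndarray, sigma_low: float = 2.0, sigma_high: float = 8.0
) -> float:
    """Bandpass log-power of one identity-mode window.

    The window's DC-centred Fourier power spectrum is weighted by a
    Gaussian bandpass annulus (difference of Gaussians with widths
    ``sigma_low`` and ``sigma_high`` in frequency-bin units, clamped at
    zero, DC removed) and the sum of ``log(1 + weighted power)`` over all
    bins returned, a stabilized measure of total in-band signal power.
    """
    win = np.asarray(identity_window, dtype=float)
    if win.ndim != 2 or win.shape[0] != win.shape[1]:
        raise ValueError("identity_window must be square")
    w = _bandpass_weight(win.shape[0], sigma_low, sigma_high)
    power = np.abs(np.fft.fftshift(np.fft.fft2(win))) ** 2
    return float(np.sum(np.log1p(w * power)))


def _power_sums_grid(
    identity: np.ndarray, grid: WindowGrid, sigma_low: float, sigma_high: float
) -> np.ndarray:
    """Vectorized :func:`power_sum` over every window of the grid."""
    wins = grid.windows(np.asarray(identity, dtype=float))
    w = _bandpass_weight(grid.side, sigma_low, sigma_high)
    power = np.abs(np.fft.fftshift(np.fft.fft2(wins, axes=(2, 3)), axes=(2, 3))) ** 2
    return np.log1p(w * power).sum(axis=(2, 3)).ravel()


# ---------------------------------------------------------------------------
# orientation


@dataclass
class OrientationPDF:
    """Discrete distribution of texture angle, mod 180 degrees.

    ``angles`` are uniform bin centres mapped into (-90, +90] and
    ``probs`` the associated probabilities (non-negative, summing to 1).
    """

    angles: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.angles.shape != self.probs.shape:
            raise ValueError("angles and probs must align")
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probs must be a probability vector")


def _bin_centers(n_angles: int) -> np.ndarray:
    """Uniform angle bin centres over [0, 180) mapped into (-90, +90]."""
    theta = np.arange(n_angles) * (180.0 / n_angles)
    return np.where(theta > 90.0, theta - 180.0, theta)


@lru_cache(maxsize=32)
def _kernel_bank(n_angles: int, kernel_len: int, profile_sigma: float) -> tuple:
    """Zero-mean oriented line-detection kernels, one per angle bin.

    Each kernel is a matched line detector: flat over ``kernel_len``
    pixels along the line direction and a Gaussian of width
    ``profile_sigma`` across it, rotated to the bin angle and centred to
    zero mean so flat patches give zero response.
    """
    half = kernel_len // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    y = -y  # angles measured with y up, image rows down
    bank = []
    for theta in np.arange(n_angles) * (np.pi / n_angles):
        u = x * np.cos(theta) + y * np.sin(theta)  # along the line
        v = -x * np.sin(theta) + y * np.cos(theta)  # across the line
        k = np.exp(-(v**2) / (2 * profile_sigma**2)) * (np.abs(u) <= kernel_len / 2)
        k -= k.mean()
        bank.append(k)
    return tuple(bank)


#: Below this total response energy a window counts as unoriented: the
#: kernels are zero-mean only to float rounding, so a constant patch leaves
#: a ~1e-28 residual that must not be normalized into a spurious PDF.
_ENERGY_EPS = 1e-18


def _orientation_energies(
    laplacian: np.ndarray,
    n_angles: int,
    kernel_len: int,
    profile_sigma: float,
) -> np.ndarray:
    """Stack of squared directional-filter responses, one raster per angle."""
    lap = np.asarray(laplacian, dtype=float)
    bank = _kernel_bank(n_angles, kernel_len, profile_sigma)
    return np.stack(
        [ndimage.convolve(lap, k, mode="reflect") ** 2 for k in bank]
    )


def orientation_pdf(
    laplacian_window: np.ndarray,
    n_angles: int = 12,
    kernel_len: int = 9,
    profile_sigma: float = 1.5,
) -> OrientationPDF:
    """Texture-orientation distribution of one Laplacian-mode window.

    The window is convolved with a bank of oriented line detectors at
    ``n_angles`` uniform steps over [0, 180); the energy of each angle bin
    is the sum of squared responses over the window, and the energies are
    normalized to a probability vector. Angles 180 degrees apart are
    indistinct by construction. A constant window (zero total energy)
    yields the uniform distribution.
    """
    if n_angles < 4:
        raise ValueError("n_angles must be >= 4")
    energies = _orientation_energies(
        laplacian_window, n_angles, kernel_len, profile_sigma
    ).sum(axis=(1, 2))
    total = energies.sum()
    if total <= _ENERGY_EPS:
        probs = np.full(n_angles, 1.0 / n_angles)
    else:
        probs = energies / total
    return OrientationPDF(angles=_bin_centers(n_angles), probs=probs)


def _horizontal_fractions(n_angles: int) -> np.ndarray:
    """Fraction of each angle bin lying within (-45, +45] degrees, mod 180."""
    width = 180.0 / n_angles
    centers = _bin_centers(n_angles)
    fracs = np.empty(n_angles)
    for i, c in enumerate(centers):
        lo, hi = c - width / 2.0, c + width / 2.0
        # measure overlap of [lo, hi] with (-45, 45] on the mod-180 circle
        overlap = 0.0
        for shift in (-180.0, 0.0, 180.0):
            overlap += max(0.0, min(hi + shift, 45.0) - max(lo + shift, -45.0))
        fracs[i] = overlap / width
    return fracs


def horizontality(pdf: OrientationPDF) -> float:
    """Rescaled probability of a near-horizontal texture angle.

    ``h = 2 P(-45 < theta <= 45) - 1``: +1 for strongly horizontal
    texture, -1 for strongly vertical, 0 when no orientation dominates.
    A bin straddling +/-45 degrees contributes the fraction of its width
    inside the interval.
    """
    fracs = _horizontal_fractions(pdf.angles.size)
    return float(2.0 * np.dot(pdf.probs, fracs) - 1.0)


def orientation(pdf: OrientationPDF) -> float:
    """Mode of the orientation distribution, in degrees.

    Ties are broken toward the smallest angle.
    """
    best = np.flatnonzero(pdf.probs == pdf.probs.max())
    return float(pdf.angles[best].min())


# ---------------------------------------------------------------------------
# assembly


def build_feature_table(
    img: GrayImage,
    global_range: tuple[float, float],
    grid: WindowGrid | None = None,
    *,
    mouse_id: str = "",
    pressure: int | None = None,
    sigma_low: float = 2.0,
    sigma_high: float = 8.0,
    n_angles: int = 12,
    kernel_len: int = 9,
    profile_sigma: float = 1.5,
    blur_sigma: float = 1.0,
    otsu_side: int = 32,
) -> pd.DataFrame:
    """Compute the 11 predictors for every window of one image.

    Feature modes are computed once over the whole raster and then
    windowed (including the directional-filter responses, whose squared
    energies are summed per window), so window statistics near window
    borders see true neighboring image content. Returns a DataFrame with
    the :data:`PREDICTORS` columns plus ``mouse_id``, ``pressure``,
    ``center_row`` and ``center_col``, one row per grid window in
    row-major order.
    """
    h, w = img.shape
    if grid is None:
        grid = make_window_grid(h, w)
    ident = identity_mode(img, global_range)
    skel = skeleton_mode(ident, otsu_side=otsu_side)
    grad = gradient_mode(ident)
    lap = laplacian_mode(ident, blur_sigma=blur_sigma)

    cols: dict[str, np.ndarray] = {}
    for name, mode_img in (
        ("identity", ident),
        ("skeleton", skel),
        ("gradient", grad),
        ("laplacian", lap),
    ):
        loc, disp = window_stats(mode_img, grid, STAT_PAIRS[name])
        cols[f"{name}_loc"] = loc
        cols[f"{name}_disp"] = disp

    cols["power_sum"] = _power_sums_grid(ident, grid, sigma_low, sigma_high)

    energies = _orientation_energies(lap, n_angles, kernel_len, profile_sigma)
    per_window = np.stack(
        [grid.windows(e).sum(axis=(2, 3)).ravel() for e in energies], axis=1
    )
    totals = per_window.sum(axis=1, keepdims=True)
    uniform = np.full(n_angles, 1.0 / n_angles)
    live = totals > _ENERGY_EPS
    probs = np.where(live, per_window / np.where(live, totals, 1.0), uniform)
    centers = _bin_centers(n_angles)
    # mode of the distribution, ties toward the smallest angle
    order = np.argsort(centers, kind="stable")
    best = order[np.argmax(probs[:, order] >= probs.max(axis=1, keepdims=True), axis=1)]
    cols["orientation"] = centers[best]
    cols["horizontality"] = 2.0 * probs @ _horizontal_fractions(n_angles) - 1.0

    table = pd.DataFrame({k: cols[k] for k in PREDICTORS})
    ctr = grid.centers()
    table["center_row"] = ctr[:, 0]
    table["center_col"] = ctr[:, 1]
    table["mouse_id"] = mouse_id
    table["pressure"] = pressure if pressure is not None else -1
    return table
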