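"""Synthetic textured-phantom generator for edge-enhanced lung projections.

The phantom is a *statistical* stand-in for an in-vivo mouse imaged with a
propagation-based edge-enhancing system; no optics are simulated. It
reproduces the features the downstream texture analysis relies on:

* a lung region of band-limited, positively skewed speckle whose amplitude
  (and, mildly, band centre) increases with the discrete ventilation
  pressure state;
* dark low-frequency rib bands applied *multiplicatively* across the
  thorax, so lung texture passes through the ribs uninterrupted;
* a dark, Gaussian-blurred heart disc overlapping the medial left lung;
* a smooth exterior with additive sensor noise only;
* a cranial-caudal anisotropy gradient within the right lung: isotropic
  speckle at the apex grading into vertically oriented speckle at the base.

Ground-truth ROI masks (rib cage, lungs, heart, diaphragm, plus a
mediastinal spine band) are emitted alongside every image, and the whole
construction is bit-reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import GrayImage, RoiSet

#: Ventilation pressures (cmH2O) used as discrete expansion states.
PRESSURES = (6, 8, 10, 12)

#: Default map pressure -> speckle amplitude gain. Strictly increasing, with
#: a ~3x swing between the extreme pressures so the windowed texture
#: statistic changes by well over 2x while mean intensity barely moves.
DEFAULT_TEXTURE_GAIN: Mapping[int, float] = {6: 1.0, 8: 1.45, 10: 2.1, 12: 3.0}

#: Default map pressure -> speckle band centre (cycles/pixel).
DEFAULT_BAND_CENTER: Mapping[int, float] = {6: 0.100, 8: 0.108, 10: 0.116, 12: 0.124}


class InvalidSpecError(ValueError):
    """Raised when phantom geometry or parameters are inconsistent."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic mouse image.

    Geometry defaults scale with ``image_side`` (fractions chosen for a
    512-px frame; a 1984-px frame simply scales up). All randomness is
    driven by ``seed``: identical specs give bit-identical output.

    Parameters
    ----------
    mouse_id
        Subject identifier carried into the feature table.
    pressure
        Ventilation pressure in cmH2O; one of {6, 8, 10, 12}.
    image_side
        Side of the square frame in pixels (default 512; 1984 supported).
    texture_gain
        Map pressure -> speckle amplitude gain; must be strictly
        increasing over the four pressures.
    band_center
        Map pressure -> speckle band centre in cycles/pixel.
    anisotropy_max
        Orientation concentration at the lung base; the built-in profile
        ramps linearly from 0 (isotropic apex) to this value (vertical
        base) along the normalized cranial-caudal position.
    anisotropy_profile
        Optional override: callable mapping normalized cranial-caudal
        position t in [0, 1] to a concentration in [0, anisotropy_max].
    rib_count, rib_width_px
        Number and Gaussian half-width of the dark rib bands.
    heart_center, heart_radius
        Heart disc geometry in pixels (row, col). Defaults overlap the
        medial left lung.
    diaphragm_height
        Row of the diaphragm dome apex in pixels.
    noise_sd
        Additive Gaussian sensor noise, 16-bit intensity units.
    amp0
        Speckle amplitude at gain 1, intensity units.
    texture_scale, brightness_offset
        Per-mouse nuisance factors (set by :func:`generate_cohort`).
    lung_scale
        Per-mouse lung-size jitter factor.
    """

    mouse_id: str
    pressure: int
    image_side: int = 512
    texture_gain: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_GAIN)
    )
    band_center: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_CENTER)
    )
    anisotropy_max: float = 6.0
    anisotropy_profile: Callable[[float], float] | None = None
    rib_count: int = 7
    rib_width_px: float | None = None
    heart_center: tuple[float, float] | None = None
    heart_radius: float | None = None
    diaphragm_height: float | None = None
    noise_sd: float = 200.0
    amp0: float = 1200.0
    texture_scale: float = 1.0
    brightness_offset: float = 0.0
    lung_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.image_side
        if s < 64:
            raise InvalidSpecError("image_side must be at least 64 px")
        if self.pressure not in PRESSURES:
            raise InvalidSpecError(f"pressure {self.pressure} not in {PRESSURES}")
        gains = [self.texture_gain[p] for p in PRESSURES if p in self.texture_gain]
        if any(b <= a for a, b in zip(gains, gains[1:])):
            raise InvalidSpecError("texture_gain must be strictly increasing")
        if self.pressure not in self.texture_gain:
            raise InvalidSpecError(f"texture_gain lacks pressure {self.pressure}")
        if self.rib_width_px is None:
            self.rib_width_px = 0.012 * s
        if self.heart_center is None:
            self.heart_center = (0.58 * s, 0.60 * s)
        if self.heart_radius is None:
            self.heart_radius = 0.13 * s
        if self.diaphragm_height is None:
            self.diaphragm_height = 0.72 * s
        r, c = self.heart_center
        for v, name in (
            (r, "heart_center row"),
            (c, "heart_center col"),
            (self.diaphragm_height, "diaphragm_height"),
        ):
            if not (0 <= v < s):
                raise InvalidSpecError(f"{name}={v} outside image of side {s}")
        if self.heart_radius <= 0 or r + self.heart_radius > s or c + self.heart_radius > s:
            raise InvalidSpecError("heart disc extends outside the image")
        if self.rib_count < 0 or self.rib_width_px <= 0:
            raise InvalidSpecError("invalid rib geometry")

    def concentration(self, t: float) -> float:
        """Orientation concentration at normalized cranial-caudal position t."""
        if self.anisotropy_profile is not None:
            return float(self.anisotropy_profile(t))
        return self.anisotropy_max * float(np.clip(t, 0.0, 1.0))

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d.pop("anisotropy_profile", None)
        d["texture_gain"] = {str(k): v for k, v in self.texture_gain.items()}
        d["band_center"] = {str(k): v for k, v in self.band_center.items()}
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["texture_gain"] = {int(k): v for k, v in d["texture_gain"].items()}
        d["band_center"] = {int(k): v for k, v in d["band_center"].items()}
        d["heart_center"] = tuple(d["heart_center"])
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _lung_geometry(spec: PhantomSpec) -> dict[str, tuple]:
    """Centres and semi-axes (pixels) of the anatomical ellipses."""
    s = spec.image_side
    inflate = spec.lung_scale * (1.0 + 0.005 * (spec.pressure - 6))
    return {
        "rib_cage": ((0.50 * s, 0.50 * s), (0.40 * s, 0.34 * s)),
        "right_lung": ((0.44 * s, 0.34 * s), (0.26 * s * inflate, 0.15 * s * inflate)),
        "left_lung": ((0.45 * s, 0.66 * s), (0.24 * s * inflate, 0.14 * s * inflate)),
    }


def make_masks(spec: PhantomSpec) -> RoiSet:
    """Ground-truth ROI masks for a phantom spec (deterministic)."""
    s = spec.image_side
    shape = (s, s)
    geo = _lung_geometry(spec)
    rib_cage = _ellipse(shape, *geo["rib_cage"])
    right_lung = _ellipse(shape, *geo["right_lung"]) & rib_cage
    left_lung = _ellipse(shape, *geo["left_lung"]) & rib_cage

    rr, cc = np.ogrid[:s, :s]
    hr, hc = spec.heart_center
    heart = (rr - hr) ** 2 + (cc - hc) ** 2 <= spec.heart_radius**2

    dome = spec.diaphragm_height + 0.06 * s * ((cc - 0.5 * s) / (0.4 * s)) ** 2
    diaphragm = (rr > dome) & rib_cage

    spine = (np.abs(cc - 0.5 * s) < 0.02 * s) & rib_cage & ~right_lung & ~left_lung

    return RoiSet(
        masks={
            "rib_cage": rib_cage,
            "right_lung": right_lung,
            "left_lung": left_lung,
            "heart": heart & rib_cage,
            "diaphragm": diaphragm,
            "spine": spine,
        }
    )


# ---------------------------------------------------------------------------
# texture synthesis


def _bandpass_noise(rng: np.random.Generator, side: int, center: float,
                    bandwidth: float, kappa: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, optionally anisotropic.

    ``kappa`` concentrates spectral energy around the horizontal frequency
    axis (a von Mises-style weight on the doubled angle), which produces
    *vertically* oriented stripes in the spatial domain; ``kappa = 0`` is
    isotropic.
    """
    w = rng.standard_normal((side, side))
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    rho = np.hypot(fy, fx)
    weight = np.exp(-((rho - center) ** 2) / (2 * bandwidth**2))
    if kappa > 0:
        phi = np.arctan2(fy, fx)
        weight = weight * np.exp(kappa * (np.cos(2 * phi) - 1.0))
    weight[0, 0] = 0.0
    f = np.fft.ifft2(np.fft.fft2(w) * weight).real
    sd = f.std()
    return f / sd if sd > 0 else f


def _speckle_field(spec: PhantomSpec, rng: np.random.Generator,
                   right_lung: np.ndarray) -> np.ndarray:
    """Positively skewed speckle with a cranial-caudal orientation gradient.

    The field is a squared band-limited Gaussian process (centred to
    near-zero mean), which gives it bright granular peaks and a
    *consistently signed* local curvature statistic, so the windowed
    Laplacian median scales linearly with the amplitude gain. Within the
    right lung an isotropic and a vertically oriented field are blended
    with a weight that ramps from 0 at the apex to 1 at the base.
    """
    s = spec.image_side
    center = spec.band_center[spec.pressure]
    bw = 0.03
    f_iso = _bandpass_noise(rng, s, center, bw, kappa=0.0)
    f_vert = _bandpass_noise(rng, s, center, bw, kappa=8.0)

    rows = np.where(right_lung.any(axis=1))[0]
    alpha = np.zeros(s)
    if rows.size:
        top, bot = rows[0], rows[-1]
        t = np.clip((np.arange(s) - top) / max(bot - top, 1), 0.0, 1.0)
        kmax = max(spec.anisotropy_max, 1e-9)
        alpha = np.clip(
            np.array([spec.concentration(ti) for ti in t]) / kmax, 0.0, 1.0
        )
    a = alpha[:, None] * right_lung  # vertical blend only inside the right lung
    f = np.sqrt(1.0 - a**2) * f_iso + a * f_vert
    return f**2 - 1.0  # E[f^2] = 1 -> near-zero mean, positive skew


def generate_mouse(spec: PhantomSpec) -> tuple[GrayImage, RoiSet]:
    """Render one phantom projection image and its ground-truth masks.

    The image is composed as::

        (base + plateau + speckle * lung) * ribs * heart * diaphragm + noise

    with a smooth low-frequency background field, a faint lung plateau,
    pressure-scaled speckle confined (with feathered edges) to the lungs,
    multiplicative dark rib bands and organ shadows, and additive sensor
    noise, quantized to an unsigned 16-bit raster.
    """
    s = spec.image_side
    rois = make_masks(spec)
    rng = np.random.default_rng(spec.seed)

    # smooth exterior/background field
    base = 28000.0 + spec.brightness_offset
    smooth = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=s / 8.0)
    sd = smooth.std()
    img = np.full((s, s), base) + (1200.0 / sd if sd > 0 else 0.0) * smooth

    # low-frequency body clutter (shoulders, abdomen, bedding) across the
    # whole frame: keeps the exterior from being trivially smooth, so
    # lung/not-lung discrimination must lean on the speckle texture
    clutter = _bandpass_noise(rng, s, center=0.02, bandwidth=0.01, kappa=0.0)
    img += 800.0 * clutter

    # faint lung plateau (weak intensity cue; texture is the real signal)
    lung = rois.lung()
    lung_soft = ndimage.gaussian_filter(lung.astype(float), sigma=0.004 * s + 1.0)
    img += 1000.0 * lung_soft

    # pressure-scaled skewed speckle, feathered to the lung support
    gain = spec.texture_gain[spec.pressure] * spec.texture_scale
    speckle = _speckle_field(spec, rng, rois["right_lung"])
    img += spec.amp0 * gain * speckle * lung_soft

    # multiplicative rib bands crossing the thorax (texture passes through)
    rr = np.arange(s)[:, None].astype(float)
    cc = np.arange(s)[None, :].astype(float)
    rib = np.zeros((s, s))
    if spec.rib_count > 0:
        spacing = 0.70 * s / spec.rib_count
        for k in range(spec.rib_count):
            yk = 0.15 * s + k * spacing + 0.04 * s * ((cc - 0.5 * s) / (0.4 * s)) ** 2
            rib += np.exp(-((rr - yk) ** 2) / (2 * spec.rib_width_px**2))
    cage_soft = ndimage.gaussian_filter(
        rois["rib_cage"].astype(float), sigma=0.004 * s + 1.0
    )
    img *= 1.0 - 0.15 * np.clip(rib, 0, 1) * cage_soft

    # dark blurred heart disc and diaphragm dome
    hr, hc = spec.heart_center
    heart_disc = ((rr - hr) ** 2 + (cc - hc) ** 2 <= spec.heart_radius**2).astype(float)
    heart_soft = ndimage.gaussian_filter(heart_disc, sigma=0.012 * s + 1.0)
    img *= 1.0 - 0.30 * heart_soft
    dia_soft = ndimage.gaussian_filter(rois["diaphragm"].astype(float), sigma=0.008 * s + 1.0)
    img *= 1.0 - 0.22 * dia_soft

    # additive sensor noise everywhere
    img += spec.noise_sd * rng.standard_normal((s, s))

    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return GrayImage(pixels=pixels, bit_depth=16), rois


def generate_cohort(
    n_mice: int,
    pressures: Sequence[int] = PRESSURES,
    master_seed: int = 0,
    image_side: int = 512,
    n_replicates: int = 1,
    **spec_overrides,
) -> list[tuple[PhantomSpec, GrayImage, RoiSet]]:
    """Generate a seeded cohort of phantom mice.

    One image is rendered per (mouse, pressure, replicate). Per-mouse
    nuisance variation — a global brightness offset, a lung-size jitter
    and a texture-amplitude jitter — is drawn from sub-seeds derived
    deterministically from ``master_seed``, so per-mouse standardization
    downstream is non-trivial and the cohort is exactly reproducible.

    Parameters
    ----------
    n_mice
        Number of virtual mice; at least 2 (leave-one-mouse-out
        cross-validation is undefined for fewer).
    pressures
        Non-empty subset of {6, 8, 10, 12}.
    master_seed
        Seeds the whole cohort.
    image_side
        Frame side in pixels (default 512 for desk-scale runtime).
    n_replicates
        Images per (mouse, pressure) cell.
    spec_overrides
        Extra keyword arguments forwarded to every :class:`PhantomSpec`
        (e.g. a custom ``texture_gain`` map).
    """
    if n_mice < 2:
        raise ValueError("n_mice must be >= 2 (leave-one-mouse-out undefined)")
    pressures = list(pressures)
    if not pressures or any(p not in PRESSURES for p in pressures):
        raise ValueError(f"pressures must be a non-empty subset of {PRESSURES}")

    ss = np.random.SeedSequence(master_seed)
    mouse_seeds = ss.spawn(n_mice)
    out: list[tuple[PhantomSpec, GrayImage, RoiSet]] = []
    for i, mss in enumerate(mouse_seeds):
        mrng = np.random.default_rng(mss)
        brightness = float(mrng.normal(0.0, 800.0))
        lung_scale = float(np.clip(mrng.normal(1.0, 0.04), 0.88, 1.12))
        texture_scale = float(np.exp(mrng.normal(0.0, 0.15)))
        for p in pressures:
            for r in range(n_replicates):
                seed = int(mrng.integers(0, 2**31 - 1))
                spec = PhantomSpec(
                    mouse_id=f"m{i:02d}",
                    pressure=p,
                    image_side=image_side,
                    brightness_offset=brightness,
                    lung_scale=lung_scale,
                    texture_scale=texture_scale,
                    seed=seed,
                    **spec_overrides,
                )
                img, rois = generate_mouse(spec)
                out.append((spec, img, rois))
    return out
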