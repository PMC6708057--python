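"""Core raster and region-of-interest containers shared across the pipeline.

A projection image travels through the pipeline as a :class:`GrayImage`
(an integer raster with a declared bit depth), and its anatomical
annotation as a :class:`RoiSet` (named binary masks on the same grid).
Feature modes derived from the image are plain float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Masks every annotated image must carry.
BASE_ROIS = ("rib_cage", "right_lung", "left_lung", "heart", "diaphragm")

#: Masks added by ROI set arithmetic (see :func:`lungtex.preprocess.derive_rois`).
DERIVED_ROIS = ("lung_heart_overlap", "outside_ribcage")


@dataclass
class GrayImage:
    """A 2-D grayscale raster with a declared bit depth.

    Parameters
    ----------
    pixels
        2-D array of intensities. Stored as given; values must lie in
        ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    pixel_pitch_um
        Physical pixel pitch in micrometres. Metadata only; no operation
        depends on it.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_pitch_um: float = 30.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size:
            lo = float(self.pixels.min())
            hi = float(self.pixels.max())
            if lo < 0 or hi > self.max_value:
                raise ValueError(
                    f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class RoiSet:
    """Named binary masks over one image grid.

    Base masks name the manually segmented anatomy (rib cage, right lung,
    left lung, heart, diaphragm); derived masks are the products of set
    arithmetic. All masks share the image shape. The rib cage and lung
    boundaries are outer envelopes: the rib cage contains the lungs, and
    the lung masks include ribs seen in projection.

    An optional ``spine`` mask (a mediastinal band between the lungs) may
    be present; it supplies certainly-not-lung training exemplars inside
    the rib cage.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.ndim != 2:
                raise ValueError(f"mask {name!r} is not 2-D")
            if shape is None:
                shape = mask.shape
            elif mask.shape != shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} != {shape}"
                )
            clean[name] = mask
        self.masks = clean

    @property
    def shape(self) -> tuple[int, int]:
        if not self.masks:
            raise ValueError("empty RoiSet has no shape")
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def lung(self) -> np.ndarray:
        """Union of the two lung masks."""
        return self.masks["right_lung"] | self.masks["left_lung"]

    def validate(self) -> None:
        """Check the structural invariants of a complete ROI set.

        Raises ``ValueError`` if base masks are missing, if the lungs
        extend outside the rib cage envelope, or if derived masks are
        inconsistent with the bases they were computed from.
        """
        for name in BASE_ROIS:
            if name not in self.masks:
                raise ValueError(f"missing base mask {name!r}")
        if np.any(self.lung() & ~self.masks["rib_cage"]):
            raise ValueError("lung masks extend outside the rib cage envelope")
        if "outside_ribcage" in self.masks:
            if np.any(self.masks["outside_ribcage"] & self.masks["rib_cage"]):
                raise ValueError("outside_ribcage overlaps rib_cage")
        if "lung_heart_overlap" in self.masks:
            if np.any(self.masks["lung_heart_overlap"] & ~self.lung()):
                raise ValueError("lung_heart_overlap not contained in the lungs")
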