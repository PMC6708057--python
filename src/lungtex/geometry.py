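"""Acquisition-geometry arithmetic for propagation-based imaging."""

from __future__ import annotations


def magnification(sod_cm: float, odd_cm: float) -> float:
    """Geometric magnification of a point-projection imaging system.

    For a cone beam, an object at source-to-object distance ``SOD`` whose
    shadow is recorded at a detector a further object-to-detector distance
    ``ODD`` downstream is magnified by ``(SOD + ODD) / SOD``.

    Parameters
    ----------
    sod_cm
        Source-to-object distance (cm); must be positive.
    odd_cm
        Object-to-detector distance (cm); must be non-negative.
    """
    if sod_cm <= 0:
        raise ValueError("source-to-object distance must be positive")
    if odd_cm < 0:
        raise ValueError("object-to-detector distance must be non-negative")
    return (sod_cm + odd_cm) / sod_cm
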