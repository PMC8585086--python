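"""Pain Mapping Intensity (PMI): intensity-weighted painted surface.

Patients draw their pain on a body template; the drawing software reports
the painted area (cm^2) in four intensity classes.  The PMI weights each
class by a fixed coefficient:

    PMI = 1*SurfaceLow + 2*SurfaceMedium + 3*SurfaceIntense + 4*SurfaceVeryIntense

so a larger or more intense drawing always yields a larger score.  Change
between two visits is oriented so that a positive value means improvement
(the painted surface shrank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["INTENSITY_COEFFICIENTS", "PainSurfaces", "compute_pmi", "pmi_change"]

#: Fixed weights for the (low, medium, intense, very intense) classes.
INTENSITY_COEFFICIENTS: tuple[int, int, int, int] = (1, 2, 3, 4)


@dataclass(frozen=True)
class PainSurfaces:
    """Painted areas in cm^2 per pain-intensity class."""

    low: float
    medium: float
    intense: float
    very_intense: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"surface {name!r} must be a nonnegative finite area, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.low, self.medium, self.intense, self.very_intense], float)


def compute_pmi(surfaces: PainSurfaces | np.ndarray) -> float:
    """Weighted-surface score in cm^2-weighted units; 0 iff nothing painted."""
    a = surfaces.as_array() if isinstance(surfaces, PainSurfaces) else np.asarray(surfaces, float)
    if a.shape[-1] != 4:
        raise ValueError("expected four surface areas")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("surfaces must be nonnegative finite areas")
    return float(a @ np.array(INTENSITY_COEFFICIENTS, float)) if a.ndim == 1 else a @ np.array(INTENSITY_COEFFICIENTS, float)


def pmi_change(baseline: float, followup: float) -> float:
    """Improvement-oriented change: baseline - followup (decrease = better).

    With this orientation a positive responder cutoff (e.g. 468) is applied
    as ``change >= cutoff``; a patient whose painted surface grew can never
    exceed a positive cutoff.
    """
    if baseline < 0 or followup < 0:
        raise ValueError("PMI scores are nonnegative")
    return float(baseline - followup)
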