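"""Cumulative volume-vs-angle profiles of the scala tympani.

The central in-memory object of the package: cumulative perilymph volume
(μL) as a function of cochlear angle (degrees from the round-window center,
increasing apically).  Profiles are stored as knots on an angular grid and
interpolated with a monotone piecewise-cubic (PCHIP), which cannot introduce
overshoot-driven non-monotonicity between knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["VolumeProfile", "NormalizedProfile"]

#: absolute slack (μL or fraction) tolerated when checking monotonicity
_MONOTONE_TOL = 1e-9


def _as_knots(angles: Iterable[float], values: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(angles, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.ndim != 1 or v.ndim != 1 or a.shape != v.shape:
        raise ValueError("angles and values must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("a profile needs at least two knots")
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(v)):
        raise ValueError("profile knots must be finite")
    if np.any(np.diff(a) <= 0):
        raise ValueError("profile angles must be strictly increasing")
    if np.any(a < 0):
        raise ValueError("profile angles must be non-negative")
    if np.any(np.diff(v) < -_MONOTONE_TOL):
        raise ValueError("cumulative volume must be non-decreasing")
    return a, np.maximum.accumulate(v)


@dataclass(frozen=True)
class VolumeProfile:
    """Cumulative ST volume (μL) over cochlear angle (deg).

    Parameters
    ----------
    angles
        Strictly increasing knot angles in degrees (0° at the round window).
    volumes
        Cumulative volume at each knot in μL (1 mm³ ≡ 1 μL); non-decreasing,
        and zero at 0° when the grid starts there.
    provenance
        One of ``measured``, ``mean_model``, ``log_model``, ``scaling_model``,
        ``canonical`` (free-form strings are accepted for derived curves).
    """

    angles: np.ndarray
    volumes: np.ndarray
    provenance: str = "measured"
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a, v = _as_knots(self.angles, self.volumes)
        if a[0] == 0.0 and abs(v[0]) > 1e-9:
            raise ValueError(f"volume at 0° must be 0, got {v[0]!r}")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "_interp", PchipInterpolator(a, v))

    # -- evaluation ------------------------------------------------------
    def __call__(self, angle):
        """Interpolated cumulative volume (μL) at ``angle`` degrees."""
        angle = np.asarray(angle, dtype=float)
        if np.any(angle < self.angles[0] - 1e-9) or np.any(angle > self.angles[-1] + 1e-9):
            raise ValueError(
                f"angle outside profile range [{self.angles[0]}, {self.angles[-1]}]"
            )
        return self._interp(np.clip(angle, self.angles[0], self.angles[-1]))[()]

    evaluate = __call__

    @property
    def max_angle(self) -> float:
        return float(self.angles[-1])

    @property
    def total(self) -> float:
        """Cumulative volume at the most apical knot (μL)."""
        return float(self.volumes[-1])

    @property
    def v360(self) -> float:
        """Volume of the basal turn, i.e. cumulative volume at 360° (μL)."""
        return float(self(360.0))

    # -- transforms ------------------------------------------------------
    def resample(self, angles: Iterable[float]) -> "VolumeProfile":
        a = np.asarray(angles, dtype=float)
        return VolumeProfile(a, self(a), provenance=self.provenance)

    def normalized(self) -> "NormalizedProfile":
        """Divide by this profile's own value at 360°."""
        v360 = self.v360
        if v360 <= 0:
            raise ValueError("cannot normalize a profile with V(360°) ≤ 0")
        return NormalizedProfile(self.angles, self.volumes / v360)


@dataclass(frozen=True)
class NormalizedProfile:
    """Volume profile expressed as a fraction of the volume at 360°."""

    angles: np.ndarray
    fractions: np.ndarray
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a, f = _as_knots(self.angles, self.fractions)
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "_interp", PchipInterpolator(a, f))
        if not (a[0] <= 360.0 <= a[-1]):
            raise ValueError("normalized profile must cover 360°")
        if abs(self(360.0) - 1.0) > 1e-9:
            raise ValueError("normalized profile must equal 1 at 360°")

    def __call__(self, angle):
        angle = np.asarray(angle, dtype=float)
        return self._interp(np.clip(angle, self.angles[0], self.angles[-1]))[()]

    evaluate = __call__

    @property
    def max_angle(self) -> float:
        return float(self.angles[-1])

    def scale(self, v360: float, provenance: str = "scaling_model") -> VolumeProfile:
        """Rescale so the value at 360° equals ``v360`` μL."""
        if v360 <= 0:
            raise ValueError("target V(360°) must be positive")
        return VolumeProfile(self.angles, self.fractions * v360, provenance=provenance)
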