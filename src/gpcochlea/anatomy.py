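"""Footprint-based anatomy model: BTL, V(360°) and full volume profiles.

Implements the estimation chain used by the research tool: the
elliptic-circular approximation (ECA) maps the cochlear footprint (A, B)
to basal turn length (BTL); a linear regression maps BTL to the scala
tympani volume at 360°; and a packaged canonical mean profile extends the
single-angle estimate to a full volume-vs-angle curve by one of three
methods (``mean``, ``log``, ``scaling``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .geometry import CochlearFootprint
from .profile import NormalizedProfile, VolumeProfile

__all__ = [
    "ECACoefficients",
    "V360Regression",
    "LogFit",
    "eca_btl",
    "predict_v360",
    "canonical_mean_profile",
    "build_mean_profile",
    "fit_log_profile",
    "estimate_profile",
    "CANONICAL_KNOT_ANGLES",
    "CANONICAL_KNOT_VOLUMES",
]

ProfileMethod = Literal["mean", "log", "scaling"]


# ---------------------------------------------------------------------------
# canonical mean profile
# ---------------------------------------------------------------------------
# Knot table of the packaged cohort-average cumulative ST volume curve on the
# 22.5° station grid.  The table is SYNTHESIZED to satisfy the published
# anchors exactly — it is not digitized from a figure:
#   * V(0°) = 0, V(360°) = 4.4 μL, V(1080°) = 5.3 μL (basal turn holds 83%
#     of the three-turn total);
#   * rapid basal rise (≈65% of the basal-turn volume reached by 180°);
#   * a local slope plateau within 270–360° (the basal area plateau) followed
#     by a drop at the start of the second turn;
#   * shallow, slowly decaying accumulation over turns two and three.
# Users with their own cohort can replace it via `build_mean_profile`.
CANONICAL_KNOT_ANGLES = np.arange(0.0, 1080.1, 22.5)
CANONICAL_KNOT_VOLUMES = np.array([
    0.0, 0.475153, 0.910915, 1.310553, 1.677062, 2.013186, 2.321447,
    2.604152, 2.863421, 3.101197, 3.319261, 3.519248, 3.702656, 3.878243,
    4.053829, 4.229416, 4.4, 4.536543, 4.620345, 4.663591, 4.696797,
    4.72895, 4.760086, 4.790236, 4.819433, 4.847707, 4.875086, 4.901599,
    4.927274, 4.952136, 4.976212, 4.999526, 5.022103, 5.043965, 5.065137,
    5.085638, 5.105491, 5.124716, 5.143333, 5.161361, 5.178818, 5.195724,
    5.212095, 5.227948, 5.243299, 5.258165, 5.27256, 5.286501, 5.3,
])


def canonical_mean_profile() -> VolumeProfile:
    """The packaged default mean ST volume profile (0–1080°, μL)."""
    return VolumeProfile(
        CANONICAL_KNOT_ANGLES, CANONICAL_KNOT_VOLUMES, provenance="canonical"
    )


# ---------------------------------------------------------------------------
# ECA and V360 regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ECACoefficients:
    """Coefficients of the elliptic-circular approximation of BTL.

    ``cross_term_variant`` selects how the A·B interaction enters:

    * ``geometric_mean`` (default): BTL = cA·A + cB·B − cCross·√(A·B).
      For the observed guinea-pig footprint range this yields BTL of
      9.4–10.1 mm, consistent with reported group medians (9.09–9.68 mm)
      and positive volumes through the V360 regression.
    * ``printed_product``: BTL = cA·A + cB·B − cCross·A·B, the formula as
      printed; for the same inputs it gives ≈4.2 mm and negative volumes,
      so it is retained only for comparison, never silently altered.
    """

    cA: float = 1.18
    cB: float = 2.69
    cCross: float = 0.72
    cross_term_variant: Literal["geometric_mean", "printed_product"] = "geometric_mean"

    def __post_init__(self) -> None:
        for v in (self.cA, self.cB, self.cCross):
            if not np.isfinite(v):
                raise ValueError("ECA coefficients must be finite")
        if self.cross_term_variant not in ("geometric_mean", "printed_product"):
            raise ValueError(f"unknown cross_term_variant {self.cross_term_variant!r}")


DEFAULT_ECA = ECACoefficients()


def eca_btl(fp: CochlearFootprint | tuple[float, float],
            coeffs: ECACoefficients = DEFAULT_ECA) -> float:
    """Basal turn length (mm) from footprint (A, B) via the ECA formula."""
    if isinstance(fp, CochlearFootprint):
        a, b = fp.A, fp.B
    else:
        a, b = float(fp[0]), float(fp[1])
    if a <= 0 or b <= 0:
        raise ValueError("footprint A and B must be positive")
    if coeffs.cross_term_variant == "geometric_mean":
        cross = np.sqrt(a * b)
    else:
        cross = a * b
    return coeffs.cA * a + coeffs.cB * b - coeffs.cCross * cross


@dataclass(frozen=True)
class V360Regression:
    """Linear map BTL (mm) → ST volume at 360° (μL): V = slope·BTL + intercept."""

    slope: float = 1.38
    intercept: float = -8.36
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("V360 regression slope must be positive")

    @property
    def min_valid_btl(self) -> float:
        """BTL below which the predicted volume is non-positive."""
        return -self.intercept / self.slope


DEFAULT_V360 = V360Regression()


def predict_v360(btl: float, reg: V360Regression = DEFAULT_V360) -> float:
    """Predicted ST volume at 360° (μL) from basal turn length (mm)."""
    v = reg.slope * btl + reg.intercept
    if v < 0:
        raise ValueError(
            f"predicted V(360°) = {v:.3f} μL ≤ 0; BTL must exceed "
            f"{reg.min_valid_btl:.3f} mm"
        )
    return v


# ---------------------------------------------------------------------------
# cohort mean profile and logarithmic fit
# ---------------------------------------------------------------------------

def build_mean_profile(
    profiles: Sequence[VolumeProfile],
    grid: Optional[Iterable[float]] = None,
    normalization: Literal["per_specimen", "cohort_mean"] = "per_specimen",
) -> NormalizedProfile:
    """Cohort mean profile, normalized to the volume at 360°.

    With ``per_specimen`` (default) every profile is divided by its own
    V(360°) before averaging, so the result captures the common *shape*;
    ``cohort_mean`` divides each profile by the cohort-mean V(360°) instead.
    Profiles that do not cover 360° are skipped with a warning.
    """
    import warnings

    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a mean profile")
    usable = []
    for i, p in enumerate(profiles):
        if p.max_angle < 360.0:
            warnings.warn(f"profile {i} covers only {p.max_angle}°; skipped",
                          stacklevel=2)
        else:
            usable.append(p)
    if len(usable) < 2:
        raise ValueError("fewer than 2 profiles cover 360°")
    if grid is None:
        max_common = min(p.max_angle for p in usable)
        grid = np.arange(0.0, max_common + 1e-9, 22.5)
    grid = np.asarray(grid, dtype=float)
    if normalization == "per_specimen":
        stack = np.array([p(grid) / p.v360 for p in usable])
    elif normalization == "cohort_mean":
        mean_v360 = float(np.mean([p.v360 for p in usable]))
        stack = np.array([p(grid) / mean_v360 for p in usable])
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    mean = stack.mean(axis=0)
    if normalization == "cohort_mean":
        # guarantee the defining property f(360°) = 1 despite averaging
        mean = mean / np.interp(360.0, grid, mean)
    return NormalizedProfile(grid, mean)


@dataclass(frozen=True)
class LogFit:
    """Parameters of the logarithmic profile V(θ) = a·ln(1 + θ/b).

    The form passes through the origin by construction; ``b`` (deg) sets how
    fast the curve bends, ``a`` (μL) the overall scale.
    """

    a: float
    b: float
    rms_residual: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("log-fit parameters a and b must be positive")

    def __call__(self, angle):
        return self.a * np.log1p(np.asarray(angle, dtype=float) / self.b)

    def profile(self, grid: Iterable[float]) -> VolumeProfile:
        grid = np.asarray(grid, dtype=float)
        return VolumeProfile(grid, self(grid), provenance="log_model")


def fit_log_profile(profile: VolumeProfile) -> LogFit:
    """Least-squares logarithmic fit V(θ) = a·ln(1 + θ/b) to a profile."""
    theta = profile.angles
    v = profile.volumes

    def model(x, a, b):
        return a * np.log1p(x / b)

    try:
        popt, _ = curve_fit(
            model, theta, v, p0=[max(v[-1], 1e-3) / np.log1p(theta[-1] / 100.0), 100.0],
            bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer pathology
        raise ValueError(f"logarithmic fit did not converge: {exc}") from exc
    resid = model(theta, *popt) - v
    return LogFit(a=float(popt[0]), b=float(popt[1]),
                  rms_residual=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# individual profile estimation
# ---------------------------------------------------------------------------

def estimate_profile(
    fp: CochlearFootprint | tuple[float, float],
    method: ProfileMethod = "scaling",
    coeffs: ECACoefficients = DEFAULT_ECA,
    reg: V360Regression = DEFAULT_V360,
    normalized: Optional[NormalizedProfile] = None,
    logfit: Optional[LogFit] = None,
) -> VolumeProfile:
    """Estimate an individual's volume profile from its footprint.

    * ``mean`` — the canonical (or supplied) mean profile unchanged,
      ignoring the individual footprint;
    * ``log`` — the logarithmic curve rescaled so its value at 360° equals
      the individual V(360°) prediction;
    * ``scaling`` — the normalized mean profile multiplied by the individual
      V(360°) prediction (the recommended method).
    """
    if normalized is None:
        normalized = canonical_mean_profile().normalized()
    if method == "mean":
        base = normalized.scale(canonical_mean_profile().v360, provenance="mean_model")
        return base
    v360 = predict_v360(eca_btl(fp, coeffs), reg)
    if method == "scaling":
        return normalized.scale(v360, provenance="scaling_model")
    if method == "log":
        if logfit is None:
            logfit = fit_log_profile(canonical_mean_profile())
        grid = normalized.angles
        shape = np.log1p(grid / logfit.b) / np.log1p(360.0 / logfit.b)
        return VolumeProfile(grid, v360 * shape, provenance="log_model")
    raise ValueError(f"unknown profile method {method!r}")
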