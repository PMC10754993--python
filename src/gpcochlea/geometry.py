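"""Geometry pipeline: segmentation contours → areas, volumes, footprint.

Operates on contour points exported from midmodiolar slicing of μCT
segmentations.  Each angular station (22.5° steps by default) holds an
ordered closed contour of the scala tympani drawn in the half-plane that
contains the modiolar axis at that azimuth.  From those contours the module
derives cross-sectional areas and centroids, the cumulative volume profile
(frustum rule along the centroid path), the lateral-wall curve, and the
cochlear footprint parameters A (basal diameter) and B (basal width).

Units: mm for lengths, mm² for areas, μL (= mm³) for volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import LinearRing

from .profile import VolumeProfile

__all__ = [
    "PlausibilityWarning",
    "ModiolarAxis",
    "ContourStation",
    "STSegmentation",
    "CrossSection",
    "LateralWallProfile",
    "CochlearFootprint",
    "cross_section_area",
    "section_centroid",
    "cross_sections",
    "volume_increments",
    "volume_profile",
    "lateral_wall",
    "extract_footprint",
]

#: coplanarity tolerance for station contours (mm)
COPLANARITY_TOL = 1e-6

#: default footprint plausibility bounds for adult guinea pigs (mm)
A_PLAUSIBLE = (3.0, 5.0)
B_PLAUSIBLE = (2.0, 3.5)


class PlausibilityWarning(UserWarning):
    """A derived quantity lies outside the expected anatomical range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModiolarAxis:
    """Rotation axis through the center of the modiolus.

    ``rw_reference`` marks the round-window center and fixes the 0° azimuth;
    angles increase apically around ``direction`` (right-handed).
    """

    origin: np.ndarray
    direction: np.ndarray
    rw_reference: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        r = np.asarray(self.rw_reference, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector (|‖d‖−1| ≤ 1e-9)")
        radial = (r - o) - np.dot(r - o, d) * d
        if np.linalg.norm(radial) < 1e-9:
            raise ValueError("rw_reference must not lie on the axis line")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "rw_reference", r)

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal frame (e1, e2, e3): e1 points at the RW (0°), e3 = axis."""
        e3 = self.direction
        e1 = (self.rw_reference - self.origin)
        e1 = e1 - np.dot(e1, e3) * e3
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(e3, e1)
        return e1, e2, e3

    def radial_direction(self, angle_deg: float) -> np.ndarray:
        """In-plane unit vector at azimuth ``angle_deg`` from the RW."""
        e1, e2, _ = self.frame()
        t = np.deg2rad(angle_deg)
        return np.cos(t) * e1 + np.sin(t) * e2

    def axial_distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of ``points`` (n,3) to the axis line."""
        rel = np.atleast_2d(points) - self.origin
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        return np.linalg.norm(perp, axis=1)


@dataclass(frozen=True)
class ContourStation:
    """One angular station: a closed ST contour at azimuth ``angle`` degrees."""

    angle: float
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.angle < 0:
            raise ValueError("station angle must be non-negative")
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
            raise ValueError("a station needs at least 3 three-dimensional points")
        object.__setattr__(self, "points", p)


@dataclass(frozen=True)
class STSegmentation:
    """Full segmentation of one scala tympani: axis + ordered stations."""

    specimen_id: str
    axis: ModiolarAxis
    stations: tuple[ContourStation, ...]
    group: Optional[str] = None

    def __post_init__(self) -> None:
        st = tuple(self.stations)
        if len(st) < 2:
            raise ValueError("a segmentation needs at least 2 stations")
        angles = np.array([s.angle for s in st])
        if np.any(np.diff(angles) <= 0):
            raise ValueError("station angles must be strictly increasing")
        object.__setattr__(self, "stations", st)
        self._check_coplanarity()

    def _check_coplanarity(self) -> None:
        e3 = self.axis.direction
        for s in self.stations:
            n = np.cross(e3, self.axis.radial_direction(s.angle))
            off = np.abs((s.points - self.axis.origin) @ n)
            if np.max(off) > COPLANARITY_TOL:
                raise ValueError(
                    f"station {s.angle}° of {self.specimen_id!r}: points deviate "
                    f"{np.max(off):.2e} mm from the slicing half-plane "
                    f"(tolerance {COPLANARITY_TOL} mm)"
                )

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle for s in self.stations])

    @property
    def max_angle(self) -> float:
        return float(self.stations[-1].angle)


@dataclass(frozen=True)
class CrossSection:
    angle: float
    area: float
    centroid: np.ndarray
    max_wall_point: np.ndarray

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("cross-sectional area must be positive")


@dataclass(frozen=True)
class LateralWallProfile:
    """Per station, the contour point farthest from the modiolar axis."""

    angles: np.ndarray
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        p = np.asarray(self.points, dtype=float)
        if p.shape != (a.size, 3):
            raise ValueError("points must be (n, 3) matching angles")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "points", p)


@dataclass(frozen=True)
class CochlearFootprint:
    """Basal diameter A and basal width B of the cochlear footprint (mm)."""

    A: float
    B: float
    eps_used: Optional[float] = None
    a_chord_angles: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0):
            raise ValueError("footprint A and B must be positive")

    def warn_if_implausible(
        self,
        a_range: tuple[float, float] = A_PLAUSIBLE,
        b_range: tuple[float, float] = B_PLAUSIBLE,
    ) -> None:
        if not (a_range[0] <= self.A <= a_range[1]):
            warnings.warn(
                f"A = {self.A:.3f} mm outside plausible range {a_range}",
                PlausibilityWarning, stacklevel=2,
            )
        if not (b_range[0] <= self.B <= b_range[1]):
            warnings.warn(
                f"B = {self.B:.3f} mm outside plausible range {b_range}",
                PlausibilityWarning, stacklevel=2,
            )


# ---------------------------------------------------------------------------
# planar contour primitives
# ---------------------------------------------------------------------------

def _planar_coords(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project 3-D contour points onto their best-fit plane.

    Returns (uv, center, basis) where ``uv`` is (n,2), ``center`` the point
    mean and ``basis`` a (2,3) orthonormal in-plane basis, so a planar point
    maps back as ``center + uv @ basis``.
    """
    p = np.asarray(points, dtype=float)
    center = p.mean(axis=0)
    rel = p - center
    _, s, vt = np.linalg.svd(rel, full_matrices=False)
    if p.shape[0] > 3 and s[2] > 1e-6 * max(s[0], 1.0):
        raise ValueError(
            f"contour points are not coplanar (out-of-plane spread {s[2]:.2e})"
        )
    basis = vt[:2]
    return rel @ basis.T, center, basis


def _prepare_contour(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("a contour needs at least 3 points")
    if p.shape[1] == 2:
        uv = p - p.mean(axis=0)
        center = np.append(p.mean(axis=0), 0.0)
        basis = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    elif p.shape[1] == 3:
        uv, center, basis = _planar_coords(p)
    else:
        raise ValueError("contour points must be 2-D or 3-D")
    ring = LinearRing(uv)
    if not ring.is_valid or not ring.is_simple:
        raise ValueError("contour is self-intersecting")
    return uv, center, basis


def _shoelace(uv: np.ndarray) -> float:
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def cross_section_area(points) -> float:
    """Absolute shoelace area (mm²) of a closed planar contour.

    Accepts (n,2) in-plane points or (n,3) coplanar points; the contour is
    closed by connecting the last point back to the first.  Orientation- and
    rigid-transform-invariant.  Self-intersecting contours are rejected.
    """
    uv, _, _ = _prepare_contour(points)
    area = abs(_shoelace(uv))
    if area <= 0:
        raise ValueError("degenerate (zero-area) contour")
    return area


def section_centroid(points) -> np.ndarray:
    """Area-weighted centroid of a closed planar contour, embedded in 3-D."""
    uv, center, basis = _prepare_contour(points)
    a = _shoelace(uv)
    if abs(a) < 1e-14:
        raise ValueError("degenerate (zero-area) contour has no centroid")
    x, y = uv[:, 0], uv[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cu = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cv = float(np.sum((y + yn) * cross)) / (6.0 * a)
    out = center + np.array([cu, cv]) @ basis
    return out[:2] if np.asarray(points).shape[1] == 2 else out


# ---------------------------------------------------------------------------
# segmentation-level operations
# ---------------------------------------------------------------------------

def cross_sections(seg: STSegmentation) -> list[CrossSection]:
    """Area, centroid and lateral-wall point for every station."""
    wall = lateral_wall(seg)
    out = []
    for s, wp in zip(seg.stations, wall.points):
        out.append(
            CrossSection(
                angle=s.angle,
                area=cross_section_area(s.points),
                centroid=section_centroid(s.points),
                max_wall_point=wp,
            )
        )
    return out


def volume_increments(areas: np.ndarray, distances: np.ndarray,
                      rule: str = "frustum") -> np.ndarray:
    """Volume (μL) between adjacent cross-sections.

    ``frustum``: d·(Aᵢ + Aᵢ₊₁ + √(AᵢAᵢ₊₁))/3, exact for a linearly tapering
    tube; ``trapezoid``: d·(Aᵢ + Aᵢ₊₁)/2, kept for sensitivity checks.
    """
    areas = np.asarray(areas, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if distances.size != areas.size - 1:
        raise ValueError("need one distance per adjacent section pair")
    if np.any(areas < 0) or np.any(distances < 0):
        raise ValueError("areas and distances must be non-negative")
    a0, a1 = areas[:-1], areas[1:]
    if rule == "frustum":
        return distances * (a0 + a1 + np.sqrt(a0 * a1)) / 3.0
    if rule == "trapezoid":
        return distances * (a0 + a1) / 2.0
    raise ValueError(f"unknown volume rule {rule!r}")


def volume_profile(seg: STSegmentation, rule: str = "frustum") -> VolumeProfile:
    """Cumulative ST volume over angle from adjacent-section increments.

    The increment between sections i and i+1 of areas Aᵢ, Aᵢ₊₁ whose
    centroids are d mm apart is the conical-frustum rule
    ``d·(Aᵢ + Aᵢ₊₁ + √(AᵢAᵢ₊₁))/3`` — exact for a linearly tapering tube and
    equal to the prism rule when the areas match.  ``rule="trapezoid"``
    switches to ``d·(Aᵢ + Aᵢ₊₁)/2`` for sensitivity checks.
    """
    secs = cross_sections(seg)
    areas = np.array([c.area for c in secs])
    cents = np.array([c.centroid for c in secs])
    d = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    vol = np.concatenate([[0.0], np.cumsum(volume_increments(areas, d, rule))])
    angles = seg.angles
    if angles[0] != 0.0:
        # profile is cumulative from the first segmented station
        warnings.warn(
            f"first station of {seg.specimen_id!r} at {angles[0]}°, not 0°",
            stacklevel=2,
        )
    return VolumeProfile(angles, vol, provenance="measured")


def lateral_wall(seg: STSegmentation) -> LateralWallProfile:
    """Per station, the contour point with maximal distance to the axis.

    Ties (within floating-point equality) are broken by the lowest point
    index, making the result deterministic.
    """
    pts, angles = [], []
    for s in seg.stations:
        dist = seg.axis.axial_distance(s.points)
        idx = int(np.argmax(dist))  # argmax returns the first maximal index
        pts.append(s.points[idx])
        angles.append(s.angle)
    return LateralWallProfile(np.array(angles), np.array(pts))


def extract_footprint(
    wall: LateralWallProfile,
    axis: ModiolarAxis,
    eps: float = 0.1,
    basal_limit: float = 360.0,
    warn_plausibility: bool = True,
) -> CochlearFootprint:
    """Footprint parameters A and B from the basal-turn lateral wall.

    Basal-turn wall points (angle ≤ ``basal_limit``) are projected onto the
    plane perpendicular to the modiolar axis.  A is the longest chord
    between two projected points whose connecting segment passes within
    ``eps`` mm of the projected axis; among equally long candidates the one
    anchored nearest the round window (0°) wins.  B is the extent of the
    projected basal wall measured perpendicular to the A chord.

    If no chord passes within ``eps`` of the axis, ``eps`` is doubled until
    one does; the value actually used is reported as ``eps_used``.
    """
    if wall.angles[-1] < basal_limit:
        raise ValueError(
            f"lateral wall covers only {wall.angles[-1]}°; "
            f"≥{basal_limit}° needed for footprint extraction"
        )
    mask = wall.angles <= basal_limit + 1e-9
    angles = wall.angles[mask]
    e1, e2, e3 = axis.frame()
    rel = wall.points[mask] - axis.origin
    proj = np.column_stack([rel @ e1, rel @ e2])  # axis projects to (0, 0)

    n = proj.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    p, q = proj[ii], proj[jj]
    # distance from origin to segment pq
    pq = q - p
    t = np.clip(-np.einsum("ij,ij->i", p, pq) / np.einsum("ij,ij->i", pq, pq), 0.0, 1.0)
    closest = p + t[:, None] * pq
    seg_dist = np.linalg.norm(closest, axis=1)
    lengths = np.linalg.norm(pq, axis=1)

    eps_used = float(eps)
    cand = seg_dist <= eps_used
    while not np.any(cand):
        eps_used *= 2.0
        cand = seg_dist <= eps_used
        if eps_used > 2.0 * np.max(lengths):
            raise ValueError("no chord through the axis found on the basal wall")
    if eps_used != eps:
        warnings.warn(
            f"no A-chord within ε = {eps} mm of the axis; widened to {eps_used} mm",
            stacklevel=2,
        )

    cl = np.where(cand, lengths, -np.inf)
    best_len = np.max(cl)
    ties = np.flatnonzero(cl >= best_len - 1e-12)
    # anchor at the round-window side: prefer the chord whose nearest
    # endpoint station is closest to 0°
    anchor = np.minimum(angles[ii[ties]], angles[jj[ties]])
    k = ties[int(np.argmin(anchor))]
    a_val = float(lengths[k])
    a_dir = pq[k] / lengths[k]
    normal = np.array([-a_dir[1], a_dir[0]])
    t_all = proj @ normal
    b_val = float(np.max(t_all) - np.min(t_all))

    fp = CochlearFootprint(
        A=a_val,
        B=b_val,
        eps_used=eps_used,
        a_chord_angles=(float(angles[ii[k]]), float(angles[jj[k]])),
    )
    if warn_plausibility:
        fp.warn_if_implausible()
    return fp
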