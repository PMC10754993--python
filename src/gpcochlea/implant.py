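"""Cochlear-implant electrode model, insertion mapping, partition, dosing.

The guinea-pig CI array is modeled as a straight conical frustum inserted
tip-first (defaults: length 5 mm, tip diameter 0.3 mm, basal diameter
0.6 mm, optional 50 μm coating on the lateral surface).  Insertion depth
(EID, mm) maps linearly to insertion angle (IA, deg) via a regression fitted
on measured (EID, IA) pairs.  Given an ST volume profile and an insertion
plan, the perilymph is partitioned into the volume basal to the implant
(cochleostomy pocket), surrounding it, and apical to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .profile import VolumeProfile

__all__ = [
    "ElectrodeSpec",
    "InsertionRegression",
    "InsertionPlan",
    "PerilymphPartition",
    "fit_insertion_regression",
    "predict_ia",
    "eid_for_ia",
    "electrode_volume",
    "partition_perilymph",
    "required_drug_amount",
    "bolus_volume",
]

Approach = Literal["round_window", "cochleostomy"]


@dataclass(frozen=True)
class ElectrodeSpec:
    """Tapered CI array geometry (mm).  Diameters are at tip and base."""

    length: float = 5.0
    tip_diameter: float = 0.3
    basal_diameter: float = 0.6
    coating_thickness: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.tip_diameter <= self.basal_diameter):
            raise ValueError("need 0 < tip_diameter ≤ basal_diameter")
        if self.length <= 0:
            raise ValueError("electrode length must be positive")
        if self.coating_thickness < 0:
            raise ValueError("coating thickness must be non-negative")

    def diameter_at(self, x: float, coated: bool = False) -> float:
        """Diameter at distance ``x`` mm from the tip (0 ≤ x ≤ length)."""
        d = self.tip_diameter + (self.basal_diameter - self.tip_diameter) * x / self.length
        return d + 2.0 * self.coating_thickness if coated else d


def electrode_volume(
    spec: ElectrodeSpec,
    eid: float,
    coated: bool = False,
    include_tip_cap: bool = False,
) -> float:
    """Volume (μL) of the inserted, tip-first portion of the array.

    Closed-form frustum integration of π·d(x)²/4 over x ∈ [0, eid].  The
    coating adds twice its thickness to every diameter (lateral surface
    only); ``include_tip_cap`` additionally counts a flat coating disc on
    the tip face.
    """
    if not (0.0 <= eid <= spec.length + 1e-12):
        raise ValueError(f"EID {eid} mm outside [0, {spec.length}] mm")
    if eid == 0.0:
        return 0.0
    d0 = spec.diameter_at(0.0, coated)
    d1 = spec.diameter_at(eid, coated)
    vol = np.pi * eid * (d0 * d0 + d0 * d1 + d1 * d1) / 12.0
    if coated and include_tip_cap:
        vol += np.pi * (d0 / 2.0) ** 2 * spec.coating_thickness
    return float(vol)


# ---------------------------------------------------------------------------
# EID ↔ IA regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionRegression:
    """Linear map IA = slope·EID + intercept, pooled across approaches."""

    slope: float
    intercept: float
    r_squared: float
    per_approach_offsets: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("regression coefficients must be finite")


def _pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs.rename(columns={"eid_mm": "eid", "ia_deg": "ia"})
        missing = {"eid", "ia"} - set(df.columns)
        if missing:
            raise ValueError(f"insertion data missing columns {sorted(missing)}")
        if "approach" not in df.columns:
            df = df.assign(approach="round_window")
        return df[["eid", "ia", "approach"]].astype({"eid": float, "ia": float})
    rows = []
    for rec in pairs:
        eid, ia = float(rec[0]), float(rec[1])
        approach = rec[2] if len(rec) > 2 else "round_window"
        rows.append((eid, ia, approach))
    return pd.DataFrame(rows, columns=["eid", "ia", "approach"])


def fit_insertion_regression(pairs, per_approach_offsets: bool = False) -> InsertionRegression:
    """Ordinary least squares IA on EID over pooled (EID, IA) pairs.

    Requires ≥3 pairs and non-constant EID.  With
    ``per_approach_offsets=True`` the mean residual of each approach is
    reported as an additive intercept offset.
    """
    df = _pairs_frame(pairs)
    if len(df) < 3:
        raise ValueError("need at least 3 (EID, IA) pairs")
    if np.ptp(df["eid"].to_numpy()) == 0:
        raise ValueError("EID is constant; no slope identifiable")
    res = stats.linregress(df["eid"], df["ia"])
    offsets = None
    if per_approach_offsets:
        resid = df["ia"] - (res.slope * df["eid"] + res.intercept)
        offsets = {k: float(v) for k, v in resid.groupby(df["approach"]).mean().items()}
    return InsertionRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        per_approach_offsets=offsets,
    )


def predict_ia(reg: InsertionRegression, eid: float, approach: Optional[str] = None) -> float:
    """Insertion angle (deg) predicted for an insertion depth (mm)."""
    ia = reg.slope * eid + reg.intercept
    if approach is not None and reg.per_approach_offsets:
        ia += reg.per_approach_offsets.get(approach, 0.0)
    if ia < 0:
        warnings.warn(f"predicted IA {ia:.1f}° < 0; clamped to 0", stacklevel=2)
        ia = 0.0
    return float(ia)


def eid_for_ia(reg: InsertionRegression, ia: float, approach: Optional[str] = None) -> float:
    """Inverse mapping: insertion depth (mm) required to reach ``ia`` deg."""
    if approach is not None and reg.per_approach_offsets:
        ia = ia - reg.per_approach_offsets.get(approach, 0.0)
    return float((ia - reg.intercept) / reg.slope)


# ---------------------------------------------------------------------------
# perilymph partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionPlan:
    """Where and how deep the array goes.

    ``entry_angle`` is 0 for the round-window approach; for a cochleostomy
    it must be given explicitly (it controls the basal pocket volume and no
    universal default exists).  ``ia`` may be supplied from a postoperative
    measurement or left None to be predicted from a regression.
    """

    approach: Approach
    eid: float
    entry_angle: float = 0.0
    ia: Optional[float] = None

    def __post_init__(self) -> None:
        if self.approach not in ("round_window", "cochleostomy"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.eid < 0:
            raise ValueError("EID must be non-negative")
        if self.approach == "round_window" and self.entry_angle != 0.0:
            raise ValueError("round-window insertion enters at 0°")
        if self.approach == "cochleostomy" and self.entry_angle <= 0.0:
            raise ValueError(
                "cochleostomy requires an explicit positive entry_angle"
            )
        if self.ia is not None and self.ia < self.entry_angle:
            raise ValueError("IA cannot be basal to the entry angle")


@dataclass(frozen=True)
class PerilymphPartition:
    """Perilymph volumes (μL) split around the inserted array."""

    basal: float
    surrounding: float
    apical: float
    implant: float
    total: float
    net_curve: Optional[pd.DataFrame] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("basal", "surrounding", "apical", "implant", "total"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"partition component {name} is negative")
        if abs(self.basal + self.surrounding + self.apical + self.implant - self.total) > 1e-9:
            raise ValueError("partition does not conserve total volume")


def partition_perilymph(
    profile: VolumeProfile,
    spec: ElectrodeSpec,
    plan: InsertionPlan,
    reg: Optional[InsertionRegression] = None,
    coated: bool = False,
    n_curve: int = 97,
) -> PerilymphPartition:
    """Split the ST perilymph into basal / surrounding / apical volumes.

    ``basal`` is the pocket between the round window and the entry site
    (non-zero only for a cochleostomy), ``surrounding`` the perilymph next
    to the array between entry and the electrode tip, ``apical`` everything
    beyond the tip.  The array's own displaced volume is reported separately
    and the four parts sum to the profile total exactly.

    The result carries ``net_curve``, remaining perilymph volume vs angle,
    obtained by spreading the array volume over [entry_angle, IA] with a
    linear arc-length↔angle mapping (this affects only the curve, never the
    three-region totals).
    """
    ia = plan.ia
    if ia is None:
        if plan.eid == 0.0:
            ia = plan.entry_angle
        else:
            if reg is None:
                raise ValueError("plan has no IA and no regression was given")
            ia = predict_ia(reg, plan.eid, plan.approach)
            ia = max(ia, plan.entry_angle)
    if ia > profile.max_angle + 1e-9:
        raise ValueError(
            f"IA {ia:.1f}° beyond the profile's apical limit {profile.max_angle}°"
        )

    total = profile.total
    v_entry = float(profile(plan.entry_angle))
    v_ia = float(profile(ia))
    implant = electrode_volume(spec, plan.eid, coated=coated)
    basal = v_entry - float(profile(profile.angles[0]))
    apical = total - v_ia
    surrounding = v_ia - v_entry - implant
    if surrounding < -1e-12:
        raise ValueError(
            "electrode displaces more than the local scalar volume "
            f"(deficit {-surrounding:.4f} μL between {plan.entry_angle}° and {ia:.1f}°)"
        )
    surrounding = max(surrounding, 0.0)

    grid = np.linspace(profile.angles[0], profile.max_angle, n_curve)
    occupied = np.zeros_like(grid)
    if plan.eid > 0 and ia > plan.entry_angle:
        inside = (grid >= plan.entry_angle) & (grid <= ia)
        # arc length from tip of the array part apical to angle θ
        s_tip = (ia - grid[inside]) / (ia - plan.entry_angle) * plan.eid
        occupied[inside] = implant - np.array(
            [electrode_volume(spec, s, coated=coated) for s in s_tip]
        )
        occupied[grid > ia] = implant
    net = profile(grid) - occupied
    net_curve = pd.DataFrame({"angle_deg": grid, "net_volume_uL": net})

    return PerilymphPartition(
        basal=basal,
        surrounding=surrounding,
        apical=apical,
        implant=implant,
        total=total,
        net_curve=net_curve,
    )


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------

def required_drug_amount(
    concentration: float,
    volume_ul: float,
    molar_mass: Optional[float] = None,
    unit: Literal["g_per_L", "mol_per_L"] = "g_per_L",
) -> float:
    """Drug mass (μg) needed to reach ``concentration`` in ``volume_ul`` μL.

    ``g_per_L`` concentrations (≡ μg/μL) multiply directly; molar
    concentrations (mol/L) additionally require the molar mass (g/mol).
    """
    if concentration < 0 or volume_ul < 0:
        raise ValueError("concentration and volume must be non-negative")
    if unit == "g_per_L":
        return float(concentration * volume_ul)
    if unit == "mol_per_L":
        if molar_mass is None:
            raise ValueError("molar concentration requires a molar mass (g/mol)")
        # mol/L · μL = μmol·1e-3 ; × g/mol → mg·1e-3 = μg
        grams = concentration * volume_ul * 1e-6 * molar_mass
        return float(grams * 1e6)
    raise ValueError(f"unknown concentration unit {unit!r}")


def bolus_volume(target_mass_ug: float, stock_concentration_g_per_L: float) -> float:
    """Injection volume (μL) of a stock solution delivering a target mass."""
    if target_mass_ug < 0:
        raise ValueError("target mass must be non-negative")
    if stock_concentration_g_per_L <= 0:
        raise ValueError("stock concentration must be positive")
    return float(target_mass_ug / stock_concentration_g_per_L)
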