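"""Plain-text readers and writers binding the modules into a workflow.

Formats (all lossless at double precision, numbers written with ``repr``):

* segmentation CSV — ``specimen_id, group, angle_deg, point_index, x_mm,
  y_mm, z_mm``; several specimens may share one file.  A sidecar JSON holds
  the modiolar axis (``origin``, ``direction``, ``rw_reference``), either as
  one object applied to all specimens or a map specimen_id → object.
* profile CSV — ``angle_deg, cum_volume_uL`` (or ``fraction``).
* cohort CSV — ``specimen_id, group, A_mm, B_mm, v360_uL``.
* insertion CSV — ``specimen_id, approach, eid_mm, ia_deg``.
* electrode spec YAML — ``length_mm, tip_diameter_mm, basal_diameter_mm,
  coating_thickness_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .evaluation import Cohort
from .geometry import ContourStation, ModiolarAxis, STSegmentation
from .implant import ElectrodeSpec
from .profile import NormalizedProfile, VolumeProfile

__all__ = [
    "read_segmentation",
    "write_segmentation",
    "read_profile",
    "write_profile",
    "read_cohort",
    "write_cohort",
    "read_insertion_dataset",
    "read_model_coefficients",
    "write_model_coefficients",
    "read_electrode_spec",
    "write_electrode_spec",
    "write_report",
]

PathLike = Union[str, Path]

_SEG_COLUMNS = ["specimen_id", "group", "angle_deg", "point_index",
                "x_mm", "y_mm", "z_mm"]


def _axis_from_dict(d: dict) -> ModiolarAxis:
    try:
        return ModiolarAxis(
            origin=np.asarray(d["origin"], dtype=float),
            direction=np.asarray(d["direction"], dtype=float),
            rw_reference=np.asarray(d["rw_reference"], dtype=float),
        )
    except KeyError as exc:
        raise ValueError(f"axis sidecar missing key {exc}") from exc


def _axis_to_dict(axis: ModiolarAxis) -> dict:
    return {
        "origin": axis.origin.tolist(),
        "direction": axis.direction.tolist(),
        "rw_reference": axis.rw_reference.tolist(),
    }


def read_segmentation(csv_path: PathLike, sidecar_path: Optional[PathLike] = None,
                      sort: bool = False) -> list[STSegmentation]:
    """Load one or more segmentations from a CSV plus its axis sidecar.

    ``sidecar_path`` defaults to the CSV path with suffix ``.axis.json``.
    Rows must be ordered by angle and point index per specimen unless
    ``sort=True``.
    """
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".axis.json")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = set(_SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path.name}: missing columns {sorted(missing)}")
    for col in ("angle_deg", "x_mm", "y_mm", "z_mm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # 1-based + header
            raise ValueError(f"{csv_path.name}: non-numeric {col} at lines {lines}")
        df[col] = pd.to_numeric(df[col])

    sidecar = json.loads(Path(sidecar_path).read_text())
    per_specimen = not {"origin", "direction", "rw_reference"} <= set(sidecar)

    segs = []
    for sid, sdf in df.groupby("specimen_id", sort=False):
        axis = _axis_from_dict(sidecar[str(sid)] if per_specimen else sidecar)
        group = sdf["group"].iloc[0]
        group = None if pd.isna(group) else str(group)
        stations = []
        angles_seen = []
        for ang, adf in sdf.groupby("angle_deg", sort=sort):
            adf = adf.sort_values("point_index") if sort else adf
            pts = adf[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
            stations.append(ContourStation(angle=float(ang), points=pts))
            angles_seen.append(float(ang))
        if not sort and np.any(np.diff(angles_seen) <= 0):
            raise ValueError(
                f"{csv_path.name}: specimen {sid!r} has unsorted station "
                "angles; pass sort=True to reorder"
            )
        stations.sort(key=lambda s: s.angle)
        segs.append(STSegmentation(specimen_id=str(sid), axis=axis,
                                   stations=tuple(stations), group=group))
    return segs


def write_segmentation(segs: list[STSegmentation], csv_path: PathLike,
                       sidecar_path: Optional[PathLike] = None) -> None:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".axis.json")
    rows = []
    sidecar = {}
    for seg in segs:
        sidecar[seg.specimen_id] = _axis_to_dict(seg.axis)
        for st in seg.stations:
            for k, p in enumerate(st.points):
                rows.append((seg.specimen_id, seg.group or "", st.angle, k,
                             repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))))
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(csv_path, index=False)
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_profile(path: PathLike) -> VolumeProfile | NormalizedProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    if "cum_volume_uL" in df.columns:
        return VolumeProfile(df["angle_deg"].to_numpy(float),
                             df["cum_volume_uL"].to_numpy(float))
    if "fraction" in df.columns:
        return NormalizedProfile(df["angle_deg"].to_numpy(float),
                                 df["fraction"].to_numpy(float))
    raise ValueError(f"{path}: expected a cum_volume_uL or fraction column")


def write_profile(profile: VolumeProfile | NormalizedProfile, path: PathLike) -> None:
    if isinstance(profile, VolumeProfile):
        df = pd.DataFrame({"angle_deg": profile.angles,
                           "cum_volume_uL": [repr(float(v)) for v in profile.volumes]})
    else:
        df = pd.DataFrame({"angle_deg": profile.angles,
                           "fraction": [repr(float(v)) for v in profile.fractions]})
    df.to_csv(path, index=False)


def read_cohort(path: PathLike, profile_dir: Optional[PathLike] = None) -> Cohort:
    """Cohort CSV; per-specimen profile CSVs are read from ``profile_dir``
    (named ``<specimen_id>.csv``) when given."""
    df = pd.read_csv(path, float_precision="round_trip")
    profiles = None
    if profile_dir is not None:
        profiles = {}
        for sid in df["specimen_id"]:
            p = Path(profile_dir) / f"{sid}.csv"
            if p.exists():
                prof = read_profile(p)
                if not isinstance(prof, VolumeProfile):
                    raise ValueError(f"{p}: expected an absolute volume profile")
                profiles[str(sid)] = prof
    return Cohort(table=df, profiles=profiles)


def write_cohort(cohort: Cohort, path: PathLike,
                 profile_dir: Optional[PathLike] = None) -> None:
    cohort.table.to_csv(path, index=False, float_format="%.17g")
    if profile_dir is not None and cohort.profiles:
        d = Path(profile_dir)
        d.mkdir(parents=True, exist_ok=True)
        for sid, prof in cohort.profiles.items():
            write_profile(prof, d / f"{sid}.csv")


def read_insertion_dataset(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"eid_mm", "ia_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_model_coefficients(path: PathLike):
    """Model-coefficient YAML → (ECACoefficients, V360Regression).

    Keys: ``eca: {cA, cB, cCross, cross_term_variant}`` and
    ``v360: {slope, intercept}``; omitted keys keep the packaged defaults.
    """
    from .anatomy import ECACoefficients, V360Regression

    d = yaml.safe_load(Path(path).read_text()) or {}
    eca = ECACoefficients(**d.get("eca", {}))
    v360 = V360Regression(**d.get("v360", {}))
    return eca, v360


def write_model_coefficients(eca, v360, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump({
        "eca": {"cA": eca.cA, "cB": eca.cB, "cCross": eca.cCross,
                "cross_term_variant": eca.cross_term_variant},
        "v360": {"slope": v360.slope, "intercept": v360.intercept},
    }))


def read_electrode_spec(path: PathLike) -> ElectrodeSpec:
    d = yaml.safe_load(Path(path).read_text())
    try:
        return ElectrodeSpec(
            length=float(d["length_mm"]),
            tip_diameter=float(d["tip_diameter_mm"]),
            basal_diameter=float(d["basal_diameter_mm"]),
            coating_thickness=float(d.get("coating_thickness_mm", 0.0)),
        )
    except KeyError as exc:
        raise ValueError(f"electrode spec missing key {exc}") from exc


def write_electrode_spec(spec: ElectrodeSpec, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump({
        "length_mm": spec.length,
        "tip_diameter_mm": spec.tip_diameter,
        "basal_diameter_mm": spec.basal_diameter,
        "coating_thickness_mm": spec.coating_thickness,
    }))


def write_report(report: dict, path: PathLike) -> None:
    """JSON report writer (full double precision via native float repr)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=default))
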