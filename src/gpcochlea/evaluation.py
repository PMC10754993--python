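"""Model evaluation: leave-one-out cross-validation and cohort statistics.

`loocv_volume` re-derives the whole estimation chain (normalized mean
profile, logarithmic fit, V360 regression) on all-but-one specimen and
scores the held-out profile, per angular station.  `loocv_insertion` does
the same for the EID→IA regression.  The remaining functions cover the
descriptive statistics used for cohorts: relative standard deviation,
Pearson R², and pairwise Mann–Whitney–Wilcoxon group comparisons with
Bonferroni correction and 1.5×IQR outlier flags.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import anatomy
from .anatomy import ECACoefficients, V360Regression, build_mean_profile, fit_log_profile
from .profile import VolumeProfile

__all__ = [
    "Cohort",
    "LoocvResult",
    "InsertionLoocvResult",
    "loocv_volume",
    "loocv_insertion",
    "rsd",
    "pearson_r2",
    "compare_groups",
]

#: exact Mann–Whitney enumeration is used up to this per-group size
_EXACT_N = 12


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cohort:
    """Per-specimen records used for fitting, LOOCV and group statistics.

    ``table`` columns: ``specimen_id``, ``group``, ``A_mm``, ``B_mm`` and
    optionally ``v360_uL``; ``profiles`` maps specimen id → measured
    :class:`VolumeProfile` (required for volume LOOCV).
    """

    table: pd.DataFrame
    profiles: Optional[dict[str, VolumeProfile]] = None

    def __post_init__(self) -> None:
        required = {"specimen_id", "group", "A_mm", "B_mm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        ids = self.table["specimen_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate specimen ids {dup}")
        if self.profiles is not None:
            unknown = set(self.profiles) - set(ids)
            if unknown:
                raise ValueError(f"profiles for unknown specimens {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.table)

    def v360(self) -> pd.Series:
        """Measured V(360°) per specimen, from the table or the profiles."""
        if "v360_uL" in self.table.columns and self.table["v360_uL"].notna().all():
            return self.table.set_index("specimen_id")["v360_uL"].astype(float)
        if self.profiles is None:
            raise ValueError("cohort has neither v360_uL column nor profiles")
        return pd.Series({sid: p.v360 for sid, p in self.profiles.items()})

    def btl(self, coeffs: ECACoefficients = anatomy.DEFAULT_ECA) -> pd.Series:
        t = self.table.set_index("specimen_id")
        return pd.Series(
            {sid: anatomy.eca_btl((row.A_mm, row.B_mm), coeffs)
             for sid, row in t.iterrows()}
        )


# ---------------------------------------------------------------------------
# volume LOOCV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoocvResult:
    """Per-specimen, per-angle signed deviations dV = estimate − measured."""

    method: str
    deviations: pd.DataFrame  # columns specimen_id, angle_deg, dv_uL
    summary: pd.DataFrame     # per angle: median, IQR, median |dV|
    n: int

    def max_median_abs_dv(self) -> float:
        """Largest per-angle median absolute deviation across the grid (μL)."""
        return float(self.summary["median_abs_dv_uL"].max())


def _fit_v360_regression(btl: np.ndarray, v360: np.ndarray) -> V360Regression:
    res = stats.linregress(btl, v360)
    if res.slope <= 0:
        raise ValueError("refit V360 regression has non-positive slope")
    return V360Regression(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2))


def loocv_volume(
    cohort: Cohort,
    method: Literal["mean", "log", "scaling"],
    angles: Optional[Iterable[float]] = None,
    coeffs: ECACoefficients = anatomy.DEFAULT_ECA,
) -> LoocvResult:
    """Leave-one-out cross-validation of a volume-profile estimation method.

    For every specimen the normalized mean profile, the logarithmic fit and
    the V360-on-BTL regression are re-derived from the remaining specimens;
    the held-out profile is then estimated by ``method`` from its footprint
    alone and the deviation recorded on the angular grid (22.5° stations up
    to the common apical limit by default).
    """
    if cohort.profiles is None:
        raise ValueError("volume LOOCV needs measured profiles")
    ids = list(cohort.table["specimen_id"])
    if len(ids) < 3:
        raise ValueError("volume LOOCV needs a cohort of at least 3")
    profiles = cohort.profiles
    if angles is None:
        max_common = min(p.max_angle for p in profiles.values())
        angles = np.arange(0.0, max_common + 1e-9, 22.5)
    angles = np.asarray(angles, dtype=float)

    btl = cohort.btl(coeffs)
    v360 = cohort.v360()
    fp = cohort.table.set_index("specimen_id")[["A_mm", "B_mm"]]

    rows = []
    for held in ids:
        rest = [i for i in ids if i != held]
        rest_profiles = [profiles[i] for i in rest]
        measured = profiles[held](angles)
        if method == "mean":
            est = np.mean([p(angles) for p in rest_profiles], axis=0)
        else:
            reg = _fit_v360_regression(btl[rest].to_numpy(), v360[rest].to_numpy())
            v360_hat = anatomy.predict_v360(float(btl[held]), reg)
            if method == "scaling":
                norm = build_mean_profile(rest_profiles, grid=angles)
                est = norm(angles) * v360_hat
            elif method == "log":
                mean_abs = VolumeProfile(
                    angles, np.mean([p(angles) for p in rest_profiles], axis=0),
                    provenance="mean_model",
                )
                lf = fit_log_profile(mean_abs)
                est = v360_hat * np.log1p(angles / lf.b) / np.log1p(360.0 / lf.b)
            else:
                raise ValueError(f"unknown LOOCV method {method!r}")
        for ang, dv in zip(angles, est - measured):
            rows.append((held, float(ang), float(dv)))

    dev = pd.DataFrame(rows, columns=["specimen_id", "angle_deg", "dv_uL"])
    g = dev.groupby("angle_deg")["dv_uL"]
    summary = pd.DataFrame({
        "median_dv_uL": g.median(),
        "iqr_dv_uL": g.quantile(0.75) - g.quantile(0.25),
        "median_abs_dv_uL": g.apply(lambda s: s.abs().median()),
    }).reset_index()
    return LoocvResult(method=method, deviations=dev, summary=summary, n=len(ids))


# ---------------------------------------------------------------------------
# insertion LOOCV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionLoocvResult:
    """Bland–Altman-style summary of predicted-minus-measured IA (deg)."""

    deviations: np.ndarray
    median_deviation: float
    median_abs_deviation: float


def loocv_insertion(pairs) -> InsertionLoocvResult:
    """Leave-one-out cross-validation of the EID→IA regression."""
    from .implant import _pairs_frame, fit_insertion_regression, predict_ia

    df = _pairs_frame(pairs).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("insertion LOOCV needs at least 3 pairs")
    devs = []
    for k in range(len(df)):
        rest = df.drop(index=k)
        reg = fit_insertion_regression(rest)
        pred = reg.slope * df.loc[k, "eid"] + reg.intercept
        devs.append(pred - df.loc[k, "ia"])
    devs = np.asarray(devs)
    return InsertionLoocvResult(
        deviations=devs,
        median_deviation=float(np.median(devs)),
        median_abs_deviation=float(np.median(np.abs(devs))),
    )


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def rsd(values: Optional[Sequence[float]] = None,
        mean: Optional[float] = None,
        sd: Optional[float] = None) -> float:
    """Relative standard deviation in percent: 100·SD/mean.

    Accepts either raw samples (sample SD, n−1 denominator) or a
    (mean, sd) summary pair.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 values for an RSD")
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
    elif mean is None or sd is None:
        raise ValueError("provide either samples or both mean and sd")
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * sd / mean


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant vectors")
    return float(stats.pearsonr(x, y).statistic ** 2)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _mww_exact_permutation(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann–Whitney p by full enumeration (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U with the method matched to the sample size.

    Exact distribution (no ties, both groups ≤ 12); exact permutation
    enumeration (ties, pooled n ≤ 16); tie-corrected normal approximation
    otherwise.  Returns (U of the first sample, p, method label).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").statistic)
    if x.size <= _EXACT_N and y.size <= _EXACT_N:
        if not has_ties:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue)
            return u, p, "exact"
        if x.size + y.size <= 16:
            return u, _mww_exact_permutation(x, y), "exact_permutation"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue)
    return u, p, "asymptotic"


def _iqr_outliers(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def compare_groups(
    cohort: Cohort,
    parameter: Literal["A", "B", "BTL", "V360"],
    coeffs: ECACoefficients = anatomy.DEFAULT_ECA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Mann–Whitney group comparisons for one parameter.

    Returns (comparisons, per-specimen values).  P-values are Bonferroni
    corrected by the number of pairwise comparisons and capped at 1.
    The value table flags 1.5×IQR outliers within each group.
    """
    t = cohort.table.set_index("specimen_id")
    if parameter == "A":
        vals = t["A_mm"].astype(float)
    elif parameter == "B":
        vals = t["B_mm"].astype(float)
    elif parameter == "BTL":
        vals = cohort.btl(coeffs)
    elif parameter == "V360":
        vals = cohort.v360()
    else:
        raise ValueError(f"unknown parameter {parameter!r}")
    groups = t["group"]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 specimens")

    pairs = list(itertools.combinations(labels, 2))
    n_comp = len(pairs)
    rows = []
    for g1, g2 in pairs:
        x = vals[groups == g1].to_numpy()
        y = vals[groups == g2].to_numpy()
        u, p, meth = mann_whitney(x, y)
        rows.append({
            "group1": g1, "group2": g2, "parameter": parameter, "U": u,
            "p_uncorrected": p, "p_bonferroni": min(1.0, p * n_comp),
            "method": meth, "n1": len(x), "n2": len(y),
        })
    comparisons = pd.DataFrame(rows)

    flag = pd.Series(False, index=vals.index)
    for lab in labels:
        m = groups == lab
        flag[m] = _iqr_outliers(vals[m].to_numpy())
    values = pd.DataFrame({
        "specimen_id": vals.index, "group": groups.values,
        "value": vals.values, "outlier": flag.values,
    })
    return comparisons, values
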