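"""NOESY buildup processing: normalized intensities -> buildup rates -> distances.

The workflow follows the standard initial-rate (isolated spin-pair)
treatment of NOESY buildups:

1. each cross/diagonal quartet at one mixing time is reduced to the
   geometric-mean normalized intensity
   ``eta = sqrt(cross_1 * cross_2 / (diag_1 * diag_2))``;
2. eta grows linearly with mixing time in the initial-rate regime; the
   buildup rate ``sigma`` (s^-1) is the slope of a least-squares line
   through the origin, accepted only when r^2 exceeds a quality threshold
   (default 0.95) and the slope is positive;
3. rates convert to interproton distances against an internal reference
   pair of known separation via ``r = r_ref * (sigma_ref / sigma)^(1/6)``
   (geminal methylene protons at 1.78 A by default).

Distances beyond 5.5 A are outside the reliable NOE range; they are capped
and flagged rather than silently used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: columns of the peak-table CSV (one row per proton pair per mixing time)
PEAK_COLUMNS = [
    "pair_id",
    "atom_i",
    "atom_j",
    "t_mix_ms",
    "cross_1",
    "cross_2",
    "diag_1",
    "diag_2",
]

RESTRAINT_COLUMNS = ["pair_id", "atom_i", "atom_j", "r_exp", "tolerance", "capped"]


@dataclass(frozen=True)
class PeakRecord:
    """Cross/diagonal intensities for one proton pair at one mixing time."""

    pair_id: str
    atom_i: str
    atom_j: str
    t_mix_ms: float
    cross_1: float
    cross_2: float
    diag_1: float
    diag_2: float


@dataclass
class BuildupCurve:
    """Normalized NOE intensity vs mixing time for one proton pair."""

    pair_id: str
    points: np.ndarray  # (n, 2): t_mix_ms, eta_norm
    sigma: float  # buildup rate, s^-1
    r_squared: float
    accepted: bool
    atom_i: str = ""
    atom_j: str = ""


@dataclass(frozen=True)
class DistanceRestraint:
    """One calibrated interproton distance with its tolerance (Angstrom)."""

    pair_id: str
    atom_i: str
    atom_j: str
    r_exp: float
    tolerance: float
    capped: bool = False

    def __post_init__(self) -> None:
        if self.r_exp <= 0:
            raise ValueError("r_exp must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def normalize_intensity(p: PeakRecord) -> float:
    """Geometric-mean normalized NOE intensity for one quartet.

    Symmetric under swapping the (cross_1, diag_1) and (cross_2, diag_2)
    sides, and invariant under a common intensity scale.
    """
    if p.diag_1 <= 0 or p.diag_2 <= 0:
        raise ValueError(
            f"peak {p.pair_id!r} at t={p.t_mix_ms} ms has a non-positive diagonal"
        )
    if p.cross_1 < 0 or p.cross_2 < 0:
        raise ValueError(f"peak {p.pair_id!r} has a negative cross intensity")
    return float(np.sqrt((p.cross_1 * p.cross_2) / (p.diag_1 * p.diag_2)))


def fit_buildup(
    points: Sequence[tuple[float, float]] | np.ndarray,
    r2_threshold: float = 0.95,
    pair_id: str = "",
    atom_i: str = "",
    atom_j: str = "",
    through_origin: bool = True,
) -> BuildupCurve:
    """Least-squares buildup rate from (t_mix_ms, eta_norm) points.

    The line is constrained through the origin (eta(0) = 0 by construction
    of the normalization); ``through_origin=False`` fits a free intercept
    for diagnostics only — the reported sigma is still the slope.  The
    curve is accepted iff r^2 > ``r2_threshold`` and sigma > 0.  A curve of
    all-zero intensities is rejected (sigma = 0), not an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (t_mix, eta) points")
    t_ms, eta = pts[:, 0], pts[:, 1]
    if np.any(eta < 0):
        raise ValueError("eta_norm must be non-negative")
    if np.all(eta == 0):
        return BuildupCurve(pair_id, pts, 0.0, 0.0, False, atom_i, atom_j)
    t_s = t_ms / 1000.0
    if through_origin:
        slope = float(np.dot(t_s, eta) / np.dot(t_s, t_s))
        pred = slope * t_s
    else:
        slope, intercept = np.polyfit(t_s, eta, 1)
        pred = slope * t_s + intercept
        slope = float(slope)
    ss_res = float(np.sum((eta - pred) ** 2))
    ss_tot = float(np.sum((eta - eta.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    accepted = bool(r2 > r2_threshold and slope > 0)
    return BuildupCurve(pair_id, pts, slope, r2, accepted, atom_i, atom_j)


def calibrate_distance(
    curve: BuildupCurve,
    ref: BuildupCurve,
    r_ref: float = 1.78,
    tolerance_frac: float = 0.10,
    cap: float = 5.5,
) -> DistanceRestraint:
    """Convert a buildup rate to a distance against the internal reference.

    ``r = r_ref * (sigma_ref / sigma)^(1/6)``.  Only the rate *ratio*
    enters, so a common scale on all rates cancels.  Distances beyond
    ``cap`` (default 5.5 A) are truncated and flagged ``capped``.
    """
    for c in (curve, ref):
        if not c.accepted:
            raise ValueError(f"buildup curve {c.pair_id!r} was not accepted")
        if c.sigma <= 0:
            raise ValueError(f"buildup curve {c.pair_id!r} has non-positive rate")
    r = r_ref * (ref.sigma / curve.sigma) ** (1.0 / 6.0)
    capped = bool(cap is not None and r > cap)
    if capped:
        r = float(cap)
    return DistanceRestraint(
        pair_id=curve.pair_id,
        atom_i=curve.atom_i,
        atom_j=curve.atom_j,
        r_exp=float(r),
        tolerance=float(tolerance_frac * r),
        capped=capped,
    )


def read_peak_table(path_or_df) -> pd.DataFrame:
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table is missing columns {missing}")
    return df


def buildup_curves(
    peaks: pd.DataFrame,
    r2_threshold: float = 0.95,
    through_origin: bool = True,
) -> dict[str, BuildupCurve]:
    """Group a peak table by pair and fit one buildup curve per pair.

    Rows with a missing/non-positive diagonal are dropped (that mixing time
    is not imputed); pairs left with fewer than 3 points are skipped.
    """
    curves: dict[str, BuildupCurve] = {}
    for pair_id, grp in peaks.groupby("pair_id", sort=False):
        pts = []
        for row in grp.itertuples(index=False):
            rec = PeakRecord(
                pair_id=str(row.pair_id),
                atom_i=str(row.atom_i),
                atom_j=str(row.atom_j),
                t_mix_ms=float(row.t_mix_ms),
                cross_1=float(row.cross_1),
                cross_2=float(row.cross_2),
                diag_1=float(row.diag_1),
                diag_2=float(row.diag_2),
            )
            if rec.diag_1 <= 0 or rec.diag_2 <= 0 or not np.isfinite(
                rec.diag_1 + rec.diag_2
            ):
                continue
            pts.append((rec.t_mix_ms, normalize_intensity(rec)))
        if len(pts) < 3:
            continue
        first = grp.iloc[0]
        curves[str(pair_id)] = fit_buildup(
            pts,
            r2_threshold=r2_threshold,
            pair_id=str(pair_id),
            atom_i=str(first["atom_i"]),
            atom_j=str(first["atom_j"]),
            through_origin=through_origin,
        )
    return curves


def calibrate_peak_table(
    peaks: pd.DataFrame,
    ref_pair: str,
    r_ref: float = 1.78,
    r2_threshold: float = 0.95,
    tolerance_frac: float = 0.10,
    cap: float = 5.5,
) -> tuple[dict[str, BuildupCurve], list[DistanceRestraint]]:
    """Full calibration: peak table -> accepted curves -> distance restraints.

    The reference pair itself is excluded from the returned restraints.
    Unaccepted curves yield no restraint.
    """
    curves = buildup_curves(peaks, r2_threshold=r2_threshold)
    if ref_pair not in curves:
        raise ValueError(f"reference pair {ref_pair!r} not found in peak table")
    ref = curves[ref_pair]
    if not ref.accepted:
        raise ValueError(f"reference pair {ref_pair!r} buildup was rejected")
    restraints = [
        calibrate_distance(c, ref, r_ref=r_ref, tolerance_frac=tolerance_frac, cap=cap)
        for pid, c in curves.items()
        if pid != ref_pair and c.accepted
    ]
    return curves, restraints


def restraints_to_frame(restraints: Iterable[DistanceRestraint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "atom_i": r.atom_i,
                "atom_j": r.atom_j,
                "r_exp": r.r_exp,
                "tolerance": r.tolerance,
                "capped": r.capped,
            }
            for r in restraints
        ],
        columns=RESTRAINT_COLUMNS,
    )


def frame_to_restraints(df: pd.DataFrame) -> list[DistanceRestraint]:
    return [
        DistanceRestraint(
            pair_id=str(row.pair_id),
            atom_i=str(row.atom_i),
            atom_j=str(row.atom_j),
            r_exp=float(row.r_exp),
            tolerance=float(row.tolerance),
            capped=bool(getattr(row, "capped", False)),
        )
        for row in df.itertuples(index=False)
    ]
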