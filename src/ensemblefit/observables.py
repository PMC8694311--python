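"""Back-calculation of ensemble-averaged NMR observables.

Two observables drive the population fit:

* effective interproton distances, averaged as ``<r^-6>^(-1/6)`` across the
  weighted conformer set (slow internal motion regime, the averaging NAMFIS
  uses); an ``r^-3`` option exists for the fast-motion limit but is off by
  default;
* vicinal scalar couplings, back-calculated per conformer from the Karplus
  relation ``J(theta) = A cos^2(theta) + B cos(theta) + C`` with
  ``theta = phi + offset`` and averaged linearly.

Degenerate proton groups (methyls, unassigned methylenes) are handled by
r^-6 summation over the equivalent partners before the effective distance
is taken.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Conformer, dihedral

AtomSpec = int | str | tuple


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients (Hz) and phase of a Karplus curve, theta = phi + offset."""

    A: float
    B: float
    C: float
    theta_offset: float = 0.0


#: named coefficient sets; the HN-HA set (Vuister & Bax) is the package default
KARPLUS_PRESETS: dict[str, KarplusParams] = {
    "vuister_bax_hn_ha": KarplusParams(6.51, -1.76, 1.60, -60.0),
    "pachler_ha_hb": KarplusParams(9.5, -1.6, 1.8, 0.0),
}

DEFAULT_KARPLUS = KARPLUS_PRESETS["vuister_bax_hn_ha"]

J_COLUMNS = [
    "residue",
    "j_hz",
    "tolerance_hz",
    "atom_1",
    "atom_2",
    "atom_3",
    "atom_4",
    "karplus",
]


@dataclass(frozen=True)
class JRestraint:
    """One measured vicinal coupling tied to a dihedral-defining atom quadruple.

    ``phi_atoms`` are atom names (or indices) i-j-k-l whose dihedral enters
    the Karplus curve; ``karplus=None`` means the caller's default set.
    """

    residue: str
    j_exp: float
    tolerance: float
    phi_atoms: tuple
    karplus: KarplusParams | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if len(self.phi_atoms) != 4:
            raise ValueError("phi_atoms must hold four atoms")


def _resolve_atom(conformer: Conformer, spec: AtomSpec) -> tuple[int, ...]:
    """Resolve an atom spec (index, name, or tuple of either for degenerate
    groups) into a tuple of 0-based indices."""
    if isinstance(spec, tuple):
        return tuple(i for s in spec for i in _resolve_atom(conformer, s))
    if isinstance(spec, (int, np.integer)):
        idx = int(spec)
        if not 0 <= idx < conformer.n_atoms:
            raise IndexError(f"atom index {idx} out of range")
        return (idx,)
    return (conformer.atom_index(str(spec)),)


def check_weights(weights: Sequence[float], n: int, tol: float = 1e-8) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < -tol):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 (got {w.sum()})")
    return np.clip(w, 0.0, None)


def pair_r6(conformer: Conformer, atom_i: AtomSpec, atom_j: AtomSpec) -> float:
    """Sum of r^-6 over all proton pairs between the two (possibly
    degenerate) atom groups."""
    gi = _resolve_atom(conformer, atom_i)
    gj = _resolve_atom(conformer, atom_j)
    total = 0.0
    for a in gi:
        for b in gj:
            if a == b:
                raise ValueError("distance requires two distinct atoms")
            d = float(np.linalg.norm(conformer.coords[a] - conformer.coords[b]))
            if d < 1e-6:
                raise ValueError(
                    f"zero inter-atomic distance for atoms {a},{b} "
                    f"in conformer {conformer.id!r}"
                )
            total += d ** -6
    return total


def pair_distance(conformer: Conformer, atom_i: AtomSpec, atom_j: AtomSpec) -> float:
    """Effective single-conformer distance: (sum r^-6)^(-1/6)."""
    return pair_r6(conformer, atom_i, atom_j) ** (-1.0 / 6.0)


def ensemble_distance(
    pool: Sequence[Conformer],
    weights: Sequence[float],
    atom_i: AtomSpec,
    atom_j: AtomSpec,
    power: int = 6,
) -> float:
    """Population-averaged effective distance ``(sum_i w_i r_i^-p)^(-1/p)``.

    ``power=6`` (default) is the slow-motion NOE average; ``power=3`` the
    fast-motion alternative.
    """
    w = check_weights(weights, len(pool))
    if power == 6:
        vals = np.array([pair_r6(c, atom_i, atom_j) for c in pool])
    else:
        vals = np.array(
            [pair_distance(c, atom_i, atom_j) ** (-power) for c in pool]
        )
    return float(np.dot(w, vals) ** (-1.0 / power))


def karplus_j(phi_deg: float, p: KarplusParams = DEFAULT_KARPLUS) -> float:
    """Karplus coupling (Hz) for dihedral ``phi_deg`` (degrees)."""
    theta = np.radians(phi_deg + p.theta_offset)
    c = np.cos(theta)
    return float(p.A * c * c + p.B * c + p.C)


def conformer_j(
    conformer: Conformer, jr: JRestraint, default: KarplusParams = DEFAULT_KARPLUS
) -> float:
    """Back-calculated coupling of a single conformer for one restraint."""
    idx = [_resolve_atom(conformer, a) for a in jr.phi_atoms]
    if any(len(g) != 1 for g in idx):
        raise ValueError("J dihedral atoms must be single atoms")
    phi = dihedral(conformer, idx[0][0], idx[1][0], idx[2][0], idx[3][0])
    return karplus_j(phi, jr.karplus or default)


def ensemble_j(
    pool: Sequence[Conformer],
    weights: Sequence[float],
    jr: JRestraint,
    p: KarplusParams = DEFAULT_KARPLUS,
) -> float:
    """Linear population average of the back-calculated coupling."""
    w = check_weights(weights, len(pool))
    vals = np.array([conformer_j(c, jr, p) for c in pool])
    return float(np.dot(w, vals))


def read_j_table(path_or_df) -> list[JRestraint]:
    """Read a J-coupling table CSV into restraints.

    Expected columns: residue, j_hz, tolerance_hz, atom_1..atom_4, and an
    optional ``karplus`` preset name.
    """
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    out = []
    for row in df.itertuples(index=False):
        preset = getattr(row, "karplus", None)
        kp = KARPLUS_PRESETS[preset] if isinstance(preset, str) and preset else None
        out.append(
            JRestraint(
                residue=str(row.residue),
                j_exp=float(row.j_hz),
                tolerance=float(row.tolerance_hz),
                phi_atoms=(
                    str(row.atom_1),
                    str(row.atom_2),
                    str(row.atom_3),
                    str(row.atom_4),
                ),
                karplus=kp,
            )
        )
    return out
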