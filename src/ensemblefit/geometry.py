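"""Coordinate-level primitives: superposition, RMSD, dihedral angles, selections.

Conventions used throughout the package:

* atom indexing is 0-based; PDB serial numbers survive only as labels;
* dihedrals follow the IUPAC sign convention (positive = clockwise rotation
  of the far bond when sighting along the central j->k bond), reported in
  degrees on the half-open interval (-180, +180];
* RMSD is evaluated after optimal least-squares (Kabsch) superposition and
  may be mass-weighted, matching the similarity criterion used for
  macrocycle clustering.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class Atom(NamedTuple):
    """One atom of a conformer: ``name`` must be unique within the molecule
    for name-based lookups to work; ``mass`` in amu."""

    name: str
    element: str
    mass: float
    residue_index: int


@dataclass(frozen=True)
class Conformer:
    """One geometry of the molecule.

    Parameters
    ----------
    id : str
        Free-form identifier (e.g. ``"conf_007"``).
    atoms : tuple of Atom
        Topology shared by every conformer of a pool (same names, order).
    coords : (N, 3) ndarray
        Cartesian coordinates in Angstrom.
    """

    id: str
    atoms: tuple[Atom, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] != len(atoms):
            raise ValueError(
                f"{len(atoms)} atoms but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if any(a.mass <= 0 for a in atoms):
            raise ValueError("atom masses must be positive")
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def atom_index(self, name: str) -> int:
        """Index of the (unique) atom called ``name``."""
        hits = [i for i, a in enumerate(self.atoms) if a.name == name]
        if not hits:
            raise KeyError(f"no atom named {name!r} in conformer {self.id!r}")
        if len(hits) > 1:
            raise KeyError(f"atom name {name!r} is not unique in {self.id!r}")
        return hits[0]

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Conformer":
        return Conformer(id if id is not None else self.id, self.atoms, coords)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, duplicate-free 0-based atom indices with a label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate_for(self, conformer: Conformer) -> None:
        if self.indices and max(self.indices) >= conformer.n_atoms:
            raise IndexError(
                f"selection {self.label!r} exceeds {conformer.n_atoms} atoms"
            )

    @classmethod
    def from_names(
        cls, conformer: Conformer, names: Iterable[str], label: str = ""
    ) -> "AtomSelection":
        return cls(tuple(conformer.atom_index(n) for n in names), label)

    @classmethod
    def all_atoms(cls, conformer: Conformer, label: str = "all") -> "AtomSelection":
        return cls(tuple(range(conformer.n_atoms)), label)

    @classmethod
    def heavy_atoms(cls, conformer: Conformer, label: str = "heavy") -> "AtomSelection":
        return cls(
            tuple(i for i, a in enumerate(conformer.atoms) if a.element != "H"),
            label,
        )


class Superposition(NamedTuple):
    """Result of a least-squares fit: aligned = coords @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def same_topology(a: Conformer, b: Conformer) -> bool:
    return a.atoms == b.atoms


def _fit_weights(
    conformer: Conformer, sel: AtomSelection | None, mass_weighted: bool
) -> tuple[np.ndarray, np.ndarray]:
    if sel is None:
        sel = AtomSelection.all_atoms(conformer)
    sel.validate_for(conformer)
    idx = np.array(sel.indices, dtype=int)
    if len(idx) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    if mass_weighted:
        w = conformer.masses[idx]
    else:
        w = np.ones(len(idx))
    return idx, w


def _check_not_degenerate(points: np.ndarray) -> None:
    # collinear/coincident selections leave the rotation undetermined
    s = np.linalg.svd(points, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) atom selection")


def superpose(
    mobile: Conformer,
    target: Conformer,
    sel: AtomSelection | None = None,
    mass_weighted: bool = False,
) -> Superposition:
    """Optimal least-squares superposition of ``mobile`` onto ``target``.

    Uses the Kabsch algorithm (SVD form); the returned rotation is always
    proper (det = +1), so mirror images are *not* matched.  The RMSD is
    computed over the selection, mass-weighted if requested:
    ``sqrt(sum(w_i d_i^2) / sum(w_i))``.
    """
    if not same_topology(mobile, target):
        raise ValueError("conformers do not share an atom list")
    idx, w = _fit_weights(mobile, sel, mass_weighted)
    m = mobile.coords[idx]
    t = target.coords[idx]
    m_cent = np.average(m, axis=0, weights=w)
    t_cent = np.average(t, axis=0, weights=w)
    mc = m - m_cent
    tc = t - t_cent
    _check_not_degenerate(tc)
    _check_not_degenerate(mc)
    rot, rssd = Rotation.align_vectors(tc, mc, weights=w)
    R = rot.as_matrix()
    rmsd_val = float(rssd / np.sqrt(w.sum()))
    translation = t_cent - R @ m_cent
    return Superposition(R, translation, rmsd_val)


def rmsd(
    a: Conformer,
    b: Conformer,
    sel: AtomSelection | None = None,
    mass_weighted: bool = False,
) -> float:
    """Post-superposition (optionally mass-weighted) RMSD in Angstrom."""
    return superpose(a, b, sel=sel, mass_weighted=mass_weighted).rmsd


def dihedral_from_coords(
    xi: np.ndarray, xj: np.ndarray, xk: np.ndarray, xl: np.ndarray
) -> float:
    """Signed IUPAC dihedral i-j-k-l in degrees, in (-180, 180]."""
    b0 = np.asarray(xi, float) - np.asarray(xj, float)
    b1 = np.asarray(xk, float) - np.asarray(xj, float)
    b2 = np.asarray(xl, float) - np.asarray(xk, float)
    n1 = np.linalg.norm(b1)
    if np.linalg.norm(b0) < 1e-8 or n1 < 1e-8 or np.linalg.norm(b2) < 1e-8:
        raise ValueError("coincident atoms in dihedral")
    b1 = b1 / n1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-8 or np.linalg.norm(w) < 1e-8:
        raise ValueError("collinear atoms in dihedral")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral(c: Conformer, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle (degrees) over four distinct atom indices."""
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct atom indices")
    for idx in (i, j, k, l):
        if not 0 <= idx < c.n_atoms:
            raise IndexError(f"atom index {idx} out of range")
    return dihedral_from_coords(
        c.coords[i], c.coords[j], c.coords[k], c.coords[l]
    )
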