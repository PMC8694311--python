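"""Multi-model PDB input/output for conformer pools.

Coordinates go through Biopython's PDB machinery; per-model scalar
annotations (conformer id, force-field energy, fitted weight), which the PDB
format has no standard slot for, are carried on ``REMARK 250`` header lines
of the form::

    REMARK 250 CONFORMER <model#> ID <id> [ENERGY <kJ/mol>] [WEIGHT <fraction>]

Files written by other programs simply come back with ``energy=None``.
"""
from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.StructureBuilder import StructureBuilder

from .geometry import Atom, Conformer

_REMARK_TAG = "REMARK 250 CONFORMER"


def element_mass(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    key = element.capitalize()
    if key not in atom_weights:
        raise KeyError(f"unknown element {element!r}")
    return float(atom_weights[key])


def _parse_remarks(path: Path) -> dict[int, dict[str, str]]:
    notes: dict[int, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(_REMARK_TAG):
                continue
            tokens = line.split()[3:]  # after "REMARK 250 CONFORMER"
            if not tokens:
                continue
            model = int(tokens[0])
            fields = dict(zip(tokens[1::2], tokens[2::2]))
            notes[model] = fields
    return notes


def read_pdb_models(path: str | Path) -> list[dict]:
    """Read a (multi-model) PDB file.

    Returns one record per MODEL: ``{"conformer": Conformer,
    "energy": float | None, "weight": float | None}``.  Atom ordering
    follows file order; masses come from the element symbol.
    """
    path = Path(path)
    notes = _parse_remarks(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    records: list[dict] = []
    for n, model in enumerate(structure, start=1):
        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    elem = (atom.element or atom.get_name()[0]).strip().upper()
                    atoms.append(
                        Atom(
                            name=atom.get_name(),
                            element=elem,
                            mass=element_mass(elem),
                            residue_index=residue.id[1],
                        )
                    )
                    coords.append(atom.get_coord())
        fields = notes.get(n, {})
        cid = fields.get("ID", f"model_{n}")
        energy = float(fields["ENERGY"]) if "ENERGY" in fields else None
        weight = float(fields["WEIGHT"]) if "WEIGHT" in fields else None
        records.append(
            {
                "conformer": Conformer(cid, tuple(atoms), np.array(coords, float)),
                "energy": energy,
                "weight": weight,
            }
        )
    return records


def read_conformers(path: str | Path) -> list[Conformer]:
    """Convenience wrapper: just the conformers, annotations dropped."""
    return [rec["conformer"] for rec in read_pdb_models(path)]


def _atom_fullname(name: str) -> str:
    # PDB column alignment: short names start in column 14
    return name if len(name) >= 4 else f" {name:<3s}"


def write_pdb_models(
    path: str | Path,
    conformers: Sequence[Conformer],
    energies: Sequence[float] | None = None,
    weights: Sequence[float] | None = None,
) -> None:
    """Write conformers as a multi-model PDB with REMARK 250 annotations."""
    if energies is not None and len(energies) != len(conformers):
        raise ValueError("energies length mismatch")
    if weights is not None and len(weights) != len(conformers):
        raise ValueError("weights length mismatch")
    builder = StructureBuilder()
    builder.init_structure("pool")
    for m, conf in enumerate(conformers):
        builder.init_model(m)
        builder.init_chain("A")
        builder.init_seg(" ")
        serial = 1
        current_res: int | None = None
        for atom, xyz in zip(conf.atoms, conf.coords):
            if atom.residue_index != current_res:
                builder.init_residue("UNK", " ", atom.residue_index, " ")
                current_res = atom.residue_index
            builder.init_atom(
                atom.name,
                np.asarray(xyz, dtype=np.float32),
                0.0,
                1.0,
                " ",
                _atom_fullname(atom.name),
                serial,
                element=atom.element,
            )
            serial += 1
    pdb_io = PDBIO()
    pdb_io.set_structure(builder.get_structure())
    buf = _io.StringIO()
    pdb_io.save(buf)
    with open(path, "w") as fh:
        for m, conf in enumerate(conformers, start=1):
            line = f"{_REMARK_TAG} {m} ID {conf.id}"
            if energies is not None:
                line += f" ENERGY {energies[m - 1]:.4f}"
            if weights is not None:
                line += f" WEIGHT {weights[m - 1]:.6f}"
            fh.write(line + "\n")
        fh.write(buf.getvalue())
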