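"""Conformer-pool hygiene: merging, energy-window filtering, deduplication.

Pools typically arrive as the union of several conformational searches.
Standard clean-up keeps everything within an energy window of the global
minimum (42 kJ/mol by convention here, boundary inclusive) and then removes
geometric redundancy with a greedy RMSD scan: entries are visited in
priority order (energy-sorted when energies exist, otherwise input order)
and dropped when within the cutoff (2.0 A default) of an already-retained
entry.  The greedy rule guarantees that every dropped entry is within the
cutoff of some survivor; it does *not* guarantee that all survivor pairs
are farther apart than the cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import AtomSelection, Conformer, rmsd
from . import pdbio


@dataclass(frozen=True)
class PoolEntry:
    conformer: Conformer
    energy: float | None = None  # kJ/mol, relative scale is arbitrary
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("energy must be finite when present")


def merge_pools(*pools: Sequence[PoolEntry]) -> list[PoolEntry]:
    """Concatenate pools from several searches, preserving order."""
    out: list[PoolEntry] = []
    for p in pools:
        out.extend(p)
    return out


def energy_filter(
    entries: Sequence[PoolEntry], window: float = 42.0
) -> list[PoolEntry]:
    """Keep entries within ``window`` kJ/mol of the global minimum (inclusive).

    Shift-invariant: only energies relative to the minimum matter.
    """
    entries = list(entries)
    if not entries:
        return []
    if any(e.energy is None for e in entries):
        raise ValueError("energy_filter requires every entry to carry an energy")
    e_min = min(e.energy for e in entries)
    return [e for e in entries if e.energy - e_min <= window]


def deduplicate(
    entries: Sequence[PoolEntry],
    sel: AtomSelection | None = None,
    rmsd_cutoff: float = 2.0,
    mass_weighted: bool = False,
    superposed: bool = True,
    sort_by_energy: bool = True,
) -> list[PoolEntry]:
    """Greedy redundancy elimination at an RMSD cutoff.

    Entries are visited lowest-energy-first when all energies are present
    and ``sort_by_energy`` (stable sort, so ties keep input order),
    otherwise in input order; an entry is dropped iff it lies within
    ``rmsd_cutoff`` of an already-retained entry.  Idempotent.
    ``superposed=False`` compares coordinates in place (no fit), for pools
    that are already pre-aligned.
    """
    entries = list(entries)
    if not entries:
        return []
    order = list(range(len(entries)))
    if sort_by_energy and all(e.energy is not None for e in entries):
        order.sort(key=lambda i: entries[i].energy)
    kept: list[int] = []
    for i in order:
        ci = entries[i].conformer
        redundant = False
        for j in kept:
            cj = entries[j].conformer
            if superposed:
                d = rmsd(ci, cj, sel=sel, mass_weighted=mass_weighted)
            else:
                idx = np.asarray(sel.indices) if sel is not None else slice(None)
                diff = ci.coords[idx] - cj.coords[idx]
                d = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
            if d <= rmsd_cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(i)
    kept.sort()  # report survivors in input order
    return [entries[i] for i in kept]


def clean_pool(
    entries: Sequence[PoolEntry],
    window: float = 42.0,
    sel: AtomSelection | None = None,
    rmsd_cutoff: float = 2.0,
    **dedup_kwargs,
) -> list[PoolEntry]:
    """Fixed pipeline order: energy filter first, then deduplication."""
    return deduplicate(
        energy_filter(entries, window=window),
        sel=sel,
        rmsd_cutoff=rmsd_cutoff,
        **dedup_kwargs,
    )


def load_pool(path: str | Path, source_tag: str = "") -> list[PoolEntry]:
    """Read a multi-model PDB pool (per-model energies from REMARK 250)."""
    tag = source_tag or Path(path).name
    return [
        PoolEntry(rec["conformer"], rec["energy"], tag)
        for rec in pdbio.read_pdb_models(path)
    ]


def save_pool(path: str | Path, entries: Sequence[PoolEntry]) -> None:
    confs = [e.conformer for e in entries]
    energies = (
        [e.energy for e in entries]
        if all(e.energy is not None for e in entries)
        else None
    )
    pdbio.write_pdb_models(path, confs, energies=energies)
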