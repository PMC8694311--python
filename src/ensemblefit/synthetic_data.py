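"""Synthetic study generator: conformer pools, planted ensembles, NMR tables.

Everything the deconvolution workflow consumes can be generated here with a
known ground truth:

* ``generate_pool`` builds macrocyclic-peptide-like conformers from a
  hard-coded 31-atom, four-residue cyclic-peptide template (ideal bond
  lengths/angles, torsion-driven NeRF rebuilding, steric-clash rejection at
  1.5 A for atoms more than two bonds apart).  The template includes a
  geminal methylene proton pair (HB2/HB3) whose separation is fixed at
  1.78 A by construction -- the internal distance reference.  Ring closure
  of the lactam bridge is notional: conformers are rebuilt as an open chain
  whose torsions sample peptide backbone basins, which is sufficient for
  exercising the inference machinery.
* ``simulate_noesy`` runs the buildup equations in reverse: cross peaks
  grow linearly with mixing time at a rate proportional to the
  population-averaged <r^-6> of the planted ensemble, diagonals stay
  constant, multiplicative uniform noise optional.  The default mixing-time
  schedule is 100-700 ms in 100 ms steps.
* ``simulate_j`` population-averages the Karplus curve over the planted
  ensemble with optional additive Gaussian noise.

All outputs are pure functions of (seed, scenario).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Atom, Conformer
from .noe_pipeline import calibrate_peak_table
from .observables import (
    KARPLUS_PRESETS,
    JRestraint,
    conformer_j,
    pair_r6,
)

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: template torsion values (degrees); PPII-like backbone, staggered chis
TEMPLATE_TORSIONS: dict[str, float] = {
    "psi1": 145.0,
    "phi2": -75.0,
    "psi2": 145.0,
    "chi2": -60.0,
    "phi3": -75.0,
    "psi3": 145.0,
    "phi4": -75.0,
    "chi4": -60.0,
    "psi4": 145.0,
}

ROTATABLE = tuple(TEMPLATE_TORSIONS)

# z-matrix rows: (name, element, residue, (a, b, c) reference names,
#                 bond A, angle deg, torsion_param|None, offset deg, chiral)
# the torsion is dihedral(a, b, c, new) = torsions[param] + offset
# (offset sign flips with molecular chirality when ``chiral``)
_ZMATRIX = [
    ("HA1", "H", 1, ("C1", "N1", "CA1"), 1.090, 109.5, None, 120.0, False),
    ("O1", "O", 1, ("N1", "CA1", "C1"), 1.231, 120.5, "psi1", 180.0, False),
    ("N2", "N", 2, ("N1", "CA1", "C1"), 1.329, 116.6, "psi1", 0.0, False),
    ("CA2", "C", 2, ("CA1", "C1", "N2"), 1.458, 121.7, None, 180.0, False),
    ("H2", "H", 2, ("CA1", "C1", "N2"), 1.010, 119.0, None, 0.0, False),
    ("C2", "C", 2, ("C1", "N2", "CA2"), 1.525, 111.0, "phi2", 0.0, False),
    ("HA2", "H", 2, ("C1", "N2", "CA2"), 1.090, 109.5, "phi2", 120.0, True),
    ("CB2", "C", 2, ("C1", "N2", "CA2"), 1.530, 109.5, "phi2", -120.0, True),
    ("CG2", "C", 2, ("N2", "CA2", "CB2"), 1.530, 112.0, "chi2", 0.0, False),
    ("HB2", "H", 2, ("N2", "CA2", "CB2"), 1.090, 109.4712, "chi2", 120.0, False),
    ("HB3", "H", 2, ("N2", "CA2", "CB2"), 1.090, 109.4712, "chi2", -120.0, False),
    ("O2", "O", 2, ("N2", "CA2", "C2"), 1.231, 120.5, "psi2", 180.0, False),
    ("N3", "N", 3, ("N2", "CA2", "C2"), 1.329, 116.6, "psi2", 0.0, False),
    ("CA3", "C", 3, ("CA2", "C2", "N3"), 1.458, 121.7, None, 180.0, False),
    ("H3", "H", 3, ("CA2", "C2", "N3"), 1.010, 119.0, None, 0.0, False),
    ("C3", "C", 3, ("C2", "N3", "CA3"), 1.525, 111.0, "phi3", 0.0, False),
    ("HA3", "H", 3, ("C2", "N3", "CA3"), 1.090, 109.5, "phi3", 120.0, False),
    ("O3", "O", 3, ("N3", "CA3", "C3"), 1.231, 120.5, "psi3", 180.0, False),
    ("N4", "N", 4, ("N3", "CA3", "C3"), 1.329, 116.6, "psi3", 0.0, False),
    ("CA4", "C", 4, ("CA3", "C3", "N4"), 1.458, 121.7, None, 180.0, False),
    ("H4", "H", 4, ("CA3", "C3", "N4"), 1.010, 119.0, None, 0.0, False),
    ("C4", "C", 4, ("C3", "N4", "CA4"), 1.525, 111.0, "phi4", 0.0, False),
    ("HA4", "H", 4, ("C3", "N4", "CA4"), 1.090, 109.5, "phi4", 120.0, False),
    ("CB4", "C", 4, ("C3", "N4", "CA4"), 1.530, 109.5, "phi4", -120.0, False),
    ("CG4", "C", 4, ("N4", "CA4", "CB4"), 1.530, 112.0, "chi4", 0.0, False),
    ("HB41", "H", 4, ("N4", "CA4", "CB4"), 1.090, 109.4712, "chi4", 120.0, False),
    ("HB42", "H", 4, ("N4", "CA4", "CB4"), 1.090, 109.4712, "chi4", -120.0, False),
    ("O4", "O", 4, ("N4", "CA4", "C4"), 1.231, 120.5, "psi4", 180.0, False),
]

#: proton pairs instrumented in the simulated NOESY experiment
DEFAULT_NOE_PAIRS: tuple[tuple[str, str], ...] = (
    ("H2", "HA1"),
    ("H2", "HA2"),
    ("H3", "HA2"),
    ("H3", "HA3"),
    ("H4", "HA3"),
    ("H4", "HA4"),
    ("H2", "H3"),
    ("H3", "H4"),
    ("HA2", "HB2"),
    ("HA2", "HB3"),
    ("HA4", "HB41"),
    ("H2", "H4"),
)

REFERENCE_PAIR: tuple[str, str] = ("HB2", "HB3")

#: simulated vicinal couplings: three backbone HN-HA plus one chi1-type
DEFAULT_J_DEFS: tuple[dict, ...] = (
    {"residue": "2", "atoms": ("C1", "N2", "CA2", "C2"),
     "karplus": "vuister_bax_hn_ha", "tolerance": 0.5},
    {"residue": "3", "atoms": ("C2", "N3", "CA3", "C3"),
     "karplus": "vuister_bax_hn_ha", "tolerance": 0.5},
    {"residue": "4", "atoms": ("C3", "N4", "CA4", "C4"),
     "karplus": "vuister_bax_hn_ha", "tolerance": 0.5},
    {"residue": "2chi", "atoms": ("HA2", "CA2", "CB2", "HB2"),
     "karplus": "pachler_ha_hb", "tolerance": 0.5},
)

#: (phi, psi) backbone basins the pool sampler draws from
BACKBONE_BASINS = ((-75.0, 145.0), (-65.0, -40.0), (-140.0, 135.0), (60.0, 45.0))
CHI_BASINS = (-60.0, 60.0, 180.0)


def _nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d bonded to c with angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= norm_n
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_conformer(
    torsions: dict[str, float] | None = None,
    chirality: int = 1,
    cid: str = "template",
) -> Conformer:
    """Rebuild the template at the given torsion values.

    ``chirality=+1`` is the parent stereochemistry at residue 2;
    ``chirality=-1`` builds the epimer (HA2/CB2 swapped about the backbone).
    """
    if chirality not in (1, -1):
        raise ValueError("chirality must be +1 or -1")
    vals = dict(TEMPLATE_TORSIONS)
    if torsions:
        unknown = set(torsions) - set(vals)
        if unknown:
            raise KeyError(f"unknown torsions {sorted(unknown)}")
        vals.update(torsions)

    coords: dict[str, np.ndarray] = {}
    atoms: list[Atom] = []

    def add(name, elem, resid, xyz):
        coords[name] = np.asarray(xyz, dtype=float)
        atoms.append(Atom(name, elem, _MASSES[elem], resid))

    # seed triple in the xy-plane
    add("N1", "N", 1, (0.0, 0.0, 0.0))
    add("CA1", "C", 1, (1.458, 0.0, 0.0))
    ang = np.radians(111.0)
    add("C1", "C", 1, (1.458 - 1.525 * np.cos(ang), 1.525 * np.sin(ang), 0.0))
    for name, elem, resid, (a, b, c), bond, angle, param, offset, chiral in _ZMATRIX:
        base = vals[param] if param is not None else 0.0
        off = offset * (chirality if chiral else 1)
        xyz = _nerf_place(coords[a], coords[b], coords[c], bond, angle, base + off)
        add(name, elem, resid, xyz)
    return Conformer(cid, tuple(atoms), np.array([coords[a.name] for a in atoms]))


def _bond_graph() -> dict[str, set[str]]:
    graph: dict[str, set[str]] = {"N1": set(), "CA1": set(), "C1": set()}
    for pair in (("N1", "CA1"), ("CA1", "C1")):
        graph[pair[0]].add(pair[1])
        graph[pair[1]].add(pair[0])
    for name, _, _, (_, _, c), *_rest in _ZMATRIX:
        graph.setdefault(name, set())
        graph[name].add(c)
        graph[c].add(name)
    return graph


def _nonbonded_pairs() -> list[tuple[int, int]]:
    """Atom-index pairs more than two bonds apart (the clash-check set)."""
    graph = _bond_graph()
    names = ["N1", "CA1", "C1"] + [row[0] for row in _ZMATRIX]
    # BFS distances per atom over the small bond tree
    dist: dict[str, dict[str, int]] = {}
    for src in names:
        d = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph[u]:
                    if v not in d:
                        d[v] = d[u] + 1
                        nxt.append(v)
            frontier = nxt
        dist[src] = d
    idx = {n: i for i, n in enumerate(names)}
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if dist[a].get(b, 99) > 2:
                pairs.append((idx[a], idx[b]))
    return pairs


_NONBONDED = _nonbonded_pairs()


def clash_free(conformer: Conformer, cutoff: float = 1.5) -> bool:
    """True when all atom pairs more than two bonds apart are >= cutoff."""
    xyz = conformer.coords
    for i, j in _NONBONDED:
        if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
            return False
    return True


def _sample_torsions(rng: np.random.Generator, jitter: float) -> dict[str, float]:
    vals: dict[str, float] = {}
    phi_psi = {}
    for r in (2, 3, 4):
        basin = BACKBONE_BASINS[rng.integers(len(BACKBONE_BASINS))]
        phi_psi[r] = basin
    vals["psi1"] = float(
        BACKBONE_BASINS[rng.integers(len(BACKBONE_BASINS))][1] + rng.normal(0, jitter)
    )
    for r in (2, 3, 4):
        phi, psi = phi_psi[r]
        vals[f"phi{r}"] = float(phi + rng.normal(0, jitter))
        vals[f"psi{r}"] = float(psi + rng.normal(0, jitter))
    for name in ("chi2", "chi4"):
        vals[name] = float(
            CHI_BASINS[rng.integers(len(CHI_BASINS))] + rng.normal(0, jitter)
        )
    return vals


def generate_pool(
    seed,
    n: int,
    chirality: int = 1,
    jitter: float = 12.0,
    clash_cutoff: float = 1.5,
    max_tries: int = 500,
) -> list[Conformer]:
    """Deterministic pool of ``n`` clash-free conformers; the first one is
    the unperturbed template."""
    if n < 1:
        raise ValueError("pool size must be >= 1")
    rng = np.random.default_rng(seed)
    pool = [build_conformer(chirality=chirality, cid="conf_000")]
    while len(pool) < n:
        for _ in range(max_tries):
            vals = _sample_torsions(rng, jitter)
            conf = build_conformer(vals, chirality=chirality,
                                   cid=f"conf_{len(pool):03d}")
            if clash_free(conf, clash_cutoff):
                pool.append(conf)
                break
        else:
            raise RuntimeError("could not generate a clash-free conformer")
    return pool


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic experiment.

    Defaults mirror the experimental design the package targets: a pool of
    20 conformers, a sparse planted ensemble of four members at
    40/30/20/10%, mixing times 100-700 ms, geminal methylene reference at
    1.78 A.  ``noise_noe`` is the multiplicative uniform half-width on peak
    intensities; ``noise_j`` the Gaussian sigma (Hz) on couplings.
    """

    seed: int = 0
    pool_size: int = 20
    true_weights: tuple[float, ...] = (0.40, 0.30, 0.20, 0.10)
    noise_noe: float = 0.0
    noise_j: float = 0.0
    t_mix_ms: tuple[float, ...] = (100, 200, 300, 400, 500, 600, 700)
    reference_pair: tuple[str, str] = REFERENCE_PAIR
    r_ref: float = 1.78
    sigma_ref: float = 0.3  # buildup rate scale of the reference pair, s^-1
    diagonal: float = 1.0e5  # constant diagonal-peak intensity
    chirality: int = 1
    noe_pairs: tuple[tuple[str, str], ...] = DEFAULT_NOE_PAIRS
    j_defs: tuple[dict, ...] = DEFAULT_J_DEFS

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true_weights must lie on the simplex")
        if len(self.true_weights) > self.pool_size:
            raise ValueError("more true members than pool conformers")
        if len(self.t_mix_ms) < 3:
            raise ValueError("mixing-time schedule needs >= 3 points")


@dataclass
class SyntheticRealization:
    """One drawn data set: pool, planted truth, and simulated tables."""

    scenario: SyntheticScenario
    pool: list[Conformer]
    truth: dict
    peaks: pd.DataFrame
    jtable: pd.DataFrame


def plant_truth(scenario: SyntheticScenario, pool: Sequence[Conformer], rng) -> dict:
    idx = rng.choice(scenario.pool_size, size=len(scenario.true_weights),
                     replace=False)
    member_ids = [pool[int(i)].id for i in idx]
    bio = member_ids[2] if len(member_ids) > 2 else member_ids[0]
    return {
        "member_indices": [int(i) for i in idx],
        "member_ids": member_ids,
        "weights": list(scenario.true_weights),
        "bioactive_id": bio,
    }


def true_weight_vector(truth: dict, pool: Sequence[Conformer]) -> np.ndarray:
    w = np.zeros(len(pool))
    for i, wt in zip(truth["member_indices"], truth["weights"]):
        w[i] = wt
    return w


def _ensemble_r6(pool, truth, atom_i, atom_j) -> float:
    return sum(
        wt * pair_r6(pool[i], atom_i, atom_j)
        for i, wt in zip(truth["member_indices"], truth["weights"])
    )


def simulate_noesy(
    scenario: SyntheticScenario,
    pool: Sequence[Conformer],
    truth: dict,
    rng,
) -> pd.DataFrame:
    """Peak table with cross peaks growing linearly at sigma ~ <r^-6>.

    The rate constant is fixed by forcing the reference pair (at its
    construction distance) to ``sigma_ref``; diagonals are constant so the
    linear-buildup model is exact at zero noise.
    """
    ref_i, ref_j = scenario.reference_pair
    c_scale = scenario.sigma_ref / _ensemble_r6(pool, truth, ref_i, ref_j)
    rows = []
    for atom_i, atom_j in tuple(scenario.noe_pairs) + (scenario.reference_pair,):
        sigma = c_scale * _ensemble_r6(pool, truth, atom_i, atom_j)
        pair_id = f"{atom_i}-{atom_j}"
        for t in scenario.t_mix_ms:
            eta = sigma * (t / 1000.0)
            eps1 = rng.uniform(-scenario.noise_noe, scenario.noise_noe)
            eps2 = rng.uniform(-scenario.noise_noe, scenario.noise_noe)
            rows.append(
                {
                    "pair_id": pair_id,
                    "atom_i": atom_i,
                    "atom_j": atom_j,
                    "t_mix_ms": float(t),
                    "cross_1": scenario.diagonal * eta * (1.0 + eps1),
                    "cross_2": scenario.diagonal * eta * (1.0 + eps2),
                    "diag_1": scenario.diagonal,
                    "diag_2": scenario.diagonal,
                }
            )
    return pd.DataFrame(rows)


def simulate_j(
    scenario: SyntheticScenario,
    pool: Sequence[Conformer],
    truth: dict,
    rng,
) -> pd.DataFrame:
    """J table: linear population average of the Karplus curve + noise."""
    rows = []
    for jd in scenario.j_defs:
        # j_exp unused here: the restraint object only routes atoms + Karplus set
        jr = JRestraint(
            residue=jd["residue"],
            j_exp=0.0,
            tolerance=jd["tolerance"],
            phi_atoms=tuple(jd["atoms"]),
            karplus=KARPLUS_PRESETS[jd["karplus"]],
        )
        j_true = sum(
            wt * conformer_j(pool[i], jr)
            for i, wt in zip(truth["member_indices"], truth["weights"])
        )
        j_obs = j_true + rng.normal(0.0, scenario.noise_j)
        rows.append(
            {
                "residue": jd["residue"],
                "j_hz": float(j_obs),
                "tolerance_hz": jd["tolerance"],
                "atom_1": jd["atoms"][0],
                "atom_2": jd["atoms"][1],
                "atom_3": jd["atoms"][2],
                "atom_4": jd["atoms"][3],
                "karplus": jd["karplus"],
            }
        )
    return pd.DataFrame(rows)


def realize(scenario: SyntheticScenario) -> SyntheticRealization:
    """Draw one complete synthetic data set from the scenario seed."""
    ss = np.random.SeedSequence(scenario.seed)
    s_pool, s_truth, s_noe, s_j = ss.spawn(4)
    pool = generate_pool(s_pool, scenario.pool_size, chirality=scenario.chirality)
    truth = plant_truth(scenario, pool, np.random.default_rng(s_truth))
    peaks = simulate_noesy(scenario, pool, truth, np.random.default_rng(s_noe))
    jtable = simulate_j(scenario, pool, truth, np.random.default_rng(s_j))
    return SyntheticRealization(scenario, pool, truth, peaks, jtable)


def restraints_from_realization(real: SyntheticRealization):
    """Calibrate the simulated tables into fit-ready restraints."""
    from .observables import read_j_table

    sc = real.scenario
    ref_pair = f"{sc.reference_pair[0]}-{sc.reference_pair[1]}"
    _, distance_restraints = calibrate_peak_table(
        real.peaks, ref_pair=ref_pair, r_ref=sc.r_ref
    )
    j_restraints = read_j_table(real.jtable)
    return distance_restraints, j_restraints


def generate_clustered_set(
    seed,
    n_groups: int = 3,
    per_group: int = 10,
    jitter_sd: float = 0.25,
    min_base_rmsd: float = 2.0,
) -> tuple[list[Conformer], np.ndarray]:
    """Planted-partition conformer set: tight groups around distant bases.

    Returns the conformers (group-major order) and the true group label per
    conformer.  Intra-group RMSDs land well under 0.7 A, inter-group well
    above ``min_base_rmsd``.
    """
    from .geometry import rmsd as _rmsd

    rng = np.random.default_rng(seed)
    candidates = generate_pool(rng.integers(2**31 - 1), 8 * n_groups)
    bases: list[Conformer] = []
    for cand in candidates:
        if all(_rmsd(cand, b) > min_base_rmsd for b in bases):
            bases.append(cand)
        if len(bases) == n_groups:
            break
    if len(bases) < n_groups:
        raise RuntimeError("could not find enough mutually distant base conformers")
    confs: list[Conformer] = []
    labels = []
    for g, base in enumerate(bases):
        for k in range(per_group):
            noise = rng.normal(0.0, jitter_sd, size=base.coords.shape)
            confs.append(base.with_coords(base.coords + noise, id=f"g{g}_m{k}"))
            labels.append(g)
    return confs, np.array(labels)
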