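"""Daura (GROMOS-style) clustering of conformer sets and ensemble comparison.

The greedy Daura loop: compute all pairwise post-superposition RMSDs,
repeatedly take the structure with the most neighbors within the cutoff as
a cluster center, remove it with its neighbors as one cluster, and iterate
until nothing is left.  Ties on neighbor count break toward the lowest
input index so results are deterministic.  The similarity criterion is a
mass-weighted RMSD over the macrocycle atoms by default, with a 0.7 A
cutoff as its customary value for small macrocycles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ensemble_fit import EnsembleSolution
from .geometry import AtomSelection, Conformer, superpose


class Cluster(NamedTuple):
    center_index: int
    member_indices: tuple[int, ...]  # includes the center

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class ClusterResult:
    """Partition of a conformer set into Daura clusters.

    Clusters are ordered by decreasing size (the greedy loop produces
    non-increasing sizes by construction); every input structure belongs to
    exactly one cluster and every member lies within ``cutoff`` of its
    center.
    """

    clusters: list[Cluster]
    cutoff: float
    selection: AtomSelection | None
    mass_weighted: bool
    ids: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    @property
    def labels(self) -> np.ndarray:
        n = sum(self.sizes)
        lab = np.full(n, -1, dtype=int)
        for k, cl in enumerate(self.clusters):
            for i in cl.member_indices:
                lab[i] = k
        return lab

    @property
    def largest_cluster_fraction(self) -> float:
        n = sum(self.sizes)
        return max(self.sizes) / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "mass_weighted": self.mass_weighted,
            "n_clusters": self.n_clusters,
            "clusters": [
                {
                    "center_index": c.center_index,
                    "center_id": self.ids[c.center_index] if self.ids else None,
                    "size": c.size,
                    "member_indices": list(c.member_indices),
                }
                for c in self.clusters
            ],
        }


def rmsd_matrix(
    conformers: Sequence[Conformer],
    sel: AtomSelection | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Symmetric matrix of pairwise post-superposition RMSDs (Angstrom)."""
    confs = list(conformers)
    n = len(confs)
    if n == 0:
        raise ValueError("need at least one conformer")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(confs[i], confs[j], sel=sel, mass_weighted=mass_weighted).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def _daura_from_matrix(mat: np.ndarray, cutoff: float) -> list[Cluster]:
    n = mat.shape[0]
    adj = mat <= cutoff
    np.fill_diagonal(adj, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (adj & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        clusters.append(Cluster(center, tuple(int(i) for i in members)))
        remaining[members] = False
    return clusters


class DauraClustering(BaseEstimator):
    """Greedy neighbor-count clustering over an RMSD cutoff.

    Parameters
    ----------
    cutoff : float, default 0.7
        RMSD similarity criterion in Angstrom.
    selection : AtomSelection or None
        Atoms over which structures are superposed and compared (e.g. the
        macrocycle heavy atoms); ``None`` means all atoms.
    mass_weighted : bool, default True

    ``fit`` accepts either a sequence of conformers or a precomputed square
    RMSD matrix.  Attributes after fitting: ``labels_`` (cluster rank per
    input, 0 = largest cluster), ``result_`` (:class:`ClusterResult`),
    ``cluster_centers_idx_``.
    """

    def __init__(
        self,
        cutoff: float = 0.7,
        selection: AtomSelection | None = None,
        mass_weighted: bool = True,
    ):
        self.cutoff = cutoff
        self.selection = selection
        self.mass_weighted = mass_weighted

    def fit(self, X, y=None) -> "DauraClustering":
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        ids: tuple[str, ...] = ()
        if isinstance(X, np.ndarray) and X.ndim == 2 and X.shape[0] == X.shape[1]:
            mat = np.asarray(X, dtype=float)
        else:
            confs = list(X)
            mat = rmsd_matrix(confs, sel=self.selection, mass_weighted=self.mass_weighted)
            ids = tuple(c.id for c in confs)
        clusters = _daura_from_matrix(mat, self.cutoff)
        self.result_ = ClusterResult(
            clusters, self.cutoff, self.selection, self.mass_weighted, ids
        )
        self.labels_ = self.result_.labels
        self.cluster_centers_idx_ = [c.center_index for c in clusters]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def daura_cluster(
    conformers: Sequence[Conformer],
    sel: AtomSelection | None = None,
    cutoff: float = 0.7,
    mass_weighted: bool = True,
) -> ClusterResult:
    """Cluster a conformer set with the greedy Daura loop."""
    confs = list(conformers)
    if not confs:
        return ClusterResult([], cutoff, sel, mass_weighted, ())
    est = DauraClustering(cutoff=cutoff, selection=sel, mass_weighted=mass_weighted)
    return est.fit(confs).result_


def compare_ensembles(
    cluster_result: ClusterResult,
    cluster_conformers: Sequence[Conformer],
    solution: EnsembleSolution,
    solution_pool: Sequence[Conformer],
    sel: AtomSelection | None = None,
    cutoff: float = 0.7,
    mass_weighted: bool | None = None,
    min_weight: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-compare cluster centers against a fitted solution ensemble.

    Returns the full cross table (one row per center x ensemble member with
    the RMSD and a ``comparable`` flag at ``cutoff``) plus a per-member
    summary naming the nearest cluster center (lowest mutual RMSD).
    ``min_weight`` restricts the comparison to members above a weight
    fraction (the headline analysis used 10%).
    """
    if mass_weighted is None:
        mass_weighted = cluster_result.mass_weighted
    by_id = {c.id: c for c in solution_pool}
    members = [
        (mid, w)
        for mid, w in zip(solution.member_ids, solution.weights)
        if w >= min_weight
    ]
    rows = []
    for cl in cluster_result.clusters:
        center = cluster_conformers[cl.center_index]
        center_id = (
            cluster_result.ids[cl.center_index]
            if cluster_result.ids
            else f"cluster_{cl.center_index}"
        )
        for mid, w in members:
            r = superpose(by_id[mid], center, sel=sel, mass_weighted=mass_weighted).rmsd
            rows.append(
                {
                    "cluster_center": center_id,
                    "cluster_size": cl.size,
                    "conformer": mid,
                    "weight": w,
                    "rmsd": r,
                    "comparable": bool(r <= cutoff),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, table
    nearest = (
        table.loc[table.groupby("conformer")["rmsd"].idxmin()]
        .loc[:, ["conformer", "weight", "cluster_center", "rmsd", "comparable"]]
        .reset_index(drop=True)
    )
    return table, nearest


def cutoff_sweep(
    conformers: Sequence[Conformer],
    sel: AtomSelection | None = None,
    cutoffs: Sequence[float] = (0.7, 1.0),
    mass_weighted: bool = True,
) -> pd.DataFrame:
    """Cluster at several cutoffs; report counts and largest-cluster share.

    The cluster count is not guaranteed monotone in the cutoff for the
    greedy scheme, but looser cutoffs merge neighbor sets on the tight,
    well-separated test sets this package generates.
    """
    cs = list(cutoffs)
    if any(c <= 0 for c in cs) or sorted(cs) != cs:
        raise ValueError("cutoffs must be positive and sorted")
    mat = rmsd_matrix(list(conformers), sel=sel, mass_weighted=mass_weighted)
    rows = []
    for c in cs:
        clusters = _daura_from_matrix(mat, c)
        sizes = [cl.size for cl in clusters]
        rows.append(
            {
                "cutoff": c,
                "n_clusters": len(clusters),
                "largest_cluster_fraction": max(sizes) / mat.shape[0],
            }
        )
    return pd.DataFrame(rows)
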