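"""Population-weighted torsional-preference reports.

A fitted solution ensemble is summarized per torsion as a polar wedge
histogram: ten 36-degree wedges covering (-180, 180], each holding the
total weight of the retained conformers whose dihedral falls inside.
Conformers below a weight floor (default 1%) are excluded, so wedge heights
sum to the retained weight.  A reference angle (e.g. the protein-bound
conformer's torsion) can be overlaid as a 1-degree marker.  Side-chain
angles are also classified into staggered rotamer wells (g+/g-/anti).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ensemble_fit import EnsembleSolution
from .geometry import Conformer, dihedral

WEDGE_WIDTH = 36.0
N_WEDGES = 10
#: wedge edges anchored at exactly -180; intervals are half-open (lo, hi]
WEDGE_EDGES = np.linspace(-180.0, 180.0, N_WEDGES + 1)


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def wedge_index(angle: float) -> int:
    """Index of the half-open wedge (lo, hi] containing ``angle``."""
    a = normalize_angle(angle)
    # ceil-style binning implements (lo, hi]
    idx = int(np.ceil((a + 180.0) / WEDGE_WIDTH)) - 1
    return min(max(idx, 0), N_WEDGES - 1)


@dataclass(frozen=True)
class WedgeHistogram:
    """Weight-per-wedge summary of one torsion across an ensemble."""

    torsion_label: str
    heights: tuple[float, ...]
    reference_angle: float | None = None

    def __post_init__(self) -> None:
        h = tuple(float(x) for x in self.heights)
        if len(h) != N_WEDGES:
            raise ValueError(f"expected {N_WEDGES} wedge heights")
        if any(x < -1e-12 for x in h):
            raise ValueError("wedge heights must be non-negative")
        if sum(h) > 1.0 + 1e-9:
            raise ValueError("wedge heights may not exceed total weight 1")
        object.__setattr__(self, "heights", h)

    @property
    def total_weight(self) -> float:
        return float(sum(self.heights))

    def to_dict(self) -> dict:
        return {
            "torsion_label": self.torsion_label,
            "wedge_edges": list(WEDGE_EDGES),
            "heights": list(self.heights),
            "reference_angle": self.reference_angle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WedgeHistogram":
        return cls(
            torsion_label=d["torsion_label"],
            heights=tuple(d["heights"]),
            reference_angle=d.get("reference_angle"),
        )


def wedge_histogram(
    solution: EnsembleSolution,
    pool: Sequence[Conformer],
    torsion: tuple[int, int, int, int],
    weight_floor: float = 0.01,
    label: str = "",
) -> WedgeHistogram:
    """Bin each retained member's dihedral, weighted by its population.

    Members below ``weight_floor`` are not taken into account, so the total
    height equals the retained weight (1 when nothing is excluded).
    """
    by_id = {c.id: c for c in pool}
    heights = np.zeros(N_WEDGES)
    for mid, w in zip(solution.member_ids, solution.weights):
        if w < weight_floor:
            continue
        conf = by_id[mid]
        ang = dihedral(conf, *torsion)
        heights[wedge_index(ang)] += w
    lab = label or "-".join(str(i) for i in torsion)
    return WedgeHistogram(lab, tuple(heights))


def overlay_reference(h: WedgeHistogram, reference_angle: float) -> WedgeHistogram:
    """Annotate a histogram with a reference torsion (1-degree marker)."""
    return replace(h, reference_angle=normalize_angle(reference_angle))


def classify_rotamer(angle: float) -> str:
    """Staggered rotamer class of a chi-type dihedral.

    Convention: g+ = (0, 120], g- = [-120, 0), anti = the remainder
    (including exactly 0 and 180).
    """
    a = normalize_angle(angle)
    if 0.0 < a <= 120.0:
        return "g+"
    if -120.0 <= a < 0.0:
        return "g-"
    return "anti"


def total_variation(h1: WedgeHistogram, h2: WedgeHistogram) -> float:
    """Total variation distance between two wedge histograms (0..1)."""
    a = np.asarray(h1.heights)
    b = np.asarray(h2.heights)
    return float(0.5 * np.abs(a - b).sum())


def polar_plot(h: WedgeHistogram, ax=None):
    """Polar wedge plot of one torsion histogram (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians(WEDGE_EDGES[:-1] + WEDGE_WIDTH / 2.0)
    ax.bar(centers, h.heights, width=np.radians(WEDGE_WIDTH), alpha=0.6)
    if h.reference_angle is not None:
        ax.bar(
            [np.radians(h.reference_angle)],
            [max(h.heights) if any(h.heights) else 1.0],
            width=np.radians(1.0),
            color="tab:blue",
        )
    ax.set_title(h.torsion_label)
    return ax
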