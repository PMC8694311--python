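"""NAMFIS-style ensemble deconvolution.

Given a conformer pool and experimental restraints (NOE-derived effective
distances and vicinal couplings), find the simplex-constrained population
weights that minimize the tolerance-scaled sum of squared deviations

    sse(w) = sum_k ((obs_k - calc_k(w)) / tol_k)^2

where distances are back-calculated with r^-6 population averaging and
couplings with linear averaging of the Karplus curve.  Distances and
couplings enter on equal footing through their tolerances.

The optimizer is SLSQP over the weight simplex with an analytic gradient,
restarted from the uniform point plus random Dirichlet draws (default 50
starts, seeded).  Members falling below a weight floor (default 1%) are
pruned and the reduced problem re-fit until stable, mirroring the
convention of reporting only conformers above 1%.

Validation follows the protocol of perturbing every observation by a fixed
fraction of random noise and re-fitting, and of jackknifing restraints one
at a time, recording the resulting weight shifts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, clone

from .geometry import AtomSelection, Conformer, superpose
from .noe_pipeline import DistanceRestraint
from .observables import (
    DEFAULT_KARPLUS,
    JRestraint,
    KarplusParams,
    conformer_j,
    pair_r6,
)


@dataclass
class ValidationReport:
    """Record of the noise / jackknife re-fits around one solution.

    ``noise_trials`` and ``jackknife_trials`` hold full-pool weight vectors;
    ``max_weight_shift`` is the largest absolute weight change (percentage
    points) seen in any trial for any pool member.
    """

    noise_trials: list[tuple[int, np.ndarray]] = field(default_factory=list)
    jackknife_trials: list[tuple[str, np.ndarray]] = field(default_factory=list)
    max_weight_shift: float = 0.0
    backcalc_table: pd.DataFrame | None = None


@dataclass
class EnsembleSolution:
    """Fitted solution ensemble: retained members with simplex weights."""

    member_ids: tuple[str, ...]
    weights: tuple[float, ...]  # fractions, sum to 1
    sse: float
    per_restraint_residuals: tuple[float, ...]
    converged: bool = True
    validation: ValidationReport | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def weights_percent(self) -> tuple[float, ...]:
        return tuple(100.0 * w for w in self.weights)

    def weight_of(self, member_id: str) -> float:
        try:
            return self.weights[self.member_ids.index(member_id)]
        except ValueError:
            return 0.0

    def to_dict(self) -> dict:
        d = {
            "member_ids": list(self.member_ids),
            "weights_percent": list(self.weights_percent),
            "sse": self.sse,
            "per_restraint_residuals": list(self.per_restraint_residuals),
            "converged": self.converged,
            "metadata": self.metadata,
        }
        if self.validation is not None:
            d["validation"] = {
                "max_weight_shift_points": self.validation.max_weight_shift,
                "n_noise_trials": len(self.validation.noise_trials),
                "n_jackknife_trials": len(self.validation.jackknife_trials),
            }
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _design_matrices(
    pool: Sequence[Conformer],
    distance_restraints: Sequence[DistanceRestraint],
    j_restraints: Sequence[JRestraint],
    karplus: KarplusParams,
    exclude_capped: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Precompute per-conformer observables.

    Returns (R6, obs_d, tol_d, JM, obs_j, tol_j, labels): R6[k, i] is the
    r^-6 term of distance restraint k in conformer i; JM[k, i] the
    back-calculated coupling of J restraint k in conformer i.
    """
    drs = [r for r in distance_restraints if not (exclude_capped and r.capped)]
    R6 = np.array(
        [[pair_r6(c, r.atom_i, r.atom_j) for c in pool] for r in drs]
    ).reshape(len(drs), len(pool))
    obs_d = np.array([r.r_exp for r in drs])
    tol_d = np.array([r.tolerance for r in drs])
    JM = np.array(
        [[conformer_j(c, jr, karplus) for c in pool] for jr in j_restraints]
    ).reshape(len(j_restraints), len(pool))
    obs_j = np.array([jr.j_exp for jr in j_restraints])
    tol_j = np.array([jr.tolerance for jr in j_restraints])
    labels = [r.pair_id for r in drs] + [f"J:{jr.residue}" for jr in j_restraints]
    return R6, obs_d, tol_d, JM, obs_j, tol_j, labels


def _residuals(w, R6, obs_d, tol_d, JM, obs_j, tol_j) -> np.ndarray:
    out = []
    if len(obs_d):
        calc_d = (R6 @ w) ** (-1.0 / 6.0)
        out.append((obs_d - calc_d) / tol_d)
    if len(obs_j):
        out.append((obs_j - JM @ w) / tol_j)
    return np.concatenate(out) if out else np.zeros(0)


def _sse_and_grad(w, R6, obs_d, tol_d, JM, obs_j, tol_j):
    sse = 0.0
    grad = np.zeros_like(w)
    if len(obs_d):
        s = R6 @ w
        calc = s ** (-1.0 / 6.0)
        res = (obs_d - calc) / tol_d
        sse += float(res @ res)
        # d calc / d w_i = -(1/6) s^(-7/6) R6[:, i]
        coeff = 2.0 * res / tol_d * (1.0 / 6.0) * s ** (-7.0 / 6.0)
        grad += coeff @ R6
    if len(obs_j):
        res = (obs_j - JM @ w) / tol_j
        sse += float(res @ res)
        grad += (-2.0 * res / tol_j) @ JM
    return sse, grad


class NamfisFitter(BaseEstimator):
    """Simplex-constrained population fit of a conformer pool to restraints.

    Parameters
    ----------
    weight_floor : float, default 0.01
        Members below this fraction are pruned and the fit repeated.
    n_starts : int, default 50
        Multi-start count: the uniform point plus ``n_starts - 1`` random
        Dirichlet draws.
    random_state : int or None
        Seed for the random starts; required for reproducible fits.
    karplus : KarplusParams or None
        Default Karplus set for J restraints that carry none.
    exclude_capped : bool, default True
        Skip distance restraints flagged as capped (beyond the reliable
        NOE range).
    prune_and_refit : bool, default True
    ftol, max_iter : SLSQP convergence controls.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (n_pool,) ndarray of fitted weights over the *full* pool
        (pruned members at exactly 0).
    member_ids_, member_weights_ : retained members (weight >= floor).
    sse_ : objective value at the optimum.
    residuals_ : tolerance-scaled residual per restraint.
    restraint_labels_ : labels aligned with ``residuals_``.
    converged_ : whether any SLSQP start reported success.
    """

    def __init__(
        self,
        weight_floor: float = 0.01,
        n_starts: int = 50,
        random_state: int | None = None,
        karplus: KarplusParams | None = None,
        exclude_capped: bool = True,
        prune_and_refit: bool = True,
        ftol: float = 1e-12,
        max_iter: int = 500,
    ):
        self.weight_floor = weight_floor
        self.n_starts = n_starts
        self.random_state = random_state
        self.karplus = karplus
        self.exclude_capped = exclude_capped
        self.prune_and_refit = prune_and_refit
        self.ftol = ftol
        self.max_iter = max_iter

    # -- internal ---------------------------------------------------------

    def _solve_simplex(self, mats, n, rng) -> tuple[np.ndarray, float, bool]:
        R6, obs_d, tol_d, JM, obs_j, tol_j = mats
        if n == 1:
            w = np.ones(1)
            sse, _ = _sse_and_grad(w, R6, obs_d, tol_d, JM, obs_j, tol_j)
            return w, sse, True

        def fun(w):
            return _sse_and_grad(w, R6, obs_d, tol_d, JM, obs_j, tol_j)

        starts = [np.full(n, 1.0 / n)]
        for _ in range(max(0, self.n_starts - 1)):
            starts.append(rng.dirichlet(np.ones(n)))
        constraints = [
            {"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(n)}
        ]
        best_w, best_sse, any_success = None, np.inf, False
        for w0 in starts:
            res = minimize(
                fun,
                w0,
                jac=True,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * n,
                constraints=constraints,
                options={"ftol": self.ftol, "maxiter": self.max_iter},
            )
            w = np.clip(res.x, 0.0, None)
            w /= w.sum()
            sse, _ = fun(w)
            any_success = any_success or bool(res.success)
            if sse < best_sse:
                best_sse, best_w = sse, w
        return best_w, best_sse, any_success

    # -- API --------------------------------------------------------------

    def fit(
        self,
        pool: Sequence[Conformer],
        distance_restraints: Sequence[DistanceRestraint] = (),
        j_restraints: Sequence[JRestraint] = (),
    ) -> "NamfisFitter":
        pool = list(pool)
        if not pool:
            raise ValueError("conformer pool is empty")
        karplus = self.karplus or DEFAULT_KARPLUS
        R6, obs_d, tol_d, JM, obs_j, tol_j, labels = _design_matrices(
            pool, distance_restraints, j_restraints, karplus, self.exclude_capped
        )
        if len(obs_d) + len(obs_j) == 0:
            raise ValueError("no usable restraints to fit against")
        rng = np.random.default_rng(self.random_state)
        n = len(pool)
        active = np.arange(n)
        mats = (R6, obs_d, tol_d, JM, obs_j, tol_j)
        w_act, sse, success = self._solve_simplex(mats, n, rng)
        if self.prune_and_refit:
            while True:
                keep = w_act >= self.weight_floor
                if keep.all() or keep.sum() == 0:
                    break
                active = active[keep]
                sub = (R6[:, active], obs_d, tol_d, JM[:, active], obs_j, tol_j)
                w_act, sse, success = self._solve_simplex(sub, len(active), rng)
        weights = np.zeros(n)
        weights[active] = w_act
        self.pool_ids_ = tuple(c.id for c in pool)
        self.weights_ = weights
        retained = [
            (pool[i].id, weights[i]) for i in active if weights[i] >= self.weight_floor
        ]
        # pruning loop guarantees retained weights >= floor except the
        # pathological all-pruned case, where everything is kept as-is
        if not retained:
            retained = [(pool[i].id, weights[i]) for i in active]
        self.member_ids_ = tuple(mid for mid, _ in retained)
        self.member_weights_ = tuple(float(w) for _, w in retained)
        self.sse_ = float(sse)
        self.residuals_ = tuple(
            float(x) for x in _residuals(weights, R6, obs_d, tol_d, JM, obs_j, tol_j)
        )
        self.restraint_labels_ = tuple(labels)
        self.converged_ = bool(success)
        self._design_ = (R6, obs_d, tol_d, JM, obs_j, tol_j)
        return self

    def solution(self) -> EnsembleSolution:
        self._check_fitted()
        return EnsembleSolution(
            member_ids=self.member_ids_,
            weights=self.member_weights_,
            sse=self.sse_,
            per_restraint_residuals=self.residuals_,
            converged=self.converged_,
            metadata={
                "weight_floor": self.weight_floor,
                "n_starts": self.n_starts,
                "random_state": self.random_state,
                "karplus": vars(self.karplus or DEFAULT_KARPLUS),
                "objective": "tolerance-scaled SSE, r^-6 distances + linear J",
            },
        )

    def backcalc_table(self) -> pd.DataFrame:
        """Observed vs back-calculated value per restraint at the optimum."""
        self._check_fitted()
        R6, obs_d, tol_d, JM, obs_j, tol_j = self._design_
        w = self.weights_
        rows = []
        if len(obs_d):
            calc_d = (R6 @ w) ** (-1.0 / 6.0)
            for lab, o, c, t in zip(self.restraint_labels_, obs_d, calc_d, tol_d):
                rows.append(
                    {"restraint": lab, "kind": "distance", "observed": o,
                     "backcalc": c, "tolerance": t, "deviation_tol": (o - c) / t}
                )
        if len(obs_j):
            calc_j = JM @ w
            for lab, o, c, t in zip(
                self.restraint_labels_[len(obs_d):], obs_j, calc_j, tol_j
            ):
                rows.append(
                    {"restraint": lab, "kind": "J", "observed": o,
                     "backcalc": c, "tolerance": t, "deviation_tol": (o - c) / t}
                )
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("fitter is not fitted yet")


def objective(
    pool: Sequence[Conformer],
    weights: Sequence[float],
    distance_restraints: Sequence[DistanceRestraint] = (),
    j_restraints: Sequence[JRestraint] = (),
    karplus: KarplusParams | None = None,
    exclude_capped: bool = True,
) -> float:
    """Tolerance-scaled SSE of a weight vector against the restraints."""
    from .observables import check_weights

    w = check_weights(weights, len(pool))
    R6, obs_d, tol_d, JM, obs_j, tol_j, _ = _design_matrices(
        list(pool), distance_restraints, j_restraints,
        karplus or DEFAULT_KARPLUS, exclude_capped,
    )
    sse, _ = _sse_and_grad(w, R6, obs_d, tol_d, JM, obs_j, tol_j)
    return float(sse)


def fit_populations(
    pool: Sequence[Conformer],
    distance_restraints: Sequence[DistanceRestraint] = (),
    j_restraints: Sequence[JRestraint] = (),
    **params,
) -> EnsembleSolution:
    """One-call wrapper around :class:`NamfisFitter`."""
    fitter = NamfisFitter(**params)
    fitter.fit(pool, distance_restraints, j_restraints)
    return fitter.solution()


def validate(
    fitter: NamfisFitter,
    pool: Sequence[Conformer],
    distance_restraints: Sequence[DistanceRestraint] = (),
    j_restraints: Sequence[JRestraint] = (),
    n_noise_trials: int = 10,
    noise_frac: float = 0.10,
    seed: int = 0,
    max_jackknife: int | None = None,
) -> ValidationReport:
    """Noise/jackknife validation of a fitted solution.

    (a) each observed value is perturbed by uniform multiplicative noise of
    +-``noise_frac`` and the fit repeated, per trial; (b) each restraint is
    dropped in turn (a seeded random subset when there are more than
    ``max_jackknife``) and the fit repeated.  Everything is reproducible
    from ``seed``.
    """
    fitter._check_fitted()
    base = np.asarray(fitter.weights_)
    pool = list(pool)
    report = ValidationReport(backcalc_table=fitter.backcalc_table())
    shifts = [0.0]
    rng = np.random.default_rng(seed)

    def refit(drs, jrs) -> np.ndarray:
        f = clone(fitter)
        f.fit(pool, drs, jrs)
        return np.asarray(f.weights_)

    for trial in range(n_noise_trials):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        trng = np.random.default_rng(trial_seed)
        drs = [
            DistanceRestraint(
                r.pair_id, r.atom_i, r.atom_j,
                r.r_exp * (1.0 + trng.uniform(-noise_frac, noise_frac)),
                r.tolerance, r.capped,
            )
            for r in distance_restraints
        ]
        jrs = [
            JRestraint(
                jr.residue,
                jr.j_exp * (1.0 + trng.uniform(-noise_frac, noise_frac)),
                jr.tolerance, jr.phi_atoms, jr.karplus,
            )
            for jr in j_restraints
        ]
        w = refit(drs, jrs)
        report.noise_trials.append((trial_seed, w))
        shifts.append(float(np.max(np.abs(w - base)) * 100.0))

    all_ids = [("d", i, r.pair_id) for i, r in enumerate(distance_restraints)] + [
        ("j", i, f"J:{jr.residue}") for i, jr in enumerate(j_restraints)
    ]
    if len(all_ids) > 1:
        chosen = all_ids
        if max_jackknife is not None and len(all_ids) > max_jackknife:
            pick = rng.choice(len(all_ids), size=max_jackknife, replace=False)
            chosen = [all_ids[i] for i in sorted(pick)]
        for kind, i, label in chosen:
            drs = [r for k, r in enumerate(distance_restraints) if not (kind == "d" and k == i)]
            jrs = [r for k, r in enumerate(j_restraints) if not (kind == "j" and k == i)]
            w = refit(drs, jrs)
            report.jackknife_trials.append((label, w))
            shifts.append(float(np.max(np.abs(w - base)) * 100.0))
    report.max_weight_shift = max(shifts)
    return report


def match_reference(
    solution: EnsembleSolution,
    pool: Sequence[Conformer],
    reference: Conformer,
    sel: AtomSelection | None = None,
    cutoff: float = 0.7,
    mass_weighted: bool = True,
) -> list[tuple[str, float, float]]:
    """Ensemble members within ``cutoff`` RMSD of a reference conformer.

    Returns ``(member_id, rmsd, weight)`` tuples sorted by RMSD; empty when
    no member is comparable.  This is the bioactive-conformer check: a hit
    means the reference geometry is populated in the solution ensemble.
    """
    by_id = {c.id: c for c in pool}
    hits = []
    for mid, w in zip(solution.member_ids, solution.weights):
        if mid not in by_id:
            raise KeyError(f"solution member {mid!r} not found in pool")
        r = superpose(by_id[mid], reference, sel=sel, mass_weighted=mass_weighted).rmsd
        if r <= cutoff:
            hits.append((mid, float(r), float(w)))
    return sorted(hits, key=lambda t: t[1])
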