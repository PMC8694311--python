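"""NAMFIS-style population fitting: objective, optimizer, matching."""
import numpy as np
import pytest

from ensemblefit import (
    NamfisFitter,
    SyntheticScenario,
    fit_populations,
    match_reference,
    objective,
    realize,
    restraints_from_realization,
)
from ensemblefit.noe_pipeline import DistanceRestraint
from ensemblefit.observables import JRestraint, conformer_j, ensemble_distance, pair_distance
from ensemblefit.synthetic_data import generate_pool, true_weight_vector


def exact_restraints_from(conformer, pairs, tolerance_frac=0.10):
    """Distance restraints generated noiselessly from one conformer."""
    out = []
    for a, b in pairs:
        r = pair_distance(conformer, a, b)
        out.append(DistanceRestraint(f"{a}-{b}", a, b, r, tolerance_frac * r))
    return out


PAIRS = [("H2", "HA1"), ("H2", "HA2"), ("H3", "HA2"), ("H3", "HA3"),
         ("H4", "HA3"), ("H4", "HA4"), ("H2", "H3"), ("H3", "H4")]


class TestObjective:
    def test_exact_restraints_give_zero(self, template):
        drs = exact_restraints_from(template, PAIRS)
        assert objective([template], [1.0], drs) == pytest.approx(0.0, abs=1e-20)

    def test_one_tolerance_off_gives_one(self, template):
        a, b = PAIRS[0]
        r = pair_distance(template, a, b)
        tol = 0.1 * r
        dr = DistanceRestraint("p", a, b, r + tol, tol)
        assert objective([template], [1.0], [dr]) == pytest.approx(1.0, rel=1e-9)

    def test_matches_straight_line_reimplementation(self, small_pool):
        """Independent loop-based re-evaluation of the tolerance-scaled SSE."""
        rng = np.random.default_rng(8)
        pool = small_pool[:3]
        w = rng.dirichlet(np.ones(3))
        drs = exact_restraints_from(small_pool[5], PAIRS[:5])
        jrs = [JRestraint("2", 6.5, 0.5, ("C1", "N2", "CA2", "C2"))]
        expected = 0.0
        for r in drs:
            calc = ensemble_distance(pool, w, r.atom_i, r.atom_j)
            expected += ((r.r_exp - calc) / r.tolerance) ** 2
        for jr in jrs:
            calc = sum(wi * conformer_j(c, jr) for wi, c in zip(w, pool))
            expected += ((jr.j_exp - calc) / jr.tolerance) ** 2
        assert objective(pool, w, drs, jrs) == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_single_true_member_recovered(self, small_pool):
        drs = exact_restraints_from(small_pool[3], PAIRS)
        sol = fit_populations(small_pool, drs, random_state=0)
        assert sol.weight_of(small_pool[3].id) >= 0.99

    def test_no_restraints_raises(self, small_pool):
        with pytest.raises(ValueError):
            fit_populations(small_pool, [], random_state=0)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            fit_populations([], [], random_state=0)

    def test_deterministic_given_seed(self, zero_noise_study):
        real, drs, jrs = zero_noise_study
        f1 = NamfisFitter(random_state=3, n_starts=10).fit(real.pool, drs, jrs)
        f2 = NamfisFitter(random_state=3, n_starts=10).fit(real.pool, drs, jrs)
        assert np.array_equal(f1.weights_, f2.weights_)

    def test_no_worse_than_uniform_start(self, zero_noise_study):
        real, drs, jrs = zero_noise_study
        f = NamfisFitter(random_state=1, n_starts=5).fit(real.pool, drs, jrs)
        n = len(real.pool)
        assert f.sse_ <= objective(real.pool, np.full(n, 1 / n), drs, jrs) + 1e-9

    def test_self_consistency_on_refit_with_members_only(self, fitted_zero_noise):
        real, drs, jrs, fitter = fitted_zero_noise
        members = [c for c in real.pool if c.id in fitter.member_ids_]
        refit = NamfisFitter(random_state=2).fit(members, drs, jrs)
        for mid, w in zip(fitter.member_ids_, fitter.member_weights_):
            assert refit.solution().weight_of(mid) == pytest.approx(w, abs=0.005)

    def test_duplicated_pool_preserves_geometry_weights(self, zero_noise_study):
        real, drs, jrs = zero_noise_study
        f0 = NamfisFitter(random_state=4).fit(real.pool, drs, jrs)
        doubled = real.pool + [c.with_coords(c.coords, id=c.id + "_dup")
                               for c in real.pool]
        f1 = NamfisFitter(random_state=4).fit(doubled, drs, jrs)
        n = len(real.pool)
        merged = f1.weights_[:n] + f1.weights_[n:]
        assert np.allclose(merged, f0.weights_, atol=0.01)

    def test_irrelevant_conformer_gets_no_weight(self, zero_noise_study):
        real, drs, jrs = zero_noise_study
        f0 = NamfisFitter(random_state=5).fit(real.pool, drs, jrs)
        # a heavily violating decoy: different seed, strongly perturbed torsions
        decoy = generate_pool(999, 2)[1].with_coords(
            generate_pool(999, 2)[1].coords, id="decoy"
        )
        f1 = NamfisFitter(random_state=5).fit(real.pool + [decoy], drs, jrs)
        assert f1.weights_[-1] < 0.01
        assert np.max(np.abs(f1.weights_[:-1] - f0.weights_)) < 0.01

    def test_residuals_align_with_restraints(self, fitted_zero_noise):
        _, drs, jrs, fitter = fitted_zero_noise
        assert len(fitter.residuals_) == len(drs) + len(jrs)
        table = fitter.backcalc_table()
        assert set(table["kind"]) == {"distance", "J"}
        assert np.allclose(
            table["deviation_tol"].to_numpy() ** 2,
            np.asarray(fitter.residuals_) ** 2,
        )

    def test_weights_on_simplex_and_floor_respected(self, fitted_zero_noise):
        *_, fitter = fitted_zero_noise
        assert fitter.weights_.min() >= 0
        assert fitter.weights_.sum() == pytest.approx(1.0, abs=1e-8)
        assert min(fitter.member_weights_) >= fitter.weight_floor


class TestMatchReference:
    def test_member_itself_matches_at_zero(self, fitted_zero_noise):
        real, _, _, fitter = fitted_zero_noise
        sol = fitter.solution()
        member = next(c for c in real.pool if c.id == sol.member_ids[0])
        hits = match_reference(sol, real.pool, member)
        assert hits[0][0] == member.id
        assert hits[0][1] == pytest.approx(0.0, abs=1e-9)
        assert hits[0][2] == pytest.approx(sol.weights[0])

    def test_distant_reference_matches_nothing(self, fitted_zero_noise):
        real, _, _, fitter = fitted_zero_noise
        far = generate_pool(777, 3)[2]
        assert match_reference(fitter.solution(), real.pool, far, cutoff=0.3) == []

    def test_planted_bioactive_found_with_planted_weight(self):
        scenario = SyntheticScenario(seed=9)
        real = realize(scenario)
        drs, jrs = restraints_from_realization(real)
        sol = NamfisFitter(random_state=9).fit(real.pool, drs, jrs).solution()
        bio_idx = real.truth["member_indices"][2]
        hits = match_reference(sol, real.pool, real.pool[bio_idx], cutoff=0.7)
        assert hits and hits[0][0] == real.truth["bioactive_id"]
        assert hits[0][2] == pytest.approx(real.truth["weights"][2], abs=0.02)
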