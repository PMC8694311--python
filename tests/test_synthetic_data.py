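"""Synthetic pool/NOESY/J generators and their round-trip guarantees."""
import itertools

import numpy as np
import pytest

from ensemblefit import SyntheticScenario, realize, restraints_from_realization
from ensemblefit.geometry import dihedral
from ensemblefit.noe_pipeline import buildup_curves, calibrate_peak_table
from ensemblefit.observables import KARPLUS_PRESETS, conformer_j, JRestraint, karplus_j
from ensemblefit.synthetic_data import (
    _NONBONDED,
    build_conformer,
    clash_free,
    generate_pool,
    plant_truth,
    simulate_j,
    simulate_noesy,
    true_weight_vector,
)


class TestGeneratePool:
    def test_single_conformer_is_template(self, template):
        pool = generate_pool(0, 1)
        assert np.allclose(pool[0].coords, template.coords)

    def test_same_seed_bit_identical(self):
        a = generate_pool(5, 6)
        b = generate_pool(5, 6)
        for x, y in zip(a, b):
            assert np.array_equal(x.coords, y.coords)

    def test_different_seeds_differ(self):
        a = generate_pool(5, 3)
        b = generate_pool(6, 3)
        assert not np.allclose(a[1].coords, b[1].coords)

    def test_all_members_clash_free(self):
        pool = generate_pool(1, 20)
        for c in pool:
            # independent clash oracle: direct loop over the non-bonded list
            for i, j in _NONBONDED:
                assert np.linalg.norm(c.coords[i] - c.coords[j]) >= 1.5
            assert clash_free(c)

    def test_shared_topology_and_ids(self):
        pool = generate_pool(2, 4)
        assert len({c.id for c in pool}) == 4
        for c in pool[1:]:
            assert c.atoms == pool[0].atoms

    def test_geminal_reference_distance_fixed(self):
        pool = generate_pool(3, 6)
        i = pool[0].atom_index("HB2")
        j = pool[0].atom_index("HB3")
        for c in pool:
            d = np.linalg.norm(c.coords[i] - c.coords[j])
            assert d == pytest.approx(1.78, abs=0.001)

    def test_epimer_flips_chi_sign_at_stereocenter(self):
        l_form = build_conformer(chirality=1)
        d_form = build_conformer(chirality=-1)
        idx = tuple(l_form.atom_index(n) for n in ("N2", "CA2", "HA2", "CB2"))
        # improper torsion around CA2 changes sign with the configuration
        a = dihedral(l_form, *idx)
        b = dihedral(d_form, *idx)
        assert np.sign(a) != np.sign(b)

    def test_unknown_torsion_name_rejected(self):
        with pytest.raises(KeyError):
            build_conformer({"phi9": 10.0})


class TestSimulateNoesy:
    def test_reference_pair_calibrates_to_r_ref_at_zero_noise(self):
        real = realize(SyntheticScenario(seed=3))
        curves, _ = calibrate_peak_table(real.peaks, ref_pair="HB2-HB3")
        from ensemblefit.noe_pipeline import calibrate_distance

        ref = curves["HB2-HB3"]
        assert calibrate_distance(ref, ref).r_exp == pytest.approx(1.78)

    def test_zero_noise_single_member_round_trip(self):
        sc = SyntheticScenario(seed=4, true_weights=(1.0,))
        real = realize(sc)
        drs, _ = restraints_from_realization(real)
        member = real.pool[real.truth["member_indices"][0]]
        from ensemblefit.observables import pair_distance

        for r in drs:
            true_r = pair_distance(member, r.atom_i, r.atom_j)
            assert r.r_exp == pytest.approx(true_r, rel=1e-3)

    def test_same_seed_identical_tables(self):
        a = realize(SyntheticScenario(seed=5, noise_noe=0.02))
        b = realize(SyntheticScenario(seed=5, noise_noe=0.02))
        assert a.peaks.equals(b.peaks)
        assert a.jtable.equals(b.jtable)

    def test_buildups_accepted_at_low_noise(self):
        real = realize(SyntheticScenario(seed=6, noise_noe=0.02))
        curves = buildup_curves(real.peaks)
        assert all(c.accepted for c in curves.values())

    def test_noise_propagates_with_one_sixth_power_law(self):
        """Delta method: relative sd of the calibrated distance is about
        (1/6) * sqrt(relvar(sigma) + relvar(sigma_ref)), with
        relvar(sigma) = var(eps)/2 * sum(t^4)/sum(t^2)^2 for uniform
        multiplicative intensity noise eps."""
        noise = 0.05
        draws = 40
        sc0 = SyntheticScenario(seed=100)
        real0 = realize(sc0)
        _, drs0 = calibrate_peak_table(real0.peaks, ref_pair="HB2-HB3")
        baseline = {r.pair_id: r.r_exp for r in drs0}
        rel_errors = {pid: [] for pid in baseline}
        sc_noise = SyntheticScenario(seed=100, noise_noe=noise)
        for k in range(draws):
            # fixed pool/truth, fresh noise stream per draw
            rng = np.random.default_rng(5000 + k)
            peaks = simulate_noesy(sc_noise, real0.pool, real0.truth, rng)
            _, drs = calibrate_peak_table(peaks, ref_pair="HB2-HB3")
            for r in drs:
                rel_errors[r.pair_id].append(r.r_exp / baseline[r.pair_id] - 1.0)
        t = np.asarray(sc0.t_mix_ms, float)
        var_eps = noise ** 2 / 3.0  # uniform(-a, a)
        relvar_sigma = (var_eps / 2.0) * (t ** 4).sum() / (t ** 2).sum() ** 2
        predicted_sd = np.sqrt(2.0 * relvar_sigma) / 6.0
        observed = [np.std(v) for v in rel_errors.values() if len(v) == draws]
        assert np.mean(observed) == pytest.approx(predicted_sd, rel=0.5)
        # and errors are unbiased to first order
        means = [abs(np.mean(v)) for v in rel_errors.values()]
        assert max(means) < 3 * predicted_sd


class TestSimulateJ:
    def test_zero_noise_single_member_exact(self):
        sc = SyntheticScenario(seed=7, true_weights=(1.0,))
        real = realize(sc)
        member = real.pool[real.truth["member_indices"][0]]
        for row in real.jtable.itertuples(index=False):
            jr = JRestraint(
                row.residue, 0.0, row.tolerance_hz,
                (row.atom_1, row.atom_2, row.atom_3, row.atom_4),
                KARPLUS_PRESETS[row.karplus],
            )
            assert row.j_hz == pytest.approx(conformer_j(member, jr), abs=1e-9)

    def test_symmetric_pair_depends_only_on_cosines(self):
        """Equal-weight members at +phi and -phi: the coupling average is the
        same whichever member comes first (cosine is even)."""
        plus = build_conformer({"chi2": 58.0}, cid="p")
        minus = build_conformer({"chi2": -58.0}, cid="m")
        jr = JRestraint("x", 0.0, 0.5, ("HA2", "CA2", "CB2", "HB2"),
                        KARPLUS_PRESETS["pachler_ha_hb"])
        a = 0.5 * (conformer_j(plus, jr) + conformer_j(minus, jr))
        b = 0.5 * (conformer_j(minus, jr) + conformer_j(plus, jr))
        assert a == pytest.approx(b)
        phi = dihedral(plus, *(plus.atom_index(n) for n in ("HA2", "CA2", "CB2", "HB2")))
        assert conformer_j(plus, jr) == pytest.approx(
            karplus_j(phi, KARPLUS_PRESETS["pachler_ha_hb"])
        )


class TestPlantTruth:
    def test_truth_members_within_pool_and_simplex(self):
        sc = SyntheticScenario(seed=8)
        real = realize(sc)
        w = true_weight_vector(real.truth, real.pool)
        assert w.sum() == pytest.approx(1.0)
        assert len(real.truth["member_ids"]) == 4
        assert real.truth["bioactive_id"] in real.truth["member_ids"]

    def test_oversized_truth_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(pool_size=2, true_weights=(0.4, 0.3, 0.2, 0.1))

    def test_non_simplex_weights_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(true_weights=(0.5, 0.6))
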