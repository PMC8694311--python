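"""Daura clustering against a brute-force oracle; ensemble comparison."""
import numpy as np
import pytest

from ensemblefit import (
    DauraClustering,
    EnsembleSolution,
    compare_ensembles,
    cutoff_sweep,
    daura_cluster,
    generate_clustered_set,
    rmsd_matrix,
)
from ensemblefit.geometry import rmsd, superpose

from conftest import random_rotation


def brute_force_daura(mat, cutoff):
    """Independent re-implementation of the greedy neighbor-count loop."""
    n = mat.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, None
        for i in sorted(remaining):
            members = {j for j in remaining if mat[i, j] <= cutoff} | {i}
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append((best_center, frozenset(best_members)))
        remaining -= best_members
    return clusters


class TestRmsdMatrix:
    def test_duplicate_pair_is_zero(self, template):
        mat = rmsd_matrix([template, template])
        assert np.allclose(mat, 0.0, atol=1e-9)

    def test_entries_match_pairwise_superposition(self, small_pool):
        confs = small_pool[:5]
        mat = rmsd_matrix(confs, mass_weighted=True)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        for i in range(5):
            for j in range(5):
                expected = superpose(confs[i], confs[j], mass_weighted=True).rmsd
                assert mat[i, j] == pytest.approx(expected, abs=1e-6)


class TestDauraCluster:
    def test_huge_cutoff_gives_one_cluster(self, small_pool):
        res = daura_cluster(small_pool, cutoff=1e6)
        assert res.n_clusters == 1
        assert res.sizes == [len(small_pool)]

    def test_tiny_cutoff_gives_singletons(self, small_pool):
        res = daura_cluster(small_pool, cutoff=1e-6)
        assert res.n_clusters == len(small_pool)

    def test_planted_partition_recovered(self):
        confs, labels = generate_clustered_set(5)
        res = daura_cluster(confs, cutoff=0.7)
        assert res.n_clusters == 3
        for cl in res.clusters:
            member_labels = {labels[i] for i in cl.member_indices}
            assert len(member_labels) == 1  # no group is split or mixed

    def test_partition_property_and_center_membership(self, small_pool):
        res = daura_cluster(small_pool, cutoff=1.2)
        all_members = [i for cl in res.clusters for i in cl.member_indices]
        assert sorted(all_members) == list(range(len(small_pool)))
        assert sum(res.sizes) == len(small_pool)
        for cl in res.clusters:
            assert cl.center_index in cl.member_indices

    def test_members_within_cutoff_of_center(self):
        confs, _ = generate_clustered_set(6)
        cutoff = 0.7
        res = daura_cluster(confs, cutoff=cutoff)
        for cl in res.clusters:
            center = confs[cl.center_index]
            for i in cl.member_indices:
                assert rmsd(confs[i], center, mass_weighted=True) <= cutoff + 1e-9

    def test_sizes_non_increasing(self):
        confs, _ = generate_clustered_set(7, per_group=8)
        res = daura_cluster(confs, cutoff=0.7)
        assert res.sizes == sorted(res.sizes, reverse=True)

    def test_equivalent_to_brute_force(self):
        confs, _ = generate_clustered_set(3)
        mat = rmsd_matrix(confs, mass_weighted=True)
        res = daura_cluster(confs, cutoff=0.7)
        expected = brute_force_daura(mat, 0.7)
        got = [(c.center_index, frozenset(c.member_indices)) for c in res.clusters]
        assert got == expected

    def test_invariant_under_global_rigid_motion(self):
        confs, _ = generate_clustered_set(8)
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        moved = [c.with_coords(c.coords @ R.T + 3.0) for c in confs]
        a = daura_cluster(confs, cutoff=0.7)
        b = daura_cluster(moved, cutoff=0.7)
        assert [set(c.member_indices) for c in a.clusters] == [
            set(c.member_indices) for c in b.clusters
        ]

    def test_empty_set_gives_empty_result(self):
        res = daura_cluster([], cutoff=0.7)
        assert res.n_clusters == 0

    def test_sklearn_style_labels(self):
        confs, labels = generate_clustered_set(9)
        est = DauraClustering(cutoff=0.7)
        pred = est.fit_predict(confs)
        assert pred.shape == (len(confs),)
        # same planted group -> same predicted cluster
        for g in range(3):
            assert len({pred[i] for i in np.flatnonzero(labels == g)}) == 1


class TestCutoffSweep:
    def test_planted_set_sweep(self):
        confs, _ = generate_clustered_set(10)
        sweep = cutoff_sweep(confs, cutoffs=[0.1, 0.7, 10.0])
        assert list(sweep["n_clusters"]) == [30, 3, 1]
        assert sweep["largest_cluster_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_single_structure(self, template):
        sweep = cutoff_sweep([template], cutoffs=[0.1, 1.0])
        assert list(sweep["n_clusters"]) == [1, 1]
        assert list(sweep["largest_cluster_fraction"]) == [1.0, 1.0]

    def test_duplicated_set_same_cluster_count(self):
        confs, _ = generate_clustered_set(11)
        doubled = confs + [c.with_coords(c.coords, id=c.id + "d") for c in confs]
        a = daura_cluster(confs, cutoff=0.7)
        b = daura_cluster(doubled, cutoff=0.7)
        assert a.n_clusters == b.n_clusters

    def test_unsorted_cutoffs_rejected(self, small_pool):
        with pytest.raises(ValueError):
            cutoff_sweep(small_pool, cutoffs=[1.0, 0.5])


class TestCompareEnsembles:
    def test_planted_member_comparable_to_its_center_only(self):
        confs, labels = generate_clustered_set(12)
        res = daura_cluster(confs, cutoff=0.7)
        # take one structure of group 0 as a fitted "ensemble member"
        member = confs[0]
        sol = EnsembleSolution((member.id,), (1.0,), 0.0, ())
        table, nearest = compare_ensembles(res, confs, sol, confs, cutoff=0.7)
        comp = table[table["comparable"]]
        assert len(comp) == 1
        center_idx = int(comp["cluster_center"].iloc[0].split("_m")[0][1:])
        assert labels[0] == center_idx  # comparable center is in its own group
        assert nearest["comparable"].all()

    def test_center_equal_member_has_zero_rmsd(self):
        confs, _ = generate_clustered_set(13)
        res = daura_cluster(confs, cutoff=0.7)
        center = confs[res.clusters[0].center_index]
        sol = EnsembleSolution((center.id,), (1.0,), 0.0, ())
        table, _ = compare_ensembles(res, confs, sol, confs, cutoff=0.0)
        match = table[table["conformer"] == center.id]
        exact = match[match["rmsd"] <= 1e-9]
        assert len(exact) == 1 and exact["comparable"].all()
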