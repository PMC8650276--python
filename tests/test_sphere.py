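"""Sphere exclusion clustering, re-assignment and cluster-to-fold draws."""

import numpy as np
import pytest

import chemsplit as cs
from chemsplit.chem import FoldedFingerprint, MoleculeRecord
from reference import brute_force_sphere_exclusion, set_tanimoto_distance


def _mol(cid, bits, n_bits=64):
    return MoleculeRecord(
        cid, "", f"smiles-{cid}", fingerprint=FoldedFingerprint(frozenset(bits), n_bits)
    )


def _random_mols(rng, n, n_bits=256, density=0.1):
    mols = []
    for i in range(n):
        bits = frozenset(int(b) for b in rng.choice(n_bits, size=max(1, int(n_bits * density)), replace=False))
        mols.append(_mol(f"m{i}", bits, n_bits))
    return mols


class TestRunSphereExclusion:
    def test_single_compound_is_its_own_center(self):
        model = cs.run_sphere_exclusion([_mol("a", {1, 2})], 0.6, order_seed=0)
        assert model.n_clusters == 1
        assert model.center_compound_ids == ["a"]
        assert model.assignment == {"a": 0}

    def test_cutoff_one_collapses_everything(self):
        rng = np.random.default_rng(0)
        mols = _random_mols(rng, 20)
        model = cs.run_sphere_exclusion(mols, 1.0, order_seed=1)
        assert model.n_clusters == 1

    def test_empty_input_gives_empty_model(self):
        model = cs.run_sphere_exclusion([], 0.6, order_seed=0)
        assert model.n_clusters == 0 and model.assignment == {}

    def test_two_near_one_far(self):
        # dist(A,B) = 1 - 4/6 = 0.333 <= 0.6 ; C disjoint from both
        a = _mol("A", {1, 2, 3, 4, 5})
        b = _mol("B", {1, 2, 3, 4, 6})
        c = _mol("C", {10, 11, 12, 13, 14})
        # the partition {A,B},{C} is order-independent here; check all seeds
        for seed in range(5):
            model = cs.run_sphere_exclusion([a, b, c], 0.6, order_seed=seed)
            assert model.n_clusters == 2
            assert model.assignment["A"] == model.assignment["B"]
            assert model.assignment["C"] != model.assignment["A"]

    def test_center_separation_and_coverage_invariants(self):
        rng = np.random.default_rng(42)
        mols = _random_mols(rng, 120, density=0.05)
        by_id = {m.compound_id: m.fingerprint.on_bits for m in mols}
        model = cs.run_sphere_exclusion(mols, 0.6, order_seed=7)
        centers = [set(fp.on_bits) for fp in model.centers]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert set_tanimoto_distance(frozenset(centers[i]), frozenset(centers[j])) > 0.6
        for cid, k in model.assignment.items():
            assert set_tanimoto_distance(by_id[cid], frozenset(centers[k])) <= 0.6


class TestReassignToNearest:
    def test_idempotent(self):
        rng = np.random.default_rng(5)
        mols = _random_mols(rng, 40)
        model = cs.run_sphere_exclusion(mols, 0.6, order_seed=2)
        once = cs.reassign_to_nearest(model, mols)
        twice = cs.reassign_to_nearest(once, mols)
        assert once.assignment == twice.assignment
        assert once.center_compound_ids == model.center_compound_ids

    def test_tie_goes_to_lowest_index_center(self):
        # B and C are centers; X equidistant to both
        b = _mol("B", {1, 2, 3, 4})
        c = _mol("C", {11, 12, 13, 14})
        x = _mol("X", {1, 2, 11, 12})
        model = cs.ClusterModel(
            centers=[b.fingerprint, c.fingerprint],
            center_compound_ids=["B", "C"],
            assignment={"B": 0, "C": 1, "X": 1},
            t_tc=0.9,
            order_seed=0,
        )
        out = cs.reassign_to_nearest(model, [b, c, x])
        assert out.assignment["X"] == 0

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(11)
        mols = _random_mols(rng, 20, n_bits=128, density=0.15)
        model = cs.run_sphere_exclusion(mols, 0.6, order_seed=3)
        out = cs.reassign_to_nearest(model, mols)
        for m in mols:
            dists = [
                set_tanimoto_distance(m.fingerprint.on_bits, c.on_bits)
                for c in model.centers
            ]
            assert out.assignment[m.compound_id] == int(np.argmin(dists))

    def test_unknown_compound_rejected(self):
        a = _mol("a", {1})
        model = cs.run_sphere_exclusion([a], 0.6, order_seed=0)
        with pytest.raises(ValueError):
            cs.reassign_to_nearest(model, [a, _mol("ghost", {2})])


class TestAssignClusterFolds:
    def test_one_cluster_one_fold(self):
        rng = np.random.default_rng(1)
        mols = _random_mols(rng, 10)
        model = cs.run_sphere_exclusion(mols, 1.0, order_seed=0)
        out = cs.assign_cluster_folds(model, cs.SplitConfig(n_folds=5), fold_seed=4)
        assert len(set(out.mapping.values())) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        mols = _random_mols(rng, 50)
        model = cs.run_sphere_exclusion(mols, 0.6, order_seed=9)
        a = cs.assign_cluster_folds(model, cs.SplitConfig(n_folds=5), fold_seed=13)
        b = cs.assign_cluster_folds(model, cs.SplitConfig(n_folds=5), fold_seed=13)
        assert a.mapping == b.mapping

    def test_fold_draw_is_uniform_over_seeds(self):
        """Monte-Carlo over seeds: each cluster hits each fold ~1/n_folds."""
        rng = np.random.default_rng(3)
        mols = _random_mols(rng, 12, density=0.04)
        model = cs.run_sphere_exclusion(mols, 0.3, order_seed=0)
        assert model.n_clusters >= 2
        n_seeds, n_folds = 2000, 5
        hits = np.zeros(n_folds)
        watched = model.center_compound_ids[0]
        for seed in range(n_seeds):
            out = cs.assign_cluster_folds(model, cs.SplitConfig(n_folds=n_folds), fold_seed=seed)
            hits[out[watched]] += 1
        freq = hits / n_seeds
        sigma = (0.2 * 0.8 / n_seeds) ** 0.5
        assert np.all(np.abs(freq - 0.2) < 4 * sigma)


class TestOracleEquivalence:
    def test_pipeline_matches_independent_reference(self):
        """Full pipeline == brute-force reference for the same shuffle."""
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(5, 50))
            mols = _random_mols(rng, n, n_bits=128, density=0.12)
            fps = [m.fingerprint.on_bits for m in mols]
            order = list(np.random.default_rng(seed).permutation(n))
            ref_centers, ref_assign = brute_force_sphere_exclusion(fps, order, 0.6)
            model = cs.run_sphere_exclusion(mols, 0.6, order_seed=seed)
            model = cs.reassign_to_nearest(model, mols)
            assert model.center_compound_ids == [mols[i].compound_id for i in ref_centers]
            for i, m in enumerate(mols):
                assert model.assignment[m.compound_id] == ref_assign[i]
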