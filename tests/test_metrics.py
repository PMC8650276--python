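"""Pair-similarity leakage report and imbalance metrics."""

import numpy as np
import pandas as pd
import pytest

import chemsplit as cs
from chemsplit.chem import FoldedFingerprint, MoleculeRecord


def _mol(cid, bits=(1, 2), n_bits=64):
    return MoleculeRecord(
        cid, "", f"smi-{cid}", fingerprint=FoldedFingerprint(frozenset(bits), n_bits)
    )


def _fold(mapping, n_folds=5):
    return cs.FoldAssignment(mapping=mapping, n_folds=n_folds, method="random")


class TestSamplePairs:
    def test_two_molecules_single_possible_pair(self):
        mols = [_mol("a"), _mol("b")]
        pairs = cs.sample_pairs(mols, 10, seed=0)
        assert len(pairs) == 10
        assert all(set(p) == {"a", "b"} for p in pairs)

    def test_seed_reproducibility(self):
        mols = [_mol(f"m{i}") for i in range(30)]
        assert cs.sample_pairs(mols, 500, seed=3) == cs.sample_pairs(mols, 500, seed=3)

    def test_no_self_pairs(self):
        mols = [_mol(f"m{i}") for i in range(5)]
        assert all(a != b for a, b in cs.sample_pairs(mols, 2000, seed=1))

    def test_participation_counts_within_binomial_4_sigma(self):
        n_mols, n_pairs = 100, 100000
        mols = [_mol(f"m{i}") for i in range(n_mols)]
        counts = {}
        for a, b in cs.sample_pairs(mols, n_pairs, seed=2):
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        p = 2.0 / n_mols
        mu, sigma = n_pairs * p, (n_pairs * p * (1 - p)) ** 0.5
        assert all(abs(c - mu) <= 4 * sigma for c in counts.values())

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            cs.sample_pairs([_mol("a")], 5, seed=0)


class TestIntraFoldFraction:
    def test_single_fold_gives_fraction_one_everywhere(self):
        pairs = [("a", "b"), ("b", "c"), ("a", "c")]
        sims = np.array([0.05, 0.55, 0.95])
        folds = _fold({"a": 0, "b": 0, "c": 0})
        report = cs.intra_fold_fraction(pairs, sims, folds)
        populated = report.pair_counts > 0
        assert np.all(report.intra_fold_fraction[populated] == 1.0)

    def test_hand_built_pairs_match_manual_tally(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d"), ("c", "d")]
        sims = np.array([0.05, 0.05, 0.95, 0.95, 0.55, 0.55])
        folds = _fold({"a": 0, "b": 0, "c": 1, "d": 1})
        report = cs.intra_fold_fraction(pairs, sims, folds)
        # bin [0,0.1): (a,b) same, (a,c) diff -> 1/2
        assert report.intra_fold_fraction[0] == 0.5
        # bin [0.5,0.6): (b,d) diff, (c,d) same -> 1/2
        assert report.intra_fold_fraction[5] == 0.5
        # bin [0.9,1.0]: (b,c) diff, (a,d) diff -> 0
        assert report.intra_fold_fraction[9] == 0.0
        assert report.pair_counts.sum() == len(pairs)

    def test_similarity_one_lands_in_the_closed_top_bin(self):
        report = cs.intra_fold_fraction(
            [("a", "b")], np.array([1.0]), _fold({"a": 2, "b": 2})
        )
        assert report.pair_counts[9] == 1
        assert report.intra_fold_fraction[9] == 1.0

    def test_empty_bins_are_nan_not_zero(self):
        report = cs.intra_fold_fraction(
            [("a", "b")], np.array([0.05]), _fold({"a": 0, "b": 1})
        )
        assert np.isnan(report.intra_fold_fraction[5])

    def test_missing_fold_rejected(self):
        with pytest.raises(ValueError):
            cs.intra_fold_fraction([("a", "zz")], np.array([0.5]), _fold({"a": 0}))


def _activity(rows):
    return cs.ActivityTable(
        pd.DataFrame(rows, columns=["compound_id", "task_id", "label"])
    )


class TestActivityTable:
    def test_duplicate_measurement_rejected(self):
        with pytest.raises(ValueError):
            _activity([("a", "t", 1), ("a", "t", 0)])

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError):
            _activity([("a", "t", 2)])


class TestTaskDataImbalance:
    def test_pigeonhole_task_is_flagged(self):
        act = _activity([(f"c{i}", "t1", 1) for i in range(4)])
        folds = _fold({f"c{i}": i for i in range(4)})
        out = cs.task_data_imbalance(act, folds)
        assert bool(out.loc[0, "below5_flag"]) is True

    def test_exactly_five_per_fold_is_not_flagged(self):
        rows, mapping = [], {}
        for f in range(5):
            for i in range(5):
                cid = f"c{f}_{i}"
                rows.append((cid, "t1", 1))
                mapping[cid] = f
        out = cs.task_data_imbalance(_activity(rows), _fold(mapping))
        assert bool(out.loc[0, "below5_flag"]) is False
        assert out.loc[0, "fold_counts"] == [5, 5, 5, 5, 5]

    def test_three_task_table_matches_hand_flags(self):
        rows, mapping = [], {}
        # t_a: 25 compounds, 5 per fold -> not flagged
        for f in range(5):
            for i in range(5):
                cid = f"a{f}_{i}"
                rows.append((cid, "t_a", i % 2))
                mapping[cid] = f
        # t_b: 12 compounds all in folds 0-2 -> folds 3,4 empty -> flagged
        for i in range(12):
            cid = f"b{i}"
            rows.append((cid, "t_b", 1))
            mapping[cid] = i % 3
        # t_c: 30 compounds, fold 4 holds only 2 -> flagged
        for i in range(28):
            cid = f"c{i}"
            rows.append((cid, "t_c", 0))
            mapping[cid] = i % 4
        for i in range(2):
            cid = f"c_extra{i}"
            rows.append((cid, "t_c", 0))
            mapping[cid] = 4
        out = cs.task_data_imbalance(_activity(rows), _fold(mapping)).set_index("task_id")
        assert bool(out.loc["t_a", "below5_flag"]) is False
        assert bool(out.loc["t_b", "below5_flag"]) is True
        assert bool(out.loc["t_c", "below5_flag"]) is True
        # totals conserve
        assert int(out["n_compounds"].sum()) == len(rows)
        assert all(sum(c) == n for c, n in zip(out["fold_counts"], out["n_compounds"]))


class TestTaskLabelImbalance:
    def test_equal_fractions_not_flagged(self):
        rows, mapping = [], {}
        for f in range(4):
            for i, label in enumerate([0, 1]):
                cid = f"c{f}_{i}"
                rows.append((cid, "t", label))
                mapping[cid] = f
        out = cs.task_label_imbalance(_activity(rows), _fold(mapping))
        assert out.loc[0, "active_fraction_std"] == 0.0
        assert bool(out.loc[0, "label_imbalance_flag"]) is False

    def test_extreme_two_fold_split_flagged(self):
        rows = [("a", "t", 1), ("b", "t", 0)]
        out = cs.task_label_imbalance(_activity(rows), _fold({"a": 0, "b": 1}))
        assert out.loc[0, "active_fraction_std"] == pytest.approx(0.5)
        assert bool(out.loc[0, "label_imbalance_flag"]) is True

    def test_std_exactly_at_threshold_is_not_flagged(self):
        # fold active fractions {0.5, 0.5, 0.6, 0.6}: population std = 0.05
        rows, mapping = [], {}
        specs = [(0, 5, 10), (1, 5, 10), (2, 6, 10), (3, 6, 10)]
        for fold, n_active, n_total in specs:
            for i in range(n_total):
                cid = f"f{fold}_{i}"
                rows.append((cid, "t", 1 if i < n_active else 0))
                mapping[cid] = fold
        out = cs.task_label_imbalance(_activity(rows), _fold(mapping))
        assert out.loc[0, "active_fraction_std"] == pytest.approx(0.05)
        assert bool(out.loc[0, "label_imbalance_flag"]) is False

    def test_empty_folds_excluded_from_std_but_counted_below5(self):
        rows = [(f"c{i}", "t", i % 2) for i in range(10)]
        mapping = {f"c{i}": 0 for i in range(10)}  # everything in fold 0
        act = _activity(rows)
        folds = _fold(mapping)
        label = cs.task_label_imbalance(act, folds)
        assert label.loc[0, "n_populated_folds"] == 1
        assert label.loc[0, "active_fraction_std"] == 0.0
        data = cs.task_data_imbalance(act, folds)
        assert bool(data.loc[0, "below5_flag"]) is True  # four empty folds


class TestAggregation:
    def test_task_size_bins(self):
        per_task = pd.DataFrame(
            {
                "task_id": ["a", "b", "c", "d"],
                "n_compounds": [7, 10, 99, 1500],
                "below5_flag": [True, True, False, False],
                "label_imbalance_flag": [True, False, False, True],
            }
        )
        out = cs.aggregate_by_task_size(per_task).set_index("task_size_bin")
        assert out.loc["<10", "n_tasks"] == 1
        assert out.loc["10", "n_tasks"] == 2  # sizes 10 and 99
        assert out.loc["1000", "n_tasks"] == 1
        assert out.loc["10", "fraction_below5"] == 0.5
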