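"""Pairing, fold assignment, oversampling and HDF5 store round-trips."""

import numpy as np
import pytest

from swallownet.audio import AudioSegment
from swallownet.dataset import (
    FoldPlan,
    PairedSample,
    assign_folds,
    enumerate_pairs,
    oversample_training,
    read_store,
    write_store,
)


def _segment(subject, phase, idx=0, group="normal", substance=None, n=64):
    return AudioSegment(
        subject_id=subject, phase=phase, segment_index=idx,
        waveform=np.full(n, 0.1), target_rate=32, duration_s=n / 32,
        group_label=group, sex="male", substance=substance,
    )


class TestEnumeratePairs:
    def test_cartesian_product_within_subject(self):
        segs = [_segment("A", "pre", i) for i in range(3)]
        segs += [_segment("A", "post", i) for i in range(4)]
        pairs = enumerate_pairs(segs)
        assert len(pairs) == 12
        assert all(p.subject_id == "A" for p in pairs)

    def test_missing_phase_gives_zero_pairs(self):
        pairs = enumerate_pairs([_segment("A", "post", i) for i in range(4)])
        assert pairs == []

    def test_no_cross_subject_pairs(self):
        # brute-force enumeration: 2x2 + 1x3 = 7 pairs
        segs = (
            [_segment("A", "pre", i) for i in range(2)]
            + [_segment("A", "post", i) for i in range(2)]
            + [_segment("B", "pre", 0)]
            + [_segment("B", "post", i) for i in range(3)]
        )
        pairs = enumerate_pairs(segs)
        assert len(pairs) == 7
        assert all(
            (p.pre.subject_id == p.post.subject_id == p.subject_id) for p in pairs
        )

    def test_substance_restricts_pairing(self):
        segs = [
            _segment("A", "pre", 0, substance="water"),
            _segment("A", "post", 0, substance="water"),
            _segment("A", "pre", 1, substance="YP"),
            _segment("A", "post", 1, substance="YP"),
        ]
        assert len(enumerate_pairs(segs, within_substance=True)) == 2
        assert len(enumerate_pairs(segs, within_substance=False)) == 4

    def test_label_from_group(self):
        segs = [
            _segment("A", "pre", group="aspiration"),
            _segment("A", "post", group="aspiration"),
        ]
        (pair,) = enumerate_pairs(segs)
        assert pair.label == 1


class TestAssignFolds:
    def test_stratified_round_robin_counts(self):
        subjects = [(f"N{i}", 0) for i in range(20)] + [(f"A{i}", 1) for i in range(10)]
        plan = assign_folds(subjects, k=10, seed=3)
        for fold in range(10):
            members = plan.subjects_in_fold(fold)
            labels = [0 if s.startswith("N") else 1 for s in members]
            assert labels.count(0) == 2
            assert labels.count(1) == 1

    def test_deterministic_given_seed(self):
        subjects = [(f"S{i}", i % 2) for i in range(30)]
        assert assign_folds(subjects, seed=5).assignment == assign_folds(
            subjects, seed=5
        ).assignment
        assert assign_folds(subjects, seed=5).assignment != assign_folds(
            subjects, seed=6
        ).assignment

    def test_partition_property(self):
        subjects = [(f"S{i}", i % 2) for i in range(23)]
        plan = assign_folds(subjects, k=10, seed=0)
        assert set(plan.assignment) == {s for s, _ in subjects}
        assert all(0 <= f < 10 for f in plan.assignment.values())

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            assign_folds([("A", 0), ("B", 1)], k=1)

    def test_best_effort_warning_for_sparse_label(self, caplog):
        subjects = [(f"N{i}", 0) for i in range(12)] + [("A0", 1)]
        with caplog.at_level("WARNING"):
            assign_folds(subjects, k=10, seed=0)
        assert "best-effort" in caplog.text


def _pair(subject, label):
    return PairedSample(
        subject_id=subject, label=label,
        pre=_segment(subject, "pre", group="normal" if label == 0 else "aspiration"),
        post=_segment(subject, "post", group="normal" if label == 0 else "aspiration"),
        sex="male",
    )


class TestOversampling:
    def test_balances_to_equality(self):
        pairs = [_pair(f"N{i}", 0) for i in range(30)] + [
            _pair(f"A{i}", 1) for i in range(10)
        ]
        out = oversample_training(pairs, seed=0)
        labels = [p.label for p in out]
        assert labels.count(0) == labels.count(1) == 30
        # all originals retained (identity, not equality: segments hold arrays)
        out_ids = {id(p) for p in out}
        assert all(id(p) in out_ids for p in pairs)

    def test_balanced_split_unchanged(self):
        pairs = [_pair("N0", 0), _pair("A0", 1)]
        out = oversample_training(pairs, seed=0)
        assert [id(p) for p in out] == [id(p) for p in pairs]

    def test_deterministic(self):
        pairs = [_pair(f"N{i}", 0) for i in range(7)] + [_pair("A0", 1)]
        a = [p.subject_id for p in oversample_training(pairs, seed=4)]
        b = [p.subject_id for p in oversample_training(pairs, seed=4)]
        assert a == b

    def test_single_label_split_warned(self, caplog):
        pairs = [_pair(f"N{i}", 0) for i in range(3)]
        with caplog.at_level("WARNING"):
            out = oversample_training(pairs, seed=0)
        assert [id(p) for p in out] == [id(p) for p in pairs]
        assert "single label" in caplog.text


class TestStore:
    def test_round_trip_ids_labels_payloads(self, tiny_store):
        path, plan, pairs = tiny_store["path"], tiny_store["plan"], tiny_store["pairs"]
        for fold in range(plan.k):
            test = read_store(path, fold, "test")
            expected = plan.subjects_in_fold(fold)
            assert {p.subject_id for p in test} == expected
            for p in test:
                assert p.pre.payload[:4] == b"RIFF"

    def test_leakage_guard(self, tiny_store):
        path, plan = tiny_store["path"], tiny_store["plan"]
        for fold in range(plan.k):
            train_ids = {p.subject_id for p in read_store(path, fold, "train")}
            test_ids = {p.subject_id for p in read_store(path, fold, "test")}
            assert not (train_ids & test_ids)
            assert train_ids | test_ids == set(plan.assignment)

    def test_training_splits_balanced(self, tiny_store):
        path, plan = tiny_store["path"], tiny_store["plan"]
        for fold in range(plan.k):
            labels = [p.label for p in read_store(path, fold, "train")]
            assert labels.count(0) == labels.count(1)

    def test_test_splits_never_oversampled(self, tiny_store):
        path, plan, pairs = tiny_store["path"], tiny_store["plan"], tiny_store["pairs"]
        for fold in range(plan.k):
            test = read_store(path, fold, "test")
            raw = [p for p in pairs if p.subject_id in plan.subjects_in_fold(fold)]
            assert len(test) == len(raw)

    def test_missing_fold_rejected(self, tiny_store):
        with pytest.raises(KeyError):
            read_store(tiny_store["path"], 99, "test")
        with pytest.raises(ValueError):
            read_store(tiny_store["path"], 0, "validation")

    def test_unplanned_subject_rejected(self, tmp_path):
        plan = FoldPlan(k=2, assignment={"A": 0}, seed=0)
        with pytest.raises(ValueError, match="absent from the plan"):
            write_store(plan, [_pair("B", 0)], tmp_path / "x.h5")
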