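"""Cluster-subset construction and occurrence filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apchip import (
    MotifProblem,
    SequenceDataset,
    build_cluster_subset,
    enumerate_references,
    filter_candidates,
    hamming,
    occurrence_threshold,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)],
    )
    def test_known_distances(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming("ACG", "ACGT")

    @given(a=dna, b=dna)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_axioms(self, a, b):
        if len(a) != len(b):
            return
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, a) == 0
        assert (hamming(a, b) == 0) == (a == b)


def brute_force_subset(reference, dataset, k):
    """Independent O(t*n*l) double-loop oracle for subset membership."""
    l = len(reference.text)
    members = {(reference.seq_index, reference.offset)}
    for i, seq in enumerate(dataset.sequences):
        if i == reference.seq_index:
            continue
        for j in range(len(seq) - l + 1):
            window = seq[j : j + l]
            if set(window) <= set("ACGT") and sum(
                x != y for x, y in zip(window, reference.text)
            ) <= k:
                members.add((i, j))
    return members


class TestBuildClusterSubset:
    def test_matches_brute_force_on_random_datasets(self, rng):
        l = 4
        for _ in range(20):
            t = int(rng.integers(2, 10))
            seqs = [
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(l, 50))))
                for _ in range(t)
            ]
            ds = SequenceDataset(seqs)
            ref = ds.lmer_at(0, int(rng.integers(0, len(seqs[0]) - l + 1)), l)
            for k in (0, 1, 2):
                got = build_cluster_subset(ref, ds, k)
                assert {(p.seq_index, p.offset) for p in got.members} == brute_force_subset(
                    ref, ds, k
                )

    def test_k0_unique_reference(self):
        ds = SequenceDataset(["ACGTAA", "TTTTTT", "GGGGGG"])
        ref = ds.lmer_at(0, 0, 4)
        sub = build_cluster_subset(ref, ds, 0)
        assert sub.members == [ref]

    def test_exact_copies_hit_every_sequence(self):
        ds = SequenceDataset(["AACGTA", "TACGTT", "CACGTG"])
        ref = ds.lmer_at(0, 1, 4)  # ACGT, present in all three
        sub = build_cluster_subset(ref, ds, 1)
        assert all(sub.hits_per_sequence[i] >= 1 for i in (1, 2))

    def test_members_within_2k_of_each_other(self, rng):
        """Triangle inequality: all pairs in one subset lie within 2k."""
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        ds = SequenceDataset(seqs)
        ref = ds.lmer_at(0, 3, 6)
        k = 3
        sub = build_cluster_subset(ref, ds, k)
        for a in sub.members:
            for b in sub.members:
                assert hamming(a.text, b.text) <= 2 * k

    def test_short_sequence_contributes_nothing(self):
        ds = SequenceDataset(["ACGTACGT", "ACG"])
        ref = ds.lmer_at(0, 0, 5)
        sub = build_cluster_subset(ref, ds, 5)
        assert all(p.seq_index == 0 for p in sub.members)

    def test_masked_positions_excluded(self):
        ds = SequenceDataset(["ACGTACGT", "ACGNACGT"])
        ref = ds.lmer_at(0, 0, 4)
        sub = build_cluster_subset(ref, ds, 4)
        # windows of seq 1 spanning the N (offsets 0..3) are excluded
        assert {p.offset for p in sub.members if p.seq_index == 1} == {4}

    def test_both_strands_adds_reverse_complement(self):
        #            ref ACGT; revcomp ACGT = ACGT is palindromic, use AACC
        ds = SequenceDataset(["AACCGG", "TTGGTT"])  # revcomp of GGTT = AACC
        ref = ds.lmer_at(0, 0, 4)  # AACC
        plus = build_cluster_subset(ref, ds, 0)
        both = build_cluster_subset(ref, ds, 0, both_strands=True)
        assert len(both.members) > len(plus.members)
        assert any(p.text == "AACC" and p.seq_index == 1 for p in both.members)


class TestEnumerateReferences:
    def test_h_sequences_only(self):
        seqs = ["ACGTAC"] * 5
        ds = SequenceDataset([s + "ACGTAC" for s in seqs])
        refs = list(enumerate_references(ds, 4, q=5, dedup=False))
        assert {r.seq_index for r in refs} == {0}  # h = t - q + 1 = 1

    def test_reference_count_bound(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(10)]
        ds = SequenceDataset(seqs)
        refs = list(enumerate_references(ds, 9, q=9, dedup=False))
        assert {r.seq_index for r in refs} == {0, 1}
        assert len(refs) <= 2 * 192

    def test_dedup_by_text(self):
        ds = SequenceDataset(["AAAAAA", "CCCCCC"])
        refs = list(enumerate_references(ds, 4, q=2))
        assert len(refs) == 1

    def test_planted_instance_is_enumerated(self, planted_easy):
        problem, dataset, truth = planted_easy
        refs = list(enumerate_references(dataset, problem.l, problem.q, dedup=False))
        truths = {(i, off) for i, (off, _, _) in truth.placements.items()}
        assert any((r.seq_index, r.offset) in truths for r in refs)


class TestFilterCandidates:
    def _problem(self, t=5, n=30, q=None, l=4, d=1):
        return MotifProblem(l=l, d=d, t=t, n=n, q=q if q is not None else t)

    def test_planted_exact_copies_accepted(self):
        ds = SequenceDataset(["AACGTA", "TACGTT", "CACGTG"])
        ref = ds.lmer_at(0, 1, 4)
        sub = build_cluster_subset(ref, ds, 1)
        assert filter_candidates(sub, self._problem(t=3, n=6), occ_threshold=1)

    def test_impossible_threshold_rejects(self):
        ds = SequenceDataset(["AACGTA", "TACGTT", "CACGTG"])
        ref = ds.lmer_at(0, 1, 4)
        sub = build_cluster_subset(ref, ds, 1)
        assert not filter_candidates(sub, self._problem(t=3, n=6), occ_threshold=10)

    def test_random_background_mostly_rejected(self, rng):
        """With q = t and pk*(n-l+1) << 1, a random reference almost never
        collects a hit in every other sequence."""
        l, k, t, n = 10, 2, 8, 40
        problem = MotifProblem(l=l, d=1, t=t, n=n, q=t)
        rejected = total = 0
        for _ in range(100):
            seqs = ["".join(rng.choice(list("ACGT"), size=n)) for _ in range(t)]
            ds = SequenceDataset(seqs)
            ref = ds.lmer_at(0, int(rng.integers(0, n - l + 1)), l)
            sub = build_cluster_subset(ref, ds, k)
            total += 1
            if not filter_candidates(sub, problem, occ_threshold=1):
                rejected += 1
        assert rejected / total >= 0.95

    def test_monotone_in_q_and_threshold(self, planted_easy):
        problem, dataset, truth = planted_easy
        ref = dataset.lmer_at(0, truth.placements[0][0], problem.l)
        sub = build_cluster_subset(ref, dataset, 2 * problem.d)

        def n_candidates(q, thr):
            p = MotifProblem(l=problem.l, d=problem.d, t=problem.t, n=problem.n, q=q)
            return int(filter_candidates(sub, p, occ_threshold=thr))

        for q in range(1, problem.t):
            assert n_candidates(q, 1) >= n_candidates(q + 1, 1)
        for thr in range(1, 5):
            assert n_candidates(problem.q, thr) >= n_candidates(problem.q, thr + 1)

    def test_occurrence_threshold_floor(self):
        problem = MotifProblem(l=15, d=3, t=20, n=600, q=20)
        assert occurrence_threshold(problem, 586) == 1


class TestSequenceDataset:
    def test_rejects_empty_and_duplicates(self):
        with pytest.raises(ValueError):
            SequenceDataset([])
        with pytest.raises(ValueError):
            SequenceDataset(["ACGT", ""])
        with pytest.raises(ValueError):
            SequenceDataset(["ACGT", "ACGT"], ids=["a", "a"])

    def test_uppercasing(self):
        ds = SequenceDataset(["acgt"])
        assert ds.sequences[0] == "ACGT"
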