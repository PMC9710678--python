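import numpy as np
import pytest

from seqppi.curation import (
    CuratedDataset,
    InteractionPair,
    SequenceRecord,
    dedupe_pairs,
    pair_similarity,
    redundancy_filter,
    sample_negatives,
    sequence_similarity,
    similarity_histogram,
    split_train_test,
)

from conftest import random_seq


def seq_map(**kwargs):
    return {k: SequenceRecord(id=k, seq=v) for k, v in kwargs.items()}


class TestSequenceSimilarity:
    def test_identical(self):
        assert sequence_similarity("PEPTIDE", "PEPTIDE") == 1.0

    def test_disjoint(self):
        assert sequence_similarity("AAAA", "CCCC") == 0.0

    def test_single_substitution(self):
        # global alignment: 5 identical of 6 positions
        assert sequence_similarity("ACDEFG", "ACDEFA") == pytest.approx(5 / 6)

    def test_symmetric(self, rng):
        a, b = random_seq(rng, 30), random_seq(rng, 45)
        assert sequence_similarity(a, b) == pytest.approx(sequence_similarity(b, a))

    def test_length_normalization_uses_longer(self):
        # a perfect substring match is diluted by the longer sequence
        assert sequence_similarity("ACDE", "ACDEWWWW") == pytest.approx(4 / 8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_similarity("", "ACD")


class TestPairSimilarity:
    def test_identical_pairs(self):
        ps = pair_similarity(("ACDEF", "WYVKL"), ("ACDEF", "WYVKL"))
        assert (ps.s1, ps.s2) == (1.0, 1.0)

    def test_within_pair_order_invariant(self):
        pa = ("ACDEFGHIKL", "MNPQRSTVWY")
        pb = ("ACDEFGHIKW", "MNPQRSTVWA")
        direct = pair_similarity(pa, pb)
        swapped = pair_similarity(pa, (pb[1], pb[0]))
        assert direct.total == pytest.approx(swapped.total)
        assert sorted([direct.s1, direct.s2]) == pytest.approx(
            sorted([swapped.s1, swapped.s2])
        )

    def test_selects_higher_total_combination(self, rng):
        # oracle: evaluate all four similarities directly
        a1, a2 = random_seq(rng, 50), random_seq(rng, 50)
        b1, b2 = random_seq(rng, 50), random_seq(rng, 50)
        s11 = sequence_similarity(a1, b1)
        s22 = sequence_similarity(a2, b2)
        s12 = sequence_similarity(a1, b2)
        s21 = sequence_similarity(a2, b1)
        ps = pair_similarity((a1, a2), (b1, b2))
        assert ps.total == pytest.approx(max(s11 + s22, s12 + s21))

    def test_unrelated_pairs_low_similarity(self, rng):
        a1, a2 = random_seq(rng, 50), random_seq(rng, 50)
        b1, b2 = random_seq(rng, 50), random_seq(rng, 50)
        ps = pair_similarity((a1, a2), (b1, b2))
        assert ps.s1 < 0.45 and ps.s2 < 0.45


class TestSimilarityHistogram:
    def test_identical_single_pair_corner_bin(self):
        seqs = seq_map(A="ACDEFGHIKL", B="MNPQRSTVWY")
        pair = [InteractionPair("A", "B", 1)]
        hist = similarity_histogram(pair, pair, seqs, bins=10)
        assert hist[9, 9] == 1
        assert hist.sum() == 1

    def test_count_conservation(self, rng):
        seqs = {}
        pairs = []
        for i in range(4):
            a, b = f"A{i}", f"B{i}"
            seqs[a] = SequenceRecord(id=a, seq=random_seq(rng, 25))
            seqs[b] = SequenceRecord(id=b, seq=random_seq(rng, 25))
            pairs.append(InteractionPair(a, b, 1))
        hist = similarity_histogram(pairs[:2], pairs[2:], seqs, bins=5)
        assert hist.sum() == 4

    def test_unrelated_mass_in_low_corner(self, rng):
        seqs = {}
        pairs = []
        for i in range(6):
            a, b = f"A{i}", f"B{i}"
            seqs[a] = SequenceRecord(id=a, seq=random_seq(rng, 60))
            seqs[b] = SequenceRecord(id=b, seq=random_seq(rng, 60))
            pairs.append(InteractionPair(a, b, 1))
        hist = similarity_histogram(pairs[:3], pairs[3:], seqs, bins=2)
        assert hist[0, 0] == hist.sum() == 9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            similarity_histogram([], [InteractionPair("A", "B", 1)], {}, 5)


class TestRedundancyFilter:
    def test_duplicates_collapse(self):
        seqs = seq_map(A="ACDEFGHIKL", B="MNPQRSTVWY")
        pairs = [
            InteractionPair("A", "B", 1),
            InteractionPair("B", "A", 1),
            InteractionPair("A", "B", 1),
        ]
        assert len(redundancy_filter(pairs, seqs)) == 1

    def test_dissimilar_pairs_all_kept(self, rng):
        seqs, pairs = {}, []
        for i in range(5):
            a, b = f"A{i}", f"B{i}"
            seqs[a] = SequenceRecord(id=a, seq=random_seq(rng, 40))
            seqs[b] = SequenceRecord(id=b, seq=random_seq(rng, 40))
            pairs.append(InteractionPair(a, b, 1))
        assert len(redundancy_filter(pairs, seqs, 0.5)) == 5

    def test_near_copy_removed_longer_kept(self, rng):
        base_a = random_seq(rng, 50)
        base_b = random_seq(rng, 50)
        # pair2: 90%-identical, slightly shorter copy of pair1
        mutated_a = "W" + base_a[3:]
        seqs = seq_map(
            A1=base_a,
            B1=base_b,
            A2=mutated_a,
            B2=base_b[:-1],
            A3=random_seq(rng, 50),
            B3=random_seq(rng, 50),
        )
        pairs = [
            InteractionPair("A1", "B1", 1),
            InteractionPair("A2", "B2", 1),
            InteractionPair("A3", "B3", 1),
        ]
        kept = redundancy_filter(pairs, seqs, 0.5)
        keys = {p.key for p in kept}
        assert ("A1", "B1") in keys and ("A3", "B3") in keys
        assert ("A2", "B2") not in keys

    def test_output_audited_against_oracle(self, rng):
        from seqppi.curation import concatenated_sequence

        seqs, pairs = {}, []
        base = random_seq(rng, 40)
        for i in range(12):
            a, b = f"A{i}", f"B{i}"
            if i % 3 == 0:
                # family of mutated copies of the same base pair
                sa = base[: 5 + i] + base[5 + i :].replace("A", "C")
                sb = base[::-1]
            else:
                sa, sb = random_seq(rng, 40), random_seq(rng, 40)
            seqs[a] = SequenceRecord(id=a, seq=sa)
            seqs[b] = SequenceRecord(id=b, seq=sb)
            pairs.append(InteractionPair(a, b, 1))
        kept = redundancy_filter(pairs, seqs, 0.5)
        # all-vs-all audit: no surviving pair above the threshold
        cats = [concatenated_sequence(p, seqs) for p in kept]
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                assert sequence_similarity(cats[i], cats[j]) <= 0.5


class TestSampleNegatives:
    def _pool(self, rng, n):
        seqs, pairs = {}, []
        for i in range(n):
            a, b = f"NA{i}", f"NB{i}"
            seqs[a] = SequenceRecord(id=a, seq=random_seq(rng, 35))
            seqs[b] = SequenceRecord(id=b, seq=random_seq(rng, 35))
            pairs.append(InteractionPair(a, b, 0))
        return seqs, pairs

    def test_exact_count_from_large_pool(self, rng):
        seqs, pool = self._pool(rng, 200)
        positives = pool[:50]  # only the count matters
        out = sample_negatives(positives, pool[50:], seqs, seed=3)
        assert len(out) == 50

    def test_duplicate_pool_collapses_with_warning(self, rng, caplog):
        import logging

        seqs = seq_map(X="ACDEFGHIKLMNPQRSTVWY", Y="YWVTSRQPNMLKIHGFEDCA")
        pool = [InteractionPair("X", "Y", 0)] * 10
        positives = [InteractionPair("X", "Y", 1)] * 3
        with caplog.at_level(logging.WARNING):
            out = sample_negatives(positives, pool, seqs, seed=0)
        assert len(out) == 1
        assert "exhausted" in caplog.text

    def test_seed_determinism(self, rng):
        seqs, pool = self._pool(rng, 80)
        a = sample_negatives(pool[:20], pool[20:], seqs, seed=7)
        b = sample_negatives(pool[:20], pool[20:], seqs, seed=7)
        c = sample_negatives(pool[:20], pool[20:], seqs, seed=8)
        assert [p.key for p in a] == [p.key for p in b]
        assert [p.key for p in a] != [p.key for p in c]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives([], [], {}, seed=0)


class TestSplitTrainTest:
    def _pairs(self, n_pos, n_neg):
        out = []
        for i in range(n_pos):
            out.append(InteractionPair(f"P{i}A", f"P{i}B", 1))
        for i in range(n_neg):
            out.append(InteractionPair(f"N{i}A", f"N{i}B", 0))
        return out

    def test_sizes(self):
        train, test = split_train_test(self._pairs(50, 50), 0.12, seed=0)
        assert len(test) == 12 and len(train) == 88

    def test_partition(self):
        pairs = self._pairs(30, 30)
        train, test = split_train_test(pairs, 0.25, seed=1)
        assert {p.key for p in train} | {p.key for p in test} == {p.key for p in pairs}
        assert {p.key for p in train} & {p.key for p in test} == set()

    def test_stratification(self):
        train, test = split_train_test(self._pairs(60, 40), 0.25, seed=2)
        assert sum(p.label for p in test) == 15
        assert sum(1 - p.label for p in test) == 10

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(self._pairs(1, 10), 0.3, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self._pairs(5, 5), 1.5, seed=0)


def test_dedupe_unordered_identity():
    pairs = [
        InteractionPair("A", "B", 1),
        InteractionPair("B", "A", 1),
        InteractionPair("A", "C", 0),
    ]
    assert len(dedupe_pairs(pairs)) == 2


def test_dataset_resolution_errors():
    ds = CuratedDataset(sequences=seq_map(A="ACD"))
    with pytest.raises(KeyError, match="unknown sequence id"):
        ds.seq_of("Z")
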