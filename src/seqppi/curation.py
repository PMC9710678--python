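"""Dataset construction and redundancy control for pair-level data.

Sequence identity here is a symmetric global-alignment statistic: identical
aligned positions divided by the length of the *longer* sequence. Pairs are
deduplicated and redundancy-filtered on the concatenation of their two
sequences (canonical order: lexicographically smaller id first), using a
CD-HIT-style greedy clustering by descending concatenated length.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class InteractionPair:
    """Two sequence ids plus a binary label (1 = binder, 0 = non-binder).

    Pairs are unordered for identity purposes: (A, B) == (B, A).
    """

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered identity."""
        return (self.id_a, self.id_b) if self.id_a <= self.id_b else (self.id_b, self.id_a)


@dataclass
class CuratedDataset:
    sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    train: list[InteractionPair] = field(default_factory=list)
    test: list[InteractionPair] = field(default_factory=list)

    def seq_of(self, seq_id: str) -> str:
        try:
            return self.sequences[seq_id].seq
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def resolve(self, pair: InteractionPair) -> tuple[str, str]:
        return self.seq_of(pair.id_a), self.seq_of(pair.id_b)


@dataclass(frozen=True)
class PairSimilarity:
    """The two per-sequence similarities of the higher-scoring combination."""

    s1: float
    s2: float

    @property
    def total(self) -> float:
        return self.s1 + self.s2


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -0.5
_aligner.extend_gap_score = -0.1


def _identity_upper_bound(a: str, b: str) -> float:
    # alignment identities cannot exceed the shared residue multiset
    ca, cb = Counter(a), Counter(b)
    shared = sum(min(ca[c], cb[c]) for c in ca)
    return shared / max(len(a), len(b))


def sequence_similarity(a: str, b: str) -> float:
    """Global-alignment identity: identical aligned positions divided by the
    longer sequence's length. Symmetric; 1.0 for identical strings."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        ident += sum(x == y for x, y in zip(seg_a, seg_b))
    return ident / max(len(a), len(b))


def pair_similarity(
    pair_a: tuple[str, str], pair_b: tuple[str, str]
) -> PairSimilarity:
    """Compare two sequence pairs as unordered objects.

    Both pairings are evaluated — (a1,b1)/(a2,b2) and (a1,b2)/(a2,b1) — and
    the combination with the larger total similarity is returned (ties go to
    the first combination).
    """
    a1, a2 = pair_a
    b1, b2 = pair_b
    c1 = (sequence_similarity(a1, b1), sequence_similarity(a2, b2))
    c2 = (sequence_similarity(a1, b2), sequence_similarity(a2, b1))
    chosen = c1 if (c1[0] + c1[1]) >= (c2[0] + c2[1]) else c2
    return PairSimilarity(s1=chosen[0], s2=chosen[1])


def similarity_histogram(
    set1: Sequence[InteractionPair],
    set2: Sequence[InteractionPair],
    sequences: Mapping[str, SequenceRecord],
    bins: int = 20,
) -> np.ndarray:
    """2D histogram of pair-vs-pair similarities across two pair sets.

    Every cross pair (p, q) in set1 x set2 contributes one count at
    (s1, s2); the returned ``bins x bins`` matrix therefore sums to
    ``len(set1) * len(set2)``. Bin edges are uniform on [0, 1].
    """
    if not set1 or not set2:
        raise ValueError("similarity_histogram requires nonempty pair sets")

    def seqs(p: InteractionPair) -> tuple[str, str]:
        return sequences[p.id_a].seq, sequences[p.id_b].seq

    s1_vals, s2_vals = [], []
    for p in set1:
        sp = seqs(p)
        for q in set2:
            ps = pair_similarity(sp, seqs(q))
            s1_vals.append(ps.s1)
            s2_vals.append(ps.s2)
    hist, _, _ = np.histogram2d(
        s1_vals, s2_vals, bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    return hist


def concatenated_sequence(
    pair: InteractionPair, sequences: Mapping[str, SequenceRecord]
) -> str:
    """Canonical concatenation: sequence of the lexicographically smaller id
    first, so (A,B) and (B,A) concatenate identically."""
    first, second = pair.key
    return sequences[first].seq + sequences[second].seq


def redundancy_filter(
    pairs: Sequence[InteractionPair],
    sequences: Mapping[str, SequenceRecord],
    threshold: float = 0.5,
) -> list[InteractionPair]:
    """Greedy identity clustering on concatenated pair sequences.

    Pairs are visited by descending concatenated length (ties broken by
    canonical id key); a pair is kept only if its concatenated-sequence
    similarity to every previously kept representative is <= threshold.
    Exact duplicates (same unordered id pair) collapse to one entry first.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    unique: dict[tuple[str, str], InteractionPair] = {}
    for p in pairs:
        unique.setdefault(p.key, p)
    ordered = sorted(
        unique.values(),
        key=lambda p: (-len(concatenated_sequence(p, sequences)), p.key),
    )
    kept: list[InteractionPair] = []
    kept_cat: list[str] = []
    for p in ordered:
        cat = concatenated_sequence(p, sequences)
        redundant = False
        for rep in kept_cat:
            if _identity_upper_bound(cat, rep) <= threshold:
                continue  # cheap bound rules out the alignment
            if sequence_similarity(cat, rep) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(p)
            kept_cat.append(cat)
    return kept


def sample_negatives(
    positives: Sequence[InteractionPair],
    candidate_negatives: Sequence[InteractionPair],
    sequences: Mapping[str, SequenceRecord],
    seed: int,
    threshold: float = 0.5,
) -> list[InteractionPair]:
    """Draw a negative set matched in size to the positives.

    Candidates are shuffled deterministically under ``seed`` and accepted
    greedily while they stay mutually non-redundant at ``threshold`` (same
    criterion as :func:`redundancy_filter`). If the pool cannot supply
    ``len(positives)`` such pairs, the maximum achievable number is returned
    with a warning.
    """
    if not candidate_negatives:
        raise ValueError("empty candidate negative pool")
    target = len(positives)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidate_negatives))
    seen: set[tuple[str, str]] = set()
    kept: list[InteractionPair] = []
    kept_cat: list[str] = []
    for idx in order:
        if len(kept) >= target:
            break
        p = candidate_negatives[int(idx)]
        if p.key in seen:
            continue
        seen.add(p.key)
        cat = concatenated_sequence(p, sequences)
        redundant = any(
            _identity_upper_bound(cat, rep) > threshold
            and sequence_similarity(cat, rep) > threshold
            for rep in kept_cat
        )
        if not redundant:
            kept.append(p)
            kept_cat.append(cat)
    if len(kept) < target:
        logger.warning(
            "negative pool exhausted: requested %d, returning %d", target, len(kept)
        )
    return kept


def split_train_test(
    pairs: Sequence[InteractionPair], test_fraction: float, seed: int
) -> tuple[list[InteractionPair], list[InteractionPair]]:
    """Label-stratified, seeded train/test split, disjoint under unordered
    pair identity. Per-class test counts are ``round(n_class * fraction)``."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    by_label: dict[int, list[InteractionPair]] = {0: [], 1: []}
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        if p.key in seen:
            raise ValueError(f"duplicate pair under unordered identity: {p.key}")
        seen.add(p.key)
        by_label[p.label].append(p)
    for label, group in by_label.items():
        if len(group) < 2:
            raise ValueError(
                f"need at least 2 pairs of label {label} to split, got {len(group)}"
            )
    rng = np.random.default_rng(seed)
    train: list[InteractionPair] = []
    test: list[InteractionPair] = []
    for label in (1, 0):
        group = by_label[label]
        n_test = int(round(len(group) * test_fraction))
        n_test = min(max(n_test, 1), len(group) - 1)
        order = rng.permutation(len(group))
        test.extend(group[int(i)] for i in order[:n_test])
        train.extend(group[int(i)] for i in order[n_test:])
    return train, test


def dedupe_pairs(pairs: Iterable[InteractionPair]) -> list[InteractionPair]:
    """Collapse (A,B)/(B,A) duplicates, keeping first occurrence."""
    out: dict[tuple[str, str], InteractionPair] = {}
    for p in pairs:
        out.setdefault(p.key, p)
    return list(out.values())
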