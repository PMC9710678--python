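"""Autocorrelation descriptors for protein sequences.

Each sequence is translated residue-by-residue through the normalized scale
set into an ``n x k`` matrix (k = number of scales, default 7). For every
scale column the lagged autocorrelation is computed at lags 1..max_lag
(default 30), giving a length ``k * max_lag`` descriptor per sequence
(default 210) and ``2 * k * max_lag`` (default 420) for an ordered pair.

Descriptor layout is scale-major: the block for scale j occupies positions
``[j*max_lag, (j+1)*max_lag)`` with lag 1..max_lag inside the block. This
ordering is recorded in model metadata so trained models can detect
mismatched configurations.

Conventions (degenerate inputs):
- ``lag >= n``: the entry is 0 (no observable signal at that offset).
- zero-variance column (e.g. homopolymer): all entries for that scale are 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .scales import ScaleSet, STANDARD_AMINO_ACIDS

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 30

#: Sequences shorter than this trigger a warning (the method was tuned for
#: sequences of at least 16 residues) but are still processed.
MIN_ADVISED_LENGTH = 16

NonstandardPolicy = Literal["strict", "drop"]


class TranslationError(ValueError):
    """Raised when a sequence cannot be mapped through the scale set."""


@dataclass(frozen=True)
class TranslatedSequence:
    """A sequence mapped to numeric values: rows are residues, columns scales."""

    sequence_id: str
    matrix: np.ndarray  # shape (n, n_scales)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class SequenceFeatures:
    """Scale-major autocorrelation descriptor for one sequence."""

    sequence_id: str
    values: np.ndarray  # shape (n_scales * max_lag,)
    max_lag: int


def translate(
    seq: str,
    scales: ScaleSet,
    *,
    sequence_id: str = "",
    on_nonstandard: NonstandardPolicy = "strict",
) -> TranslatedSequence:
    """Map an amino-acid string through the scale set.

    Parameters
    ----------
    on_nonstandard:
        ``"strict"`` (default) raises on any residue outside the 20 standard
        codes, naming the offenders; ``"drop"`` removes such residues with a
        logged warning.
    """
    cleaned = "".join(seq.split()).upper()
    if not cleaned:
        raise TranslationError("empty sequence")
    standard = set(STANDARD_AMINO_ACIDS)
    bad = sorted({c for c in cleaned if c not in standard})
    if bad:
        if on_nonstandard == "strict":
            raise TranslationError(
                f"non-standard residue(s) in sequence {sequence_id or cleaned[:12]!r}: "
                + ", ".join(repr(c) for c in bad)
            )
        logger.warning(
            "dropping %d non-standard residue(s) (%s) from sequence %r",
            sum(cleaned.count(c) for c in bad),
            ", ".join(bad),
            sequence_id or cleaned[:12],
        )
        cleaned = "".join(c for c in cleaned if c in standard)
        if not cleaned:
            raise TranslationError(
                f"sequence {sequence_id!r} empty after dropping non-standard residues"
            )
    mat = np.empty((len(cleaned), len(scales)), dtype=np.float64)
    for j, scale in enumerate(scales):
        lut = scale.values
        mat[:, j] = [lut[c] for c in cleaned]
    return TranslatedSequence(sequence_id=sequence_id, matrix=mat)


def autocorrelation(
    ts: TranslatedSequence, max_lag: int = DEFAULT_MAX_LAG
) -> SequenceFeatures:
    """Lagged autocorrelation per scale column, normalized by the column's
    population variance; mean and variance are taken over the full column.

    ``AC[lag, j] = (1/(n-lag)) * sum_i (S[i,j]-m_j)(S[i+lag,j]-m_j) / var_j``
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    mat = ts.matrix
    n, k = mat.shape
    if n == 0:
        raise TranslationError("empty translated sequence")
    if n < MIN_ADVISED_LENGTH:
        logger.warning(
            "sequence %r has length %d < %d; descriptors may be unreliable",
            ts.sequence_id,
            n,
            MIN_ADVISED_LENGTH,
        )
    centered = mat - mat.mean(axis=0)
    var = np.square(centered).mean(axis=0)  # population variance, divisor n
    # a constant column must yield zero AC; guard against fp residue in the mean
    constant = np.all(mat == mat[0:1, :], axis=0)
    ok = (~constant) & (var > 0.0)
    out = np.zeros((k, max_lag), dtype=np.float64)
    for lag in range(1, min(max_lag + 1, n)):
        prods = (centered[:-lag] * centered[lag:]).sum(axis=0) / (n - lag)
        out[ok, lag - 1] = prods[ok] / var[ok]
    return SequenceFeatures(
        sequence_id=ts.sequence_id, values=out.ravel(), max_lag=max_lag
    )


def sequence_features(
    seq: str,
    scales: ScaleSet,
    max_lag: int = DEFAULT_MAX_LAG,
    *,
    sequence_id: str = "",
    on_nonstandard: NonstandardPolicy = "strict",
) -> np.ndarray:
    """Convenience: translate + autocorrelation, returning the raw vector."""
    ts = translate(seq, scales, sequence_id=sequence_id, on_nonstandard=on_nonstandard)
    return autocorrelation(ts, max_lag).values


def pair_features(
    seq_a: str,
    seq_b: str,
    scales: ScaleSet,
    max_lag: int = DEFAULT_MAX_LAG,
    *,
    on_nonstandard: NonstandardPolicy = "strict",
) -> np.ndarray:
    """Ordered-pair descriptor: ``[features(A), features(B)]`` concatenated.

    Ordered by construction: swapping the arguments swaps the two halves.
    """
    fa = sequence_features(seq_a, scales, max_lag, on_nonstandard=on_nonstandard)
    fb = sequence_features(seq_b, scales, max_lag, on_nonstandard=on_nonstandard)
    return np.concatenate([fa, fb])


def invert_sequence(seq: str) -> str:
    """Character-reverse a sequence ('ANLMK' -> 'KMLNA')."""
    return seq[::-1]


def augment_pair(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    """The four training-time representations of an unordered pair.

    Returns ``[(A,B), (B,A), (A,B_inv), (B,A_inv)]`` where ``X_inv`` is the
    character-reversed sequence. Note the autocorrelation descriptor is
    reversal-invariant, so in feature space the last two representations
    coincide with the first two; the four orderings are kept as specified.
    """
    return [
        (seq_a, seq_b),
        (seq_b, seq_a),
        (seq_a, invert_sequence(seq_b)),
        (seq_b, invert_sequence(seq_a)),
    ]
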