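"""Proteome scanning and classifier evaluation (ROC, operating points,
permutation feature importance)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import gnn_model as gm
from . import rf_model as rm
from .consensus import ConsensusPipeline
from .curation import CuratedDataset, InteractionPair, SequenceRecord
from .features import MIN_ADVISED_LENGTH, TranslationError, translate
from .scales import ScaleSet, load_default_scale_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocSummary:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class ScanResult:
    """Ranked scan output: (target_id, score) rows, scores non-increasing,
    ties broken by target id; skipped ids are reported, not silently lost."""

    query_id: str
    method: str
    entries: tuple[tuple[str, float], ...]
    skipped: tuple[str, ...] = ()

    def top(self, k: int) -> tuple[tuple[str, float], ...]:
        return self.entries[:k]


def _check_two_classes(labels: np.ndarray) -> None:
    present = set(np.unique(labels))
    if present != {0, 1}:
        raise ValueError(f"need both classes present, got labels {sorted(present)}")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC points and trapezoid AUC. The AUC equals the probability that a
    random positive outscores a random negative, ties counted half."""
    y = np.asarray(labels, dtype=np.int64).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(roc_auc_score(y, s)))


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> RocSummary:
    """Operating-point summary: binder iff score >= threshold."""
    y = np.asarray(labels, dtype=np.int64).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    _check_two_classes(y)
    pred = (s >= threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return RocSummary(
        auc=float(roc_auc_score(y, s)),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        threshold=threshold,
    )


def _method_tag(model: object) -> str:
    if isinstance(model, rm.TrainedPPIModel):
        return "rf"
    if isinstance(model, gm.GNNModel):
        return "gnn"
    if isinstance(model, ConsensusPipeline):
        return "consensus"
    return type(model).__name__


def _batch_scorer(
    model: object, scales: ScaleSet | None
) -> Callable[[Sequence[InteractionPair], CuratedDataset], np.ndarray]:
    if isinstance(model, rm.TrainedPPIModel):
        return lambda pairs, ds: rm.predict_pairs(model, pairs, ds, scales)
    if isinstance(model, gm.GNNModel):
        return lambda pairs, ds: gm.predict_gnn_pairs(model, pairs, ds, scales)
    if isinstance(model, ConsensusPipeline):
        return lambda pairs, ds: model.predict_pairs(pairs, ds, scales)
    raise TypeError(f"cannot score with model of type {type(model).__name__}")


def scan_proteome(
    model: object,
    query_seq: str,
    db: str | Path,
    scales: ScaleSet | None = None,
    query_id: str = "query",
) -> ScanResult:
    """Score the query against every sequence of a FASTA database.

    Sequences shorter than the advised minimum (16 residues) are scored
    anyway with a logged warning; untranslatable database entries are
    skipped with a warning and listed in the result.
    """
    db = Path(db)
    if not db.exists():
        raise FileNotFoundError(f"database FASTA not found: {db}")
    scales = scales if scales is not None else load_default_scale_set()
    records = list(SeqIO.parse(str(db), "fasta"))
    if not records:
        raise ValueError(f"database FASTA is empty or unreadable: {db}")
    query_seq = "".join(query_seq.split()).upper()
    translate(query_seq, scales, sequence_id=query_id)  # strict: bad query errors
    if len(query_seq) < MIN_ADVISED_LENGTH:
        logger.warning(
            "query length %d is below the advised minimum of %d; scanning anyway",
            len(query_seq),
            MIN_ADVISED_LENGTH,
        )
    ds = CuratedDataset()
    ds.sequences[query_id] = SequenceRecord(id=query_id, seq=query_seq)
    targets: list[str] = []
    skipped: list[str] = []
    for rec in records:
        seq = str(rec.seq).upper()
        try:
            translate(seq, scales, sequence_id=rec.id)
        except TranslationError as exc:
            logger.warning("skipping database entry %r: %s", rec.id, exc)
            skipped.append(rec.id)
            continue
        if len(seq) < MIN_ADVISED_LENGTH:
            logger.warning(
                "database entry %r has length %d < %d; scoring anyway",
                rec.id,
                len(seq),
                MIN_ADVISED_LENGTH,
            )
        ds.sequences[rec.id] = SequenceRecord(id=rec.id, seq=seq)
        targets.append(rec.id)
    if not targets:
        raise ValueError("no translatable sequences in database")
    pairs = [InteractionPair(id_a=query_id, id_b=t, label=0) for t in targets]
    scores = _batch_scorer(model, scales)(pairs, ds)
    ranked = sorted(zip(targets, scores.tolist()), key=lambda kv: (-kv[1], kv[0]))
    return ScanResult(
        query_id=query_id,
        method=_method_tag(model),
        entries=tuple(ranked),
        skipped=tuple(skipped),
    )


def write_scan_tsv(result: ScanResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# query: {result.query_id}\tmethod: {result.method}\n")
        fh.write("rank\ttarget_id\tscore\n")
        for rank, (tid, score) in enumerate(result.entries, 1):
            fh.write(f"{rank}\t{tid}\t{score:.6f}\n")
        for tid in result.skipped:
            fh.write(f"# skipped: {tid}\n")


def permutation_feature_importance(
    model: rm.TrainedPPIModel,
    test_pairs: Sequence[InteractionPair],
    dataset: CuratedDataset,
    feature_block: str,
    seed: int = 0,
    scales: ScaleSet | None = None,
    threshold: float = 0.5,
    n_repeats: int = 1,
) -> dict[str, float]:
    """Performance loss from shuffling one scale's descriptor block.

    The block is that scale's max_lag-long slice in *both* halves of the
    pair vector. Values are shuffled jointly across the test set (seeded),
    metrics recomputed on single-representation (A,B) features, and the
    mean drop (baseline minus permuted) returned for accuracy, sensitivity,
    specificity and AUC.
    """
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    model.check_compatible(scales)
    try:
        j = model.scale_names.index(feature_block)
    except ValueError:
        raise KeyError(
            f"unknown feature block {feature_block!r}; available: {model.scale_names}"
        ) from None
    cache = rm._FeatureCache(scales, model.max_lag)
    x = np.vstack([cache.pair(*dataset.resolve(p)) for p in test_pairs])
    y = np.asarray([p.label for p in test_pairs], dtype=np.int64)
    _check_two_classes(y)
    base = confusion_at_threshold(model.predict_matrix(x), y, threshold)
    lag = model.max_lag
    half = len(model.scale_names) * lag
    cols = np.concatenate(
        [np.arange(j * lag, (j + 1) * lag), np.arange(half + j * lag, half + (j + 1) * lag)]
    )
    rng = np.random.default_rng(seed)
    deltas = {"accuracy": 0.0, "sensitivity": 0.0, "specificity": 0.0, "auc": 0.0}
    for _ in range(n_repeats):
        perm = rng.permutation(x.shape[0])
        xp = x.copy()
        xp[:, cols] = x[perm][:, cols]
        got = confusion_at_threshold(model.predict_matrix(xp), y, threshold)
        deltas["accuracy"] += base.accuracy - got.accuracy
        deltas["sensitivity"] += base.sensitivity - got.sensitivity
        deltas["specificity"] += base.specificity - got.specificity
        deltas["auc"] += base.auc - got.auc
    return {k: v / n_repeats for k, v in deltas.items()}
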