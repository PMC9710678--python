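"""Random-forest interaction classifier on pair autocorrelation descriptors.

Training expands every pair into its four representations — (A,B), (B,A),
(A,B_inv), (B,A_inv) — each inheriting the pair label, and fits an unpruned
bagged forest (default 750 trees, 20 features per split) on the resulting
420-dimensional vectors. Prediction scores all four representations of the
query pair and averages the forest vote fractions, which makes the score
exactly symmetric under argument swap.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import features as feat
from .curation import CuratedDataset, InteractionPair
from .scales import ScaleSet, load_default_scale_set

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class RFConfig:
    n_trees: int = 750
    mtry: int = 20  # features considered per split; ~ floor(sqrt(420))
    seed: int = 0
    max_lag: int = feat.DEFAULT_MAX_LAG
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class ModelFormatError(ValueError):
    """Raised when a stored model is corrupt or mismatches the session config."""


@dataclass
class TrainedPPIModel:
    forest: RandomForestClassifier
    scale_names: tuple[str, ...]
    max_lag: int
    config: RFConfig
    training_fingerprint: str = ""
    _feature_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_features(self) -> int:
        return 2 * len(self.scale_names) * self.max_lag

    def check_compatible(self, scales: ScaleSet, max_lag: int | None = None) -> None:
        if scales.names != self.scale_names:
            raise ModelFormatError(
                f"scale configuration mismatch: model was trained with "
                f"{self.scale_names}, session uses {scales.names}"
            )
        if max_lag is not None and max_lag != self.max_lag:
            raise ModelFormatError(
                f"max_lag mismatch: model was trained with max_lag={self.max_lag}, "
                f"session uses max_lag={max_lag}"
            )

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        """Vote fraction for the binder class per feature row."""
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ModelFormatError(
                f"feature matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, "
                f"model expects {self.n_features}"
            )
        return self.forest.predict_proba(x)[:, 1]


class _FeatureCache:
    """Per-sequence descriptor cache; augmentation reuses the same strings."""

    def __init__(self, scales: ScaleSet, max_lag: int):
        self.scales = scales
        self.max_lag = max_lag
        self._store: dict[str, np.ndarray] = {}

    def get(self, seq: str) -> np.ndarray:
        v = self._store.get(seq)
        if v is None:
            v = feat.sequence_features(seq, self.scales, self.max_lag)
            self._store[seq] = v
        return v

    def pair(self, seq_a: str, seq_b: str) -> np.ndarray:
        return np.concatenate([self.get(seq_a), self.get(seq_b)])


def build_training_matrix(
    pairs: Sequence[InteractionPair],
    dataset: CuratedDataset,
    scales: ScaleSet,
    max_lag: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand pairs 4-way and featurize; returns (X, y) with 4 rows per pair."""
    cache = _FeatureCache(scales, max_lag)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for p in pairs:
        seq_a, seq_b = dataset.resolve(p)
        for ra, rb in feat.augment_pair(seq_a, seq_b):
            rows.append(cache.pair(ra, rb))
            labels.append(p.label)
    return np.vstack(rows), np.asarray(labels, dtype=np.int64)


def _fingerprint(pairs: Sequence[InteractionPair]) -> str:
    h = hashlib.sha256()
    for key, label in sorted((p.key, p.label) for p in pairs):
        h.update(f"{key[0]}\t{key[1]}\t{label}\n".encode())
    return h.hexdigest()[:16]


def train_rf(
    dataset: CuratedDataset,
    scales: ScaleSet | None = None,
    config: RFConfig | None = None,
    pairs: Sequence[InteractionPair] | None = None,
) -> TrainedPPIModel:
    """Fit the forest on the dataset's training pairs (or an explicit list).

    Raises ``ValueError`` if only one class is present.
    """
    scales = scales if scales is not None else load_default_scale_set()
    config = config if config is not None else RFConfig()
    pairs = list(pairs if pairs is not None else dataset.train)
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError(f"training data must contain both classes, got labels {labels}")
    x, y = build_training_matrix(pairs, dataset, scales, config.max_lag)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.mtry,
        max_depth=None,  # grown unpruned
        bootstrap=True,
        random_state=config.seed,
        n_jobs=config.n_jobs,
    )
    forest.fit(x, y)
    logger.info("trained forest: %d trees on %d rows (%d pairs x 4)", config.n_trees, len(y), len(pairs))
    return TrainedPPIModel(
        forest=forest,
        scale_names=scales.names,
        max_lag=config.max_lag,
        config=config,
        training_fingerprint=_fingerprint(pairs),
    )


def predict_pair(
    model: TrainedPPIModel,
    seq_a: str,
    seq_b: str,
    scales: ScaleSet | None = None,
) -> float:
    """Binder propensity in [0, 1]: forest vote fraction averaged over the
    four pair representations. Symmetric: score(A,B) == score(B,A)."""
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    model.check_compatible(scales)
    cache = _FeatureCache(scales, model.max_lag)
    rows = np.vstack(
        [cache.pair(ra, rb) for ra, rb in feat.augment_pair(seq_a, seq_b)]
    )
    # swapping A and B permutes the four representations, so averaging in
    # sorted order makes the score exactly symmetric (fp-order independent)
    return float(np.sort(model.predict_matrix(rows)).sum() / 4.0)


def predict_pairs(
    model: TrainedPPIModel,
    pairs: Sequence[InteractionPair],
    dataset: CuratedDataset,
    scales: ScaleSet | None = None,
) -> np.ndarray:
    """Vectorized scoring of many pairs (shared per-sequence cache)."""
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    model.check_compatible(scales)
    cache = _FeatureCache(scales, model.max_lag)
    rows: list[np.ndarray] = []
    for p in pairs:
        seq_a, seq_b = dataset.resolve(p)
        for ra, rb in feat.augment_pair(seq_a, seq_b):
            rows.append(cache.pair(ra, rb))
    scores = model.predict_matrix(np.vstack(rows))
    return np.sort(scores.reshape(len(pairs), 4), axis=1).sum(axis=1) / 4.0


def save_model(model: TrainedPPIModel, path: str) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "kind": "seqppi-rf",
        "scale_names": model.scale_names,
        "max_lag": model.max_lag,
        "config": model.config,
        "training_fingerprint": model.training_fingerprint,
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(
    path: str,
    expected_scales: ScaleSet | None = None,
    expected_max_lag: int | None = None,
) -> TrainedPPIModel:
    """Load a stored model, verifying format and (optionally) that its
    feature metadata matches the session configuration."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt pickle, truncated file, wrong format
        raise ModelFormatError(f"cannot read model file {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "seqppi-rf":
        raise ModelFormatError(f"{path!r} is not a seqppi random-forest model file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    model = TrainedPPIModel(
        forest=payload["forest"],
        scale_names=tuple(payload["scale_names"]),
        max_lag=int(payload["max_lag"]),
        config=payload["config"],
        training_fingerprint=payload.get("training_fingerprint", ""),
    )
    if expected_scales is not None or expected_max_lag is not None:
        model.check_compatible(
            expected_scales
            if expected_scales is not None
            else load_default_scale_set(model.scale_names),
            expected_max_lag,
        )
    return model
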