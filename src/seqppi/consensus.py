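"""Consensus combiner: a 2-8-8-1 network over the two base predictors' scores.

The forest and the graph network produce score distributions of different
shape, so a learned nonlinear combiner is used instead of a linear blend.
Architecture: 2 inputs, two hidden layers of 8 (leaky-ReLU), one sigmoid
output — 105 parameters. To avoid leakage, the base scores used for
training must come from predictions on data the base models were not
trained on; :func:`train_consensus_pipeline` handles the internal split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import gnn_model as gm
from . import rf_model as rm
from .curation import CuratedDataset, InteractionPair
from .nn import AdamW, MLP, Tensor, bce_with_logits
from .scales import ScaleSet


@dataclass
class ConsensusConfig:
    learning_rate: float = 1e-2
    epochs: int = 2000
    seed: int = 0
    weight_decay: float = 0.01
    patience: int = 300  # early stop when loss plateaus this many epochs
    min_delta: float = 1e-5


class ConsensusNet:
    """Fully connected 2-8-8-1 scorer (105 parameters)."""

    LAYER_SIZES = [2, 8, 8, 1]

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.mlp = MLP(self.LAYER_SIZES, rng, slope=0.01)

    @property
    def n_params(self) -> int:
        return self.mlp.n_params

    def zero_params(self) -> None:
        for p in self.mlp.params:
            p.data[:] = 0.0

    def _logits(self, rf: np.ndarray, gnn: np.ndarray) -> np.ndarray:
        x = np.column_stack([rf, gnn]).astype(np.float64)
        return self.mlp(Tensor(x)).data.astype(np.float64).ravel()

    def score(self, rf: np.ndarray, gnn: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self._logits(rf, gnn)))


def _validate_scores(name: str, scores: np.ndarray) -> np.ndarray:
    arr = np.asarray(scores, dtype=np.float64).ravel()
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError(f"{name} scores must lie in [0, 1]")
    return arr


def train_consensus(
    rf_scores: Sequence[float],
    gnn_scores: Sequence[float],
    labels: Sequence[int],
    seed: int = 0,
    config: ConsensusConfig | None = None,
) -> ConsensusNet:
    """Fit the combiner on held-out base-model scores (binary cross-entropy,
    AdamW, early stop on loss plateau). Deterministic under ``seed``."""
    config = config if config is not None else ConsensusConfig(seed=seed)
    rf = _validate_scores("rf", np.asarray(rf_scores))
    gnn = _validate_scores("gnn", np.asarray(gnn_scores))
    y = np.asarray(labels, dtype=np.float64).ravel()
    if not (len(rf) == len(gnn) == len(y)):
        raise ValueError(
            f"length mismatch: rf={len(rf)}, gnn={len(gnn)}, labels={len(y)}"
        )
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes")
    net = ConsensusNet(seed=seed)
    x = np.column_stack([rf, gnn])
    opt = AdamW(net.mlp.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    best, stale = np.inf, 0
    for _ in range(config.epochs):
        logits = net.mlp(Tensor(x))
        loss = bce_with_logits(logits, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        cur = float(loss.data)
        if cur < best - config.min_delta:
            best, stale = cur, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return net


def predict_consensus(net: ConsensusNet, rf_score: float, gnn_score: float) -> float:
    """Combined binder propensity in (0, 1)."""
    if not (0.0 <= rf_score <= 1.0 and 0.0 <= gnn_score <= 1.0):
        raise ValueError("base scores must lie in [0, 1]")
    return float(net.score(np.array([rf_score]), np.array([gnn_score]))[0])


@dataclass
class ConsensusPipeline:
    """Base models plus the trained combiner, ready for end-to-end scoring."""

    rf: rm.TrainedPPIModel
    gnn: gm.GNNModel
    net: ConsensusNet

    def predict_pairs(
        self,
        pairs: Sequence[InteractionPair],
        dataset: CuratedDataset,
        scales: ScaleSet | None = None,
    ) -> np.ndarray:
        rf_s = rm.predict_pairs(self.rf, pairs, dataset, scales)
        gnn_s = gm.predict_gnn_pairs(self.gnn, pairs, dataset, scales)
        return self.net.score(rf_s, gnn_s)


def save_pipeline(pipeline: ConsensusPipeline, path: str) -> None:
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "kind": "seqppi-consensus",
            "rf": pipeline.rf,
            "gnn_config": pipeline.gnn.config,
            "gnn_scale_names": pipeline.gnn.scale_names,
            "gnn_state": {
                name: getattr(pipeline.gnn, name).state()
                for name in (
                    "node_encoder",
                    "edge_mlp",
                    "node_mlp",
                    "global_mlp",
                    "pair_head",
                )
            },
            "net_state": pipeline.net.mlp.state(),
        },
        path,
    )


def load_pipeline(path: str) -> ConsensusPipeline:
    import joblib

    from .rf_model import ModelFormatError

    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "seqppi-consensus":
        raise ModelFormatError(f"{path!r} is not a seqppi consensus model file")
    gnn = gm.GNNModel(payload["gnn_config"], tuple(payload["gnn_scale_names"]))
    for name, arrays in payload["gnn_state"].items():
        getattr(gnn, name).load_state(arrays)
    net = ConsensusNet()
    net.mlp.load_state(payload["net_state"])
    return ConsensusPipeline(rf=payload["rf"], gnn=gnn, net=net)


def train_consensus_pipeline(
    dataset: CuratedDataset,
    scales: ScaleSet | None = None,
    rf_config: rm.RFConfig | None = None,
    gnn_config: gm.GNNConfig | None = None,
    consensus_config: ConsensusConfig | None = None,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> ConsensusPipeline:
    """Leakage-safe consensus training: base models fit on 80% of the
    training pairs, the combiner on their scores for the remaining 20%."""
    from .curation import split_train_test

    base_pairs, holdout = split_train_test(dataset.train, holdout_fraction, seed)
    rf = rm.train_rf(dataset, scales, rf_config, pairs=base_pairs)
    gnn = gm.train_gnn(dataset, gnn_config, scales, pairs=base_pairs)
    rf_s = rm.predict_pairs(rf, holdout, dataset, scales)
    gnn_s = gm.predict_gnn_pairs(gnn, holdout, dataset, scales)
    labels = [p.label for p in holdout]
    net = train_consensus(rf_s, gnn_s, labels, seed=seed, config=consensus_config)
    return ConsensusPipeline(rf=rf, gnn=gnn, net=net)
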