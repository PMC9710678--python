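"""Graph-network interaction predictor on residue chain graphs.

Each sequence becomes a graph: one node per residue carrying its raw
per-residue scale profile, edges between consecutive residues (stored as two
directed edges per adjacency so both residues message each other). Node
profiles are encoded to 32 dimensions by a learned MLP; edge features start
as 32-dimensional all-ones vectors; a 128-dimensional global feature starts
at zero. Five message-passing rounds then update, in order, edges (from
endpoint nodes + edge state), nodes (from mean of incident updated edges +
node state) and the global feature (from mean node state, mean edge state
and previous global state). The final global feature is the 128-dim
sequence readout; a pair is scored by concatenating both readouts into a
256-dim vector fed to a final MLP with sigmoid output.

Training minimizes binary cross-entropy with AdamW at a main learning rate
followed by a refinement phase at a lower rate. All tensor math is plain
numpy via :mod:`seqppi.nn` (reverse-mode autodiff), float32, single CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np

from .curation import CuratedDataset, InteractionPair
from .features import NonstandardPolicy, translate
from .nn import (
    DTYPE,
    AdamW,
    MLP,
    Tensor,
    add,
    bce_with_logits,
    chain_incoming_mean,
    concat,
    gather_rows,
    masked_mean_axis1,
    narrow,
    reshape,
    segment_mean,
)
from .rf_model import ModelFormatError
from .scales import ScaleSet, load_default_scale_set

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class GNNConfig:
    node_dim: int = 32
    graph_dim: int = 128
    rounds: int = 5
    learning_rate: float = 1e-5
    refine_learning_rate: float = 1e-7
    epochs: int = 350
    refine_epochs: int = 50
    seed: int = 0
    profile_count: int = 7  # raw per-residue scales fed to the node encoder
    batch_size: int = 128
    leaky_slope: float = 0.01
    weight_decay: float = 0.01
    head_hidden: int = 64

    def __post_init__(self) -> None:
        for name in ("node_dim", "graph_dim", "rounds", "epochs", "profile_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def desk_scale(self, epochs: int = 200, learning_rate: float = 1e-3) -> "GNNConfig":
        """Small-data variant: fewer epochs, faster learning rate, no refine."""
        return replace(
            self, epochs=epochs, learning_rate=learning_rate, refine_epochs=0
        )


@dataclass(frozen=True)
class SequenceGraph:
    """Chain graph for one sequence: raw node profiles + directed edge list."""

    sequence_id: str
    node_raw: np.ndarray  # (n, profile_count) float32
    edge_src: np.ndarray  # (2*(n-1),) int64
    edge_dst: np.ndarray  # (2*(n-1),) int64

    @property
    def n_nodes(self) -> int:
        return int(self.node_raw.shape[0])

    @property
    def n_edges(self) -> int:
        """Directed edge count: 2 per undirected adjacency."""
        return int(self.edge_src.shape[0])


def build_graph(
    seq: str,
    scales: ScaleSet,
    *,
    sequence_id: str = "",
    on_nonstandard: NonstandardPolicy = "strict",
) -> SequenceGraph:
    """Construct the residue chain graph with raw scale profiles as node input."""
    ts = translate(seq, scales, sequence_id=sequence_id, on_nonstandard=on_nonstandard)
    n = ts.length
    if n == 1:
        logger.warning("sequence %r has a single residue: graph has no edges", sequence_id)
        src = np.empty(0, dtype=np.int64)
        dst = np.empty(0, dtype=np.int64)
    else:
        fwd = np.arange(n - 1, dtype=np.int64)
        src = np.concatenate([fwd, fwd + 1])
        dst = np.concatenate([fwd + 1, fwd])
    return SequenceGraph(
        sequence_id=sequence_id,
        node_raw=ts.matrix.astype(DTYPE),
        edge_src=src,
        edge_dst=dst,
    )


class GNNModel:
    """Parameter container: encoder, edge/node/global update MLPs, pair head."""

    def __init__(self, config: GNNConfig, scale_names: tuple[str, ...]):
        if len(scale_names) != config.profile_count:
            raise ValueError(
                f"profile_count={config.profile_count} but {len(scale_names)} scales given"
            )
        self.config = config
        self.scale_names = tuple(scale_names)
        rng = np.random.default_rng(config.seed)
        nd, gd, s = config.node_dim, config.graph_dim, config.leaky_slope
        self.node_encoder = MLP([config.profile_count, nd, nd], rng, slope=s)
        self.edge_mlp = MLP([3 * nd, nd, nd], rng, slope=s)
        self.node_mlp = MLP([2 * nd, nd, nd], rng, slope=s)
        self.global_mlp = MLP([2 * nd + gd, gd, gd], rng, slope=s)
        self.pair_head = MLP([2 * gd, config.head_hidden, 1], rng, slope=s)
        self.loss_history: list[float] = []

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for mlp in (
            self.node_encoder,
            self.edge_mlp,
            self.node_mlp,
            self.global_mlp,
            self.pair_head,
        ):
            out.extend(mlp.params)
        return out

    def zero_params(self) -> None:
        """Analytic limit helper: with all parameters zero, the sigmoid head
        outputs exactly 0.5 for every input."""
        for p in self.params:
            p.data[:] = 0.0


def _stack_graphs(
    graphs: Sequence[SequenceGraph],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Concatenate graphs into one disjoint batch graph."""
    xs, srcs, dsts, ngids, egids = [], [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        xs.append(g.node_raw)
        srcs.append(g.edge_src + offset)
        dsts.append(g.edge_dst + offset)
        ngids.append(np.full(g.n_nodes, gid, dtype=np.int64))
        egids.append(np.full(g.n_edges, gid, dtype=np.int64))
        offset += g.n_nodes
    return (
        np.concatenate(xs, axis=0),
        np.concatenate(srcs),
        np.concatenate(dsts),
        np.concatenate(ngids),
        np.concatenate(egids),
        len(graphs),
    )


class _DenseBatch:
    """Graphs padded to a common length for slice-based message passing.

    Chain topology makes gather/scatter unnecessary: the two endpoint nodes
    of every adjacency are the ``[:-1]`` and ``[1:]`` slices of the padded
    node tensor, and a node's incoming edges are one shifted slice of each
    directed edge tensor. Padded slots are zero-masked wherever they feed an
    aggregation, so the result matches the per-edge formulation exactly (up
    to float summation order).
    """

    __slots__ = ("x", "node_mask", "edge_mask", "inv_deg", "inv_n", "inv_e", "n_graphs", "max_len")

    def __init__(self, graphs: Sequence[SequenceGraph]):
        lengths = np.array([g.n_nodes for g in graphs], dtype=np.int64)
        b = len(graphs)
        lmax = int(lengths.max())
        p = graphs[0].node_raw.shape[1]
        self.n_graphs = b
        self.max_len = lmax
        self.x = np.zeros((b, lmax, p), dtype=DTYPE)
        for i, g in enumerate(graphs):
            self.x[i, : g.n_nodes] = g.node_raw
        pos = np.arange(lmax)
        self.node_mask = (pos[None, :] < lengths[:, None]).astype(DTYPE)[..., None]
        epos = np.arange(max(lmax - 1, 0))
        self.edge_mask = (epos[None, :] < (lengths - 1)[:, None]).astype(DTYPE)[..., None]
        # in-degree: 2 for interior nodes, 1 for chain ends, 0 for padding
        deg = np.zeros((b, lmax), dtype=DTYPE)
        for i, n in enumerate(lengths):
            if n >= 2:
                deg[i, :n] = 2.0
                deg[i, 0] = deg[i, n - 1] = 1.0
        with np.errstate(divide="ignore"):
            self.inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-9), 0.0)[..., None].astype(DTYPE)
        self.inv_n = (1.0 / lengths).astype(DTYPE)[:, None]
        n_edges = 2.0 * np.maximum(lengths - 1, 0)
        with np.errstate(divide="ignore"):
            self.inv_e = np.where(n_edges > 0, 1.0 / np.maximum(n_edges, 1e-9), 0.0).astype(DTYPE)[:, None]


def _readout_dense(model: GNNModel, db: _DenseBatch) -> Tensor:
    cfg = model.config
    b, lmax, p = db.x.shape
    nd, gd = cfg.node_dim, cfg.graph_dim
    lm1 = max(lmax - 1, 0)
    h = reshape(model.node_encoder(reshape(Tensor(db.x), (b * lmax, p))), (b, lmax, nd))
    e_f = Tensor(np.ones((b, lm1, nd), dtype=DTYPE))  # edges i -> i+1
    e_b = Tensor(np.ones((b, lm1, nd), dtype=DTYPE))  # edges i+1 -> i
    g = Tensor(np.zeros((b, gd), dtype=DTYPE))
    for _ in range(cfg.rounds):
        h_lo = narrow(h, 1, 0, lm1)
        h_hi = narrow(h, 1, 1, lm1)
        fwd_in = reshape(concat([h_lo, h_hi, e_f], axis=2), (b * lm1, 3 * nd))
        bwd_in = reshape(concat([h_hi, h_lo, e_b], axis=2), (b * lm1, 3 * nd))
        e_out = model.edge_mlp(concat([fwd_in, bwd_in], axis=0))
        e_f = reshape(narrow(e_out, 0, 0, b * lm1), (b, lm1, nd))
        e_b = reshape(narrow(e_out, 0, b * lm1, b * lm1), (b, lm1, nd))
        agg = chain_incoming_mean(e_f, e_b, db.edge_mask, db.inv_deg)
        h = reshape(
            model.node_mlp(reshape(concat([agg, h], axis=2), (b * lmax, 2 * nd))),
            (b, lmax, nd),
        )
        node_agg = masked_mean_axis1(h, db.node_mask, db.inv_n)
        edge_agg = add(
            masked_mean_axis1(e_f, db.edge_mask, db.inv_e),
            masked_mean_axis1(e_b, db.edge_mask, db.inv_e),
        )
        g = model.global_mlp(concat([node_agg, edge_agg, g], axis=1))
    return g


def _readout_batch(model: GNNModel, graphs: Sequence[SequenceGraph]) -> Tensor:
    """Encode + message passing; returns (n_graphs, graph_dim) readouts."""
    x, src, dst, ngid, egid, n_graphs = _stack_graphs(graphs)
    n_nodes = x.shape[0]
    cfg = model.config
    h = model.node_encoder(Tensor(x))
    e = Tensor(np.ones((src.shape[0], cfg.node_dim), dtype=DTYPE))
    g = Tensor(np.zeros((n_graphs, cfg.graph_dim), dtype=DTYPE))
    for _ in range(cfg.rounds):
        e = model.edge_mlp(concat([gather_rows(h, src), gather_rows(h, dst), e]))
        agg = segment_mean(e, dst, n_nodes)
        h = model.node_mlp(concat([agg, h]))
        node_agg = segment_mean(h, ngid, n_graphs)
        edge_agg = segment_mean(e, egid, n_graphs)
        g = model.global_mlp(concat([node_agg, edge_agg, g]))
    return g


def message_passing_round(
    model: GNNModel,
    graph: SequenceGraph,
    node_feat: np.ndarray,
    edge_feat: np.ndarray,
    global_feat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One explicit round on a single graph (inference only).

    Returns updated (node, edge, global) feature arrays; the graph topology
    is untouched. Update order: edges, then nodes, then global.
    """
    n = graph.n_nodes
    h = Tensor(np.asarray(node_feat, dtype=DTYPE))
    e = Tensor(np.asarray(edge_feat, dtype=DTYPE))
    g = Tensor(np.asarray(global_feat, dtype=DTYPE).reshape(1, -1))
    e2 = model.edge_mlp(
        concat([gather_rows(h, graph.edge_src), gather_rows(h, graph.edge_dst), e])
    )
    h2 = model.node_mlp(concat([segment_mean(e2, graph.edge_dst, n), h]))
    gid = np.zeros(n, dtype=np.int64)
    egid = np.zeros(graph.n_edges, dtype=np.int64)
    g2 = model.global_mlp(
        concat([segment_mean(h2, gid, 1), segment_mean(e2, egid, 1), g])
    )
    return h2.data, e2.data, g2.data.ravel()


def encode_sequence(
    model: GNNModel, seq: str, scales: ScaleSet | None = None
) -> np.ndarray:
    """128-dim graph-level representation of one sequence."""
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    _check_scales(model, scales)
    graph = build_graph(seq, scales)
    return _readout_batch(model, [graph]).data[0].copy()


def _check_scales(model: GNNModel, scales: ScaleSet) -> None:
    if scales.names != model.scale_names:
        raise ModelFormatError(
            f"scale configuration mismatch: model uses {model.scale_names}, "
            f"session uses {scales.names}"
        )


def _pair_logits(model: GNNModel, graphs: Sequence[SequenceGraph]) -> Tensor:
    """Graphs are ordered [A1..Ak, B1..Bk]; returns (k, 1) logits."""
    readouts = _readout_batch(model, graphs)
    k = len(graphs) // 2
    idx_a = np.arange(k, dtype=np.int64)
    idx_b = idx_a + k
    pair_vec = concat([gather_rows(readouts, idx_a), gather_rows(readouts, idx_b)])
    return model.pair_head(pair_vec)


def _pair_logits_dense(model: GNNModel, db: _DenseBatch) -> Tensor:
    """Dense-path logits; the batch holds 2k graphs ordered [A1..Ak, B1..Bk]."""
    readouts = _readout_dense(model, db)
    k = db.n_graphs // 2
    pair_vec = concat([narrow(readouts, 0, 0, k), narrow(readouts, 0, k, k)], axis=1)
    return model.pair_head(pair_vec)


def _sigmoid64(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))


def predict_gnn(
    model: GNNModel,
    seq_a: str,
    seq_b: str,
    scales: ScaleSet | None = None,
    symmetrize: bool = False,
) -> float:
    """Binder propensity in (0, 1). Order-sensitive by default (the pair
    vector is an ordered concatenation); ``symmetrize=True`` averages the
    scores of (A,B) and (B,A)."""
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    _check_scales(model, scales)
    ga = build_graph(seq_a, scales, sequence_id="A")
    gb = build_graph(seq_b, scales, sequence_id="B")
    if symmetrize:
        logits = _pair_logits(model, [ga, gb, gb, ga]).data.ravel()
        return float(_sigmoid64(logits).mean())
    logit = _pair_logits(model, [ga, gb]).data.ravel()[0]
    return float(_sigmoid64(np.asarray(logit)))


def predict_gnn_pairs(
    model: GNNModel,
    pairs: Sequence[InteractionPair],
    dataset: CuratedDataset,
    scales: ScaleSet | None = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Score many pairs in batches; returns scores in pair order."""
    scales = scales if scales is not None else load_default_scale_set(model.scale_names)
    _check_scales(model, scales)
    cache: dict[str, SequenceGraph] = {}

    def graph_of(seq_id: str) -> SequenceGraph:
        g = cache.get(seq_id)
        if g is None:
            g = build_graph(dataset.seq_of(seq_id), scales, sequence_id=seq_id)
            cache[seq_id] = g
        return g

    out = np.empty(len(pairs), dtype=np.float64)
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        graphs = [graph_of(p.id_a) for p in chunk] + [graph_of(p.id_b) for p in chunk]
        logits = _pair_logits_dense(model, _DenseBatch(graphs)).data.ravel()
        out[start : start + len(chunk)] = _sigmoid64(logits)
    return out


def train_gnn(
    dataset: CuratedDataset,
    config: GNNConfig | None = None,
    scales: ScaleSet | None = None,
    pairs: Sequence[InteractionPair] | None = None,
) -> GNNModel:
    """Train on the dataset's training pairs: binary cross-entropy, AdamW,
    main phase at ``learning_rate`` for ``epochs`` then ``refine_epochs`` at
    ``refine_learning_rate``. Deterministic under ``config.seed``.

    Raises ``RuntimeError`` if the loss diverges to NaN.
    """
    config = config if config is not None else GNNConfig()
    scales = scales if scales is not None else load_default_scale_set()
    pairs = list(pairs if pairs is not None else dataset.train)
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError(f"training data must contain both classes, got labels {labels}")
    if len(scales) != config.profile_count:
        raise ValueError(
            f"profile_count={config.profile_count} but scale set has {len(scales)} scales"
        )
    model = GNNModel(config, scales.names)
    graph_cache: dict[str, SequenceGraph] = {}

    def graph_of(seq_id: str) -> SequenceGraph:
        g = graph_cache.get(seq_id)
        if g is None:
            g = build_graph(dataset.seq_of(seq_id), scales, sequence_id=seq_id)
            graph_cache[seq_id] = g
        return g

    items = [(graph_of(p.id_a), graph_of(p.id_b), float(p.label)) for p in pairs]
    rng = np.random.default_rng(config.seed + 1)
    # fixed minibatch membership, bucketed by length to limit padding waste;
    # batch visit order is reshuffled every epoch
    perm = rng.permutation(len(items))
    by_len = sorted(perm, key=lambda i: max(items[int(i)][0].n_nodes, items[int(i)][1].n_nodes))
    batches: list[tuple[_DenseBatch, np.ndarray]] = []
    for start in range(0, len(by_len), config.batch_size):
        idx = [int(i) for i in by_len[start : start + config.batch_size]]
        graphs = [items[i][0] for i in idx] + [items[i][1] for i in idx]
        targets = np.array([items[i][2] for i in idx], dtype=np.float64)
        batches.append((_DenseBatch(graphs), targets))
    opt = AdamW(model.params, lr=config.learning_rate, weight_decay=config.weight_decay)
    schedule = [(config.learning_rate, config.epochs)]
    if config.refine_epochs > 0:
        schedule.append((config.refine_learning_rate, config.refine_epochs))
    for lr, n_epochs in schedule:
        opt.lr = lr
        for epoch in range(n_epochs):
            epoch_loss = 0.0
            for bi in rng.permutation(len(batches)):
                db, targets = batches[int(bi)]
                logits = _pair_logits_dense(model, db)
                loss = bce_with_logits(logits, targets)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(targets)
            model.loss_history.append(epoch_loss / len(items))
    return model


def save_gnn(model: GNNModel, path: str) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "kind": "seqppi-gnn",
        "config": model.config,
        "scale_names": model.scale_names,
        "state": {
            name: getattr(model, name).state()
            for name in ("node_encoder", "edge_mlp", "node_mlp", "global_mlp", "pair_head")
        },
    }
    joblib.dump(payload, path)


def load_gnn(path: str, expected_scales: ScaleSet | None = None) -> GNNModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "seqppi-gnn":
        raise ModelFormatError(f"{path!r} is not a seqppi graph-network model file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    model = GNNModel(payload["config"], tuple(payload["scale_names"]))
    for name, arrays in payload["state"].items():
        getattr(model, name).load_state(arrays)
    if expected_scales is not None:
        _check_scales(model, expected_scales)
    return model
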