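import logging

import numpy as np
import pytest

from seqppi import gnn_model as gm
from seqppi.gnn_model import GNNConfig, GNNModel
from seqppi.rf_model import ModelFormatError
from seqppi.scales import load_default_scale_set
from seqppi.synthetic import SyntheticConfig, generate_pair_dataset

from conftest import random_seq


@pytest.fixture(scope="module")
def tiny_gnn(scale_set):
    return GNNModel(GNNConfig(seed=3), scale_set.names)


@pytest.fixture(scope="module")
def tiny_trained(scale_set):
    ds = generate_pair_dataset(
        SyntheticConfig(
            n_pos=40, n_neg=40, seed=9, length_range=(16, 28), test_fraction=0.25
        )
    )
    cfg = GNNConfig(epochs=25, refine_epochs=0, learning_rate=1e-3, seed=2)
    return ds, gm.train_gnn(ds, cfg, scale_set)


class TestBuildGraph:
    def test_chain_topology(self, scale_set):
        g = gm.build_graph("ACDEFGHIKL", scale_set)
        assert g.n_nodes == 10
        assert g.n_edges == 18  # 9 undirected adjacencies, both directions
        undirected = {frozenset((int(s), int(d))) for s, d in zip(g.edge_src, g.edge_dst)}
        assert undirected == {frozenset((i, i + 1)) for i in range(9)}

    def test_node_features_are_raw_profiles(self, scale_set):
        g = gm.build_graph("ANL", scale_set)
        for i, aa in enumerate("ANL"):
            assert np.allclose(g.node_raw[i], [s.values[aa] for s in scale_set], atol=1e-6)

    def test_single_residue_warns(self, scale_set, caplog):
        with caplog.at_level(logging.WARNING):
            g = gm.build_graph("A", scale_set)
        assert g.n_nodes == 1 and g.n_edges == 0
        assert "single residue" in caplog.text


class TestArchitectureDimensions:
    def test_node_encoding_dim_32(self, tiny_gnn, scale_set):
        g = gm.build_graph("ACDEFGHIKL", scale_set)
        from seqppi.nn import Tensor

        h = tiny_gnn.node_encoder(Tensor(g.node_raw))
        assert h.data.shape == (10, 32)

    def test_edge_features_start_as_ones(self, tiny_gnn, scale_set):
        # the first round consumes all-ones edge features by construction
        g = gm.build_graph("ACDEF", scale_set)
        h, e, glob = gm.message_passing_round(
            tiny_gnn,
            g,
            node_feat=np.zeros((5, 32)),
            edge_feat=np.ones((8, 32)),
            global_feat=np.zeros(128),
        )
        assert e.shape == (8, 32)

    def test_readout_dim_128(self, tiny_gnn):
        vec = gm.encode_sequence(tiny_gnn, "ACDEFGHIKLMNPQRSTVWY")
        assert vec.shape == (128,)

    def test_default_rounds_five(self):
        assert GNNConfig().rounds == 5

    def test_pair_concat_dim_256(self, tiny_gnn, scale_set):
        ga = gm.build_graph("ACDEFGHIKL", scale_set, sequence_id="a")
        gb = gm.build_graph("MNPQRSTVWY", scale_set, sequence_id="b")
        readouts = gm._readout_batch(tiny_gnn, [ga, gb])
        assert readouts.data.shape == (2, 128)
        assert tiny_gnn.pair_head.sizes[0] == 256

    def test_profile_count_must_match_scales(self, scale_set):
        with pytest.raises(ValueError, match="profile_count"):
            GNNModel(GNNConfig(profile_count=13), scale_set.names)


class TestMessagePassingRound:
    def test_topology_preserved_and_deterministic(self, tiny_gnn, scale_set):
        g = gm.build_graph("ACDEFGHIK", scale_set)
        h0 = np.random.default_rng(0).normal(size=(9, 32)).astype(np.float32)
        e0 = np.ones((16, 32), dtype=np.float32)
        g0 = np.zeros(128, dtype=np.float32)
        h1, e1, g1 = gm.message_passing_round(tiny_gnn, g, h0, e0, g0)
        h2, e2, g2 = gm.message_passing_round(tiny_gnn, g, h0, e0, g0)
        assert h1.shape == h0.shape and e1.shape == e0.shape and g1.shape == (128,)
        assert np.array_equal(h1, h2) and np.array_equal(e1, e2) and np.array_equal(g1, g2)

    def test_edge_storage_order_irrelevant(self, tiny_gnn, scale_set):
        from dataclasses import replace

        g = gm.build_graph("ACDEFGHIK", scale_set)
        rng = np.random.default_rng(4)
        perm = rng.permutation(g.n_edges)
        g_perm = replace(g, edge_src=g.edge_src[perm], edge_dst=g.edge_dst[perm])
        h0 = rng.normal(size=(9, 32)).astype(np.float32)
        e0 = np.ones((16, 32), dtype=np.float32)
        g0 = np.zeros(128, dtype=np.float32)
        h1, _, gl1 = gm.message_passing_round(tiny_gnn, g, h0, e0, g0)
        h2, _, gl2 = gm.message_passing_round(tiny_gnn, g_perm, h0, e0[perm], g0)
        assert np.allclose(h1, h2, atol=1e-5)
        assert np.allclose(gl1, gl2, atol=1e-5)

    def test_dense_path_matches_sparse(self, tiny_gnn, scale_set, rng):
        graphs = [
            gm.build_graph(random_seq(rng, int(n)), scale_set, sequence_id=str(n))
            for n in rng.integers(5, 40, size=8)
        ]
        dense = gm._readout_dense(tiny_gnn, gm._DenseBatch(graphs)).data
        sparse = gm._readout_batch(tiny_gnn, graphs).data
        assert np.allclose(dense, sparse, atol=1e-3)


class TestPredict:
    def test_output_strictly_in_unit_interval(self, tiny_gnn, rng):
        for _ in range(4):
            s = gm.predict_gnn(tiny_gnn, random_seq(rng, 30), random_seq(rng, 30))
            assert 0.0 < s < 1.0

    def test_order_sensitive_by_default(self, tiny_trained, rng):
        _, model = tiny_trained
        a, b = random_seq(rng, 30), random_seq(rng, 40)
        assert gm.predict_gnn(model, a, b) != gm.predict_gnn(model, b, a)

    def test_symmetrize_flag(self, tiny_trained, rng):
        _, model = tiny_trained
        a, b = random_seq(rng, 30), random_seq(rng, 40)
        ab = gm.predict_gnn(model, a, b, symmetrize=True)
        ba = gm.predict_gnn(model, b, a, symmetrize=True)
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_zeroed_parameters_give_half(self, scale_set, rng):
        model = GNNModel(GNNConfig(seed=0), scale_set.names)
        model.zero_params()
        for _ in range(3):
            s = gm.predict_gnn(model, random_seq(rng, 25), random_seq(rng, 25))
            assert s == pytest.approx(0.5, abs=1e-7)

    def test_batch_matches_single(self, tiny_trained):
        ds, model = tiny_trained
        pairs = ds.test[:4]
        batch = gm.predict_gnn_pairs(model, pairs, ds)
        for p, s in zip(pairs, batch):
            single = gm.predict_gnn(model, ds.seq_of(p.id_a), ds.seq_of(p.id_b))
            assert s == pytest.approx(single, abs=2e-3)


class TestTrainGNN:
    def test_loss_decreases(self, tiny_trained):
        _, model = tiny_trained
        hist = model.loss_history
        assert hist[-1] < hist[0]
        assert min(hist[:20]) < hist[0]

    def test_seed_reproducibility(self, scale_set):
        ds = generate_pair_dataset(
            SyntheticConfig(
                n_pos=15, n_neg=15, seed=4, length_range=(16, 24), test_fraction=0.2
            )
        )
        cfg = GNNConfig(epochs=5, refine_epochs=0, learning_rate=1e-3, seed=6)
        a = gm.train_gnn(ds, cfg, scale_set)
        b = gm.train_gnn(ds, cfg, scale_set)
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa.data, pb.data)

    def test_single_class_rejected(self, scale_set):
        ds = generate_pair_dataset(
            SyntheticConfig(
                n_pos=6, n_neg=6, seed=1, length_range=(16, 24), test_fraction=0.2
            )
        )
        pos_only = [p for p in ds.train if p.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            gm.train_gnn(ds, GNNConfig(epochs=1), scale_set, pairs=pos_only)

    def test_refinement_phase_runs(self, scale_set):
        ds = generate_pair_dataset(
            SyntheticConfig(
                n_pos=10, n_neg=10, seed=2, length_range=(16, 24), test_fraction=0.2
            )
        )
        cfg = GNNConfig(
            epochs=3, refine_epochs=2, learning_rate=1e-3, refine_learning_rate=1e-5, seed=0
        )
        model = gm.train_gnn(ds, cfg, scale_set)
        assert len(model.loss_history) == 5


class TestSaveLoadGNN:
    def test_roundtrip(self, tiny_trained, tmp_path, rng):
        _, model = tiny_trained
        path = tmp_path / "gnn.joblib"
        gm.save_gnn(model, str(path))
        loaded = gm.load_gnn(str(path))
        for _ in range(5):
            a, b = random_seq(rng, 25), random_seq(rng, 30)
            assert gm.predict_gnn(loaded, a, b) == pytest.approx(
                gm.predict_gnn(model, a, b), abs=1e-9
            )

    def test_corrupted_rejected(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"\x00\x01garbage")
        with pytest.raises(ModelFormatError):
            gm.load_gnn(str(path))

    def test_scale_mismatch_rejected(self, tiny_trained, tmp_path):
        _, model = tiny_trained
        path = tmp_path / "gnn.joblib"
        gm.save_gnn(model, str(path))
        with pytest.raises(ModelFormatError, match="scale configuration"):
            gm.load_gnn(str(path), expected_scales=load_default_scale_set(["polarity"]))
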