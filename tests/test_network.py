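import numpy as np
import pytest

from conftest import random_rotation, transform_record
from _oracles import (
    dense_attention,
    dense_edge_update,
    dense_global_update,
    dense_node_update,
)
from graphfun import autodiff as ad
from graphfun.features import featurize
from graphfun.graph import ProteinGraph
from graphfun.network import (
    GNNConfig,
    GNNModel,
    attention_weights,
    edge_update,
    global_node_update,
    node_update,
    protein_scores,
    residue_scores,
    trunk_forward,
)


def _toy_graph(n, edges, d_node=6, d_edge=5, seed=0):
    rng = np.random.default_rng(seed)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    return ProteinGraph(
        n_nodes=n,
        edges=edges,
        ca_coords=rng.standard_normal((n, 3)),
        node_features=rng.standard_normal((n, d_node)),
        edge_features=rng.standard_normal((len(edges), d_edge)),
        meta={"protein_id": "toy"},
    )


def _model(graph, hidden=8, layers=1, seed=0, use_global=True,
           tasks=("ghost",), labels=()):
    return GNNModel(
        graph.node_features.shape[1], graph.edge_features.shape[1],
        GNNConfig(hidden=hidden, n_layers=layers, use_global=use_global,
                  residue_tasks=tasks, protein_labels=labels),
        seed=seed,
    )


def _states(graph, model):
    h = ad.Tensor(graph.node_features) @ model.params["node_in.W"] + model.params["node_in.b"]
    e = ad.Tensor(graph.edge_features) @ model.params["edge_in.W"] + model.params["edge_in.b"]
    return h, e


PATH3 = [(0, 1), (1, 0), (1, 2), (2, 1)]  # 3-node path graph


class TestAttention:
    def test_isolated_node_gets_alpha_one(self):
        g = _toy_graph(1, np.zeros((0, 2)))
        m = _model(g)
        h, e = _states(g, m)
        alpha, seg, _ = attention_weights(h, e, m, 0, g)
        assert alpha.value[0] == pytest.approx(1.0)

    def test_rows_sum_to_one_random_graph(self):
        rng = np.random.default_rng(1)
        from graphfun.graph import build_radius_graph
        from conftest import record_from_ca

        rec = record_from_ca(rng.uniform(0, 25, (20, 3)))
        topo = build_radius_graph(rec)
        g = _toy_graph(20, topo.edges, seed=1)
        m = _model(g, seed=2)
        h, e = _states(g, m)
        alpha, seg, _ = attention_weights(h, e, m, 0, g)
        sums = np.zeros(20)
        np.add.at(sums, seg, alpha.value)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        assert (alpha.value >= 0).all()

    def test_matches_dense_oracle_on_path_graph(self):
        g = _toy_graph(3, PATH3, seed=3)
        m = _model(g, hidden=4, seed=4)
        h, e = _states(g, m)
        alpha, seg, _ = attention_weights(h, e, m, 0, g)
        A = dense_attention(
            h.value, e.value, [tuple(x) for x in g.edges],
            m.params["layer0.WQ"].value, m.params["layer0.WK"].value,
            m.params["layer0.WE"].value, 4.0,
        )
        for k, (j, i) in enumerate(g.edges):
            assert alpha.value[k] == pytest.approx(A[j, i], abs=1e-9)
        for i in range(3):
            assert alpha.value[len(g.edges) + i] == pytest.approx(A[i, i], abs=1e-9)


class TestNodeUpdate:
    def test_zero_weights_residual_identity(self):
        g = _toy_graph(4, [(0, 1), (1, 0)], seed=5)
        m = _model(g, seed=6)
        m.params["layer0.WV"].value[:] = 0.0
        m.params["layer0.WE"].value[:] = 0.0
        h, e = _states(g, m)
        alpha, _, e_proj = attention_weights(h, e, m, 0, g)
        out = node_update(h, e, alpha, e_proj, m, 0, g)
        np.testing.assert_allclose(out.value, h.value, atol=1e-12)

    def test_isolated_node_single_term(self):
        g = _toy_graph(1, np.zeros((0, 2)), seed=7)
        m = _model(g, seed=8)
        m.params["layer0.WV"].value = np.eye(8)
        h, e = _states(g, m)
        alpha, _, e_proj = attention_weights(h, e, m, 0, g)
        out = node_update(h, e, alpha, e_proj, m, 0, g)
        np.testing.assert_allclose(out.value, 2 * h.value, atol=1e-12)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(9)
        edges = [(0, 1), (1, 0), (1, 2), (2, 1), (0, 4), (4, 0), (3, 4), (4, 3)]
        g = _toy_graph(5, edges, seed=9)
        m = _model(g, seed=10)
        h, e = _states(g, m)
        alpha, _, e_proj = attention_weights(h, e, m, 0, g)
        out = node_update(h, e, alpha, e_proj, m, 0, g)
        A = dense_attention(
            h.value, e.value, edges,
            m.params["layer0.WQ"].value, m.params["layer0.WK"].value,
            m.params["layer0.WE"].value, 8.0,
        )
        expected = dense_node_update(
            h.value, e.value, edges, A,
            m.params["layer0.WV"].value, m.params["layer0.WE"].value,
        )
        np.testing.assert_allclose(out.value, expected, atol=1e-9)


class TestEdgeUpdate:
    def test_zero_final_layer_is_identity(self):
        g = _toy_graph(3, PATH3, seed=11)
        m = _model(g, seed=12)
        m.params["layer0.mlp.W2"].value[:] = 0.0
        h, e = _states(g, m)
        out = edge_update(h, e, m, 0, g)
        np.testing.assert_allclose(out.value, e.value, atol=1e-12)

    def test_shape_preserved(self):
        g = _toy_graph(3, PATH3, seed=13)
        m = _model(g, seed=14)
        h, e = _states(g, m)
        assert edge_update(h, e, m, 0, g).value.shape == e.value.shape

    def test_matches_concat_mlp_oracle(self):
        from scipy.special import erf

        g = _toy_graph(3, PATH3, seed=15)
        m = _model(g, seed=16)
        h, e = _states(g, m)
        out = edge_update(h, e, m, 0, g)
        gelu = lambda x: x * 0.5 * (1 + erf(x / np.sqrt(2)))
        expected = dense_edge_update(
            h.value, e.value, [tuple(x) for x in g.edges],
            m.params["layer0.mlp.W1"].value, m.params["layer0.mlp.b1"].value,
            m.params["layer0.mlp.W2"].value, m.params["layer0.mlp.b2"].value,
            gelu,
        )
        np.testing.assert_allclose(out.value, expected, atol=1e-9)


class TestGlobalUpdate:
    def test_single_node_mean_is_projection(self):
        g = _toy_graph(1, np.zeros((0, 2)), seed=17)
        m = _model(g, seed=18)
        h, _ = _states(g, m)
        _, gstate = global_node_update(h, m, 0)
        expected = h.value @ m.params["layer0.glob.P"].value + m.params["layer0.glob.bP"].value
        np.testing.assert_allclose(gstate.value.ravel(), expected.ravel(), atol=1e-12)

    def test_permutation_invariance_of_global_state(self):
        g = _toy_graph(6, np.zeros((0, 2)), seed=19)
        m = _model(g, seed=20)
        h, _ = _states(g, m)
        out, gstate = global_node_update(h, m, 0)
        perm = np.random.default_rng(0).permutation(6)
        hp = ad.Tensor(h.value[perm])
        outp, gstatep = global_node_update(hp, m, 0)
        np.testing.assert_allclose(gstatep.value, gstate.value, atol=1e-12)
        np.testing.assert_allclose(outp.value, out.value[perm], atol=1e-12)

    def test_matches_dense_oracle(self):
        g = _toy_graph(4, np.zeros((0, 2)), seed=21)
        m = _model(g, seed=22)
        h, _ = _states(g, m)
        out, _ = global_node_update(h, m, 0)
        p = {k: m.params[f"layer0.glob.{k}"].value for k in ("P", "bP", "U", "bU", "V", "bV")}
        expected, _ = dense_global_update(h.value, p["P"], p["bP"], p["U"], p["bU"], p["V"], p["bV"])
        np.testing.assert_allclose(out.value, expected, atol=1e-9)

    def test_empty_graph_errors(self):
        m = _model(_toy_graph(2, np.zeros((0, 2))), seed=23)
        with pytest.raises(ValueError):
            global_node_update(ad.Tensor(np.zeros((0, 8))), m, 0)


class TestTrunk:
    def test_permutation_equivariance(self):
        edges = [(0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2)]
        g = _toy_graph(4, edges, seed=24)
        m = _model(g, layers=2, seed=25)
        h, _ = trunk_forward(g, m)
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        pedges = np.array([[inv[j], inv[i]] for j, i in edges])
        order = np.lexsort((pedges[:, 0], pedges[:, 1]))
        # edge feature rows are reordered together with the relabelled edges
        g2 = ProteinGraph(
            n_nodes=4, edges=pedges[order], ca_coords=g.ca_coords[perm],
            node_features=g.node_features[perm],
            edge_features=g.edge_features[order],
            meta={},
        )
        h2, _ = trunk_forward(g2, m)
        np.testing.assert_allclose(h2.value, h.value[perm], atol=1e-9)

    def test_zero_weights_reduce_to_projected_input(self):
        g = _toy_graph(4, PATH3, seed=26)
        m = _model(g, layers=3, seed=27)
        for name, p in m.params.items():
            if name.startswith("layer"):
                p.value[:] = 0.0
        h, e = trunk_forward(g, m)
        h0, e0 = _states(g, m)
        np.testing.assert_allclose(h.value, h0.value, atol=1e-12)
        np.testing.assert_allclose(e.value, e0.value, atol=1e-12)

    def test_composition_of_sub_operations(self):
        g = _toy_graph(3, PATH3, seed=28)
        m = _model(g, layers=1, seed=29)
        h, e = _states(g, m)
        alpha, _, e_proj = attention_weights(h, e, m, 0, g)
        hh = node_update(h, e, alpha, e_proj, m, 0, g)
        ee = edge_update(hh, e, m, 0, g)
        hg, _ = global_node_update(hh, m, 0)
        hf, ef = trunk_forward(g, m)
        np.testing.assert_allclose(hf.value, hg.value, atol=1e-12)
        np.testing.assert_allclose(ef.value, ee.value, atol=1e-12)

    def test_rigid_transform_invariance_end_to_end(self, small_record):
        from graphfun.features import structural_profile, StubEmbeddingProvider
        from graphfun.geometry import edge_geometric_features, node_geometric_features
        from graphfun.features import assemble_graph
        from graphfun.graph import build_radius_graph

        emb = StubEmbeddingProvider(8).embed(small_record.id, len(small_record))
        prof = structural_profile(small_record, n_points=120)
        topo = build_radius_graph(small_record)
        g1 = assemble_graph(
            small_record, topo, emb, prof,
            node_geometric_features(small_record),
            edge_geometric_features(small_record, topo.edges),
        )
        rng = np.random.default_rng(30)
        moved = transform_record(small_record, random_rotation(rng), rng.uniform(-20, 20, 3))
        topo2 = build_radius_graph(moved)
        g2 = assemble_graph(
            moved, topo2, emb, prof,
            node_geometric_features(moved),
            edge_geometric_features(moved, topo2.edges),
        )
        m = _model(g1, hidden=16, layers=2, seed=31)
        h1, _ = trunk_forward(g1, m)
        h2, _ = trunk_forward(g2, m)
        assert np.abs(h1.value - h2.value).max() <= 1e-4


class TestHeads:
    def test_zero_head_gives_half(self):
        g = _toy_graph(3, PATH3, seed=32)
        m = _model(g, seed=33)
        m.params["head.res.ghost.w"].value[:] = 0.0
        h, _ = trunk_forward(g, m)
        scores = residue_scores(h, m)["ghost"]
        np.testing.assert_allclose(scores.value, 0.5, atol=1e-12)

    def test_scores_strictly_inside_unit_interval(self):
        g = _toy_graph(3, PATH3, seed=34)
        m = _model(g, seed=35)
        h, _ = trunk_forward(g, m)
        s = residue_scores(h, m)["ghost"].value
        assert (s > 0).all() and (s < 1).all()

    def test_hand_set_head_matches_sigmoid_oracle(self):
        g = _toy_graph(2, [(0, 1), (1, 0)], seed=36)
        m = _model(g, seed=37)
        h, _ = trunk_forward(g, m)
        w = m.params["head.res.ghost.w"]
        b = m.params["head.res.ghost.b"]
        s = residue_scores(h, m)["ghost"].value.ravel()
        expected = 1 / (1 + np.exp(-(h.value @ w.value + b.value))).ravel()
        np.testing.assert_allclose(s, expected, atol=1e-9)

    def test_protein_head_uniform_pooling_is_mean(self):
        g = _toy_graph(5, np.zeros((0, 2)), seed=38)
        m = _model(g, seed=39, labels=("soluble",))
        m.params["head.prot.att"].value[:] = 0.0
        h, _ = trunk_forward(g, m)
        s = protein_scores(h, m)
        pooled = h.value.mean(axis=0)
        expected = 1 / (1 + np.exp(-(pooled @ m.params["head.prot.W"].value
                                     + m.params["head.prot.b"].value)))
        np.testing.assert_allclose(s.value.ravel(), expected, atol=1e-9)

    def test_single_residue_pooling_is_that_residue(self):
        g = _toy_graph(1, np.zeros((0, 2)), seed=40)
        m = _model(g, seed=41, labels=("a", "b"))
        h, _ = trunk_forward(g, m)
        s = protein_scores(h, m)
        expected = 1 / (1 + np.exp(-(h.value[0] @ m.params["head.prot.W"].value
                                     + m.params["head.prot.b"].value)))
        np.testing.assert_allclose(s.value.ravel(), expected, atol=1e-9)

    def test_attention_pooling_matches_oracle(self):
        g = _toy_graph(4, np.zeros((0, 2)), seed=42)
        m = _model(g, seed=43, labels=("x",))
        h, _ = trunk_forward(g, m)
        s = protein_scores(h, m)
        a = h.value @ m.params["head.prot.att"].value
        w = np.exp(a - a.max())
        w = w / w.sum()
        pooled = (w * h.value).sum(axis=0)
        expected = 1 / (1 + np.exp(-(pooled @ m.params["head.prot.W"].value
                                     + m.params["head.prot.b"].value)))
        np.testing.assert_allclose(s.value.ravel(), expected, atol=1e-9)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        g = _toy_graph(3, PATH3, seed=44)
        m = _model(g, layers=2, seed=45, labels=("l1",))
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = GNNModel.load(path)
        assert m2.config == m.config
        for k in m.params:
            np.testing.assert_allclose(
                m2.params[k].value, m.params[k].value, atol=1e-6
            )
        h1, _ = trunk_forward(g, m)
        h2, _ = trunk_forward(g, m2)
        np.testing.assert_allclose(h1.value, h2.value, atol=1e-12)

    def test_feature_dim_mismatch_errors(self):
        g = _toy_graph(3, PATH3, seed=46)
        m = _model(g, seed=47)
        bad = _toy_graph(3, PATH3, d_node=9, seed=48)
        with pytest.raises(ValueError):
            trunk_forward(bad, m)
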