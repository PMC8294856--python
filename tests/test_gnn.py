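import numpy as np
import pytest
from scipy import sparse

from graphgo.features import SignatureMatrix, SignatureVocabulary
from graphgo.gnn import (
    GnnModel,
    TrainConfig,
    bce_loss,
    dnn_interpro_forward,
    ensemble_average,
    gcn_forward,
    gnn_scores,
    input_forward,
    load_model,
    output_forward,
    predict,
    save_model,
    sigmoid,
    train,
    _gnn_batch_grads,
)
from graphgo.graph import ProteinGraph, batch_neighborhood, normalized_adjacency
from graphgo.homology import HomologyTable
from graphgo.scores import ScoreMatrix

from test_graph import random_graph


def tiny_config(**kw):
    defaults = dict(hidden_dim=8, batch_size=8, epochs=3, dropout=0.0, seeds=(0,))
    defaults.update(kw)
    return TrainConfig(**defaults)


def make_features(rng, proteins, m):
    vocab = SignatureVocabulary(tuple(f"S{j:03d}" for j in range(m)))
    x = sparse.csr_matrix((rng.random((len(proteins), m)) < 0.3).astype(float))
    return SignatureMatrix(proteins, vocab, x)


class TestForwards:
    def test_zero_input_weights_give_zero_representation(self):
        model = GnnModel(5, 3, ["t1", "t2", "t3"], tiny_config(), seed=0)
        model.params["W0"][:] = 0
        model.params["b0"][:] = 0
        x = sparse.random(4, 5, density=0.5, format="csr")
        assert np.all(input_forward(x, model) == 0)

    def test_zero_feature_row_maps_to_activated_bias(self):
        model = GnnModel(5, 3, list("abc"), tiny_config(), seed=1)
        model.params["b0"] = np.linspace(-1, 1, 8)
        x = sparse.csr_matrix((1, 5))
        assert np.allclose(input_forward(x, model)[0], np.maximum(model.params["b0"], 0))

    def test_forwards_match_scalar_loop_oracles(self):
        """Input, GCN and output layers against per-entry dense loops."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            n, m, d, k = 6, 5, 4, 3
            model = GnnModel(m, k, [f"t{i}" for i in range(k)],
                             tiny_config(hidden_dim=d), seed=int(rng.integers(1e6)))
            x = (rng.random((n, m)) < 0.4).astype(float)
            adj = sparse.csr_matrix(rng.random((n, n)))
            h0 = input_forward(sparse.csr_matrix(x), model)
            w0, b0 = model.params["W0"], model.params["b0"]
            for i in range(n):
                want = np.maximum(x[i] @ w0 + b0, 0)
                assert np.allclose(h0[i], want, atol=1e-6)
            w1, b1 = model.params["W1"], model.params["b1"]
            h1 = gcn_forward(h0, adj, w1, b1)
            dense_adj = adj.toarray()
            for i in range(n):
                agg = sum(dense_adj[i, j] * h0[j] for j in range(n))
                want = np.maximum(agg @ w1 + b1, 0) + h0[i]
                assert np.allclose(h1[i], want, atol=1e-6)
            scores = output_forward(h1, model)
            wo, bo = model.params["Wo"], model.params["bo"]
            for i in range(n):
                for j in range(k):
                    want = 1 / (1 + np.exp(-(wo[j] @ h1[i] + bo[j])))
                    assert scores[i, j] == pytest.approx(want, abs=1e-6)

    def test_zero_weight_gcn_collapses_to_identity(self):
        """With W=0, b=0 each residual layer is the identity, for any graph."""
        rng = np.random.default_rng(23)
        g = random_graph(rng, 12, p=0.4)
        adj = normalized_adjacency(g).matrix
        h = rng.random((12, 8))
        out = gcn_forward(h, adj, np.zeros((8, 8)), np.zeros(8))
        assert np.array_equal(out, h)

    def test_zero_output_params_score_half(self):
        model = GnnModel(4, 2, ["a", "b"], tiny_config(), seed=2)
        model.params["Wo"][:] = 0
        model.params["bo"][:] = 0
        assert np.all(output_forward(np.ones((3, 8)), model) == 0.5)

    def test_sigmoid_saturation(self):
        model = GnnModel(4, 1, ["a"], tiny_config(), seed=3)
        model.params["Wo"][:] = 0
        model.params["bo"][:] = 30.0
        assert output_forward(np.zeros((1, 8)), model)[0, 0] == pytest.approx(1.0, abs=1e-9)


class TestLoss:
    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bce_loss(y, y, [True, True]) <= 1e-10

    def test_uniform_half_scores_give_ln2(self):
        y = np.array([[1, 0, 1], [0, 0, 1]], dtype=float)
        loss = bce_loss(np.full((2, 3), 0.5), y, [True, True])
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_double_loop_oracle_with_mask(self):
        rng = np.random.default_rng(29)
        s = rng.uniform(0.01, 0.99, size=(4, 3))
        y = (rng.random((4, 3)) < 0.5).astype(float)
        mask = [True, False, True, True]
        total, n = 0.0, 0
        for i in range(4):
            if not mask[i]:
                continue
            for j in range(3):
                total += -(y[i, j] * np.log(s[i, j]) + (1 - y[i, j]) * np.log(1 - s[i, j]))
                n += 1
        assert bce_loss(s, y, mask) == pytest.approx(total / n, abs=1e-12)

    def test_empty_mask_is_hard_error(self):
        with pytest.raises(ValueError):
            bce_loss(np.ones((2, 2)) / 2, np.zeros((2, 2)), [False, False])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through input + 2 GCN layers + output vs central differences."""
        rng = np.random.default_rng(31)
        n, m, d, k = 6, 5, 4, 3
        cfg = tiny_config(hidden_dim=d, n_gcn_layers=2)
        model = GnnModel(m, k, [f"t{i}" for i in range(k)], cfg, seed=7)
        g = random_graph(rng, n, p=0.5)
        adj = normalized_adjacency(g).matrix
        x = sparse.csr_matrix((rng.random((n, m)) < 0.5).astype(float))
        y = (rng.random((3, k)) < 0.5).astype(float)
        seed_pos = np.array([0, 2, 4])
        _, grads = _gnn_batch_grads(model, x, adj, y, seed_pos, rng=None)

        def loss_at():
            s = gnn_scores(x, adj, model)[seed_pos]
            return bce_loss(s, y, np.ones(3, dtype=bool))

        eps = 1e-6
        for key in ("W0", "b0", "W1", "b1", "W2", "b2", "Wo", "bo"):
            arr = model.params[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss_at()
                arr[idx] = orig - eps
                down = loss_at()
                arr[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key][idx] == pytest.approx(numeric, abs=1e-5), key


@pytest.fixture(scope="module")
def toy_training_problem():
    """30-protein, 2-community graph where each community has its own term and
    a community-specific signature — separable with both channels."""
    rng = np.random.default_rng(37)
    n = 30
    proteins = [f"p{i:02d}" for i in range(n)]
    community = np.array([i % 2 for i in range(n)])
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p_edge = 0.4 if community[i] == community[j] else 0.02
            if rng.random() < p_edge:
                edges.append((proteins[i], proteins[j], 0.9))
    graph = ProteinGraph(proteins, edges)
    m = 10
    x = np.zeros((n, m))
    for i in range(n):
        x[i, community[i]] = 1.0  # informative
        for j in rng.integers(2, m, size=3):
            x[i, j] = 1.0  # noise
    feats = SignatureMatrix(proteins, SignatureVocabulary(tuple(f"S{j}" for j in range(m))),
                            sparse.csr_matrix(x))
    from graphgo.ontology import AnnotationTable
    y = np.zeros((n, 2), dtype=np.int8)
    y[np.arange(n), community] = 1
    table = AnnotationTable(proteins, ["GO:1", "GO:2"], y)
    return feats, graph, table


class TestTraining:
    def test_loss_decreases_on_separable_data(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        norm = normalized_adjacency(graph)
        cfg = tiny_config(hidden_dim=16, epochs=10, batch_size=10, prior_bias_init=False)
        _, history = train(feats, norm, table, config=cfg, seed=5)
        assert np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_zero_epochs_returns_initialized_model(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        norm = normalized_adjacency(graph)
        cfg = tiny_config(epochs=0)
        model, history = train(feats, norm, table, config=cfg, seed=5)
        reference = GnnModel(feats.m, 2, table.terms, cfg, seed=5)
        assert history == []
        for k in reference.params:
            if k != "bo":  # output bias gets the prior initialization
                assert np.array_equal(model.params[k], reference.params[k])

    def test_same_seed_reproduces_parameters_bitwise(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        norm = normalized_adjacency(graph)
        cfg = tiny_config(hidden_dim=16, epochs=3, dropout=0.5)
        m1, _ = train(feats, norm, table, config=cfg, seed=9)
        m2, _ = train(feats, norm, table, config=cfg, seed=9)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_permutation_equivariance(self, toy_training_problem):
        """Permuting node order of features+graph permutes score rows identically."""
        feats, graph, table = toy_training_problem
        rng = np.random.default_rng(41)
        model = GnnModel(feats.m, 2, table.terms, tiny_config(hidden_dim=16), seed=3)
        norm = normalized_adjacency(graph)
        scores = gnn_scores(feats.rows(graph.nodes), norm.matrix, model)
        perm = rng.permutation(len(graph.nodes))
        p_nodes = [graph.nodes[i] for i in perm]
        p_graph = ProteinGraph(p_nodes, [(u, v, w) for (u, v), w in graph.edges.items()])
        p_norm = normalized_adjacency(p_graph)
        p_scores = gnn_scores(feats.rows(p_nodes), p_norm.matrix, model)
        assert np.allclose(p_scores, scores[perm], atol=1e-12)


class TestPredictFallback:
    def test_in_graph_prediction_equals_composed_forwards(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        norm = normalized_adjacency(graph)
        model = GnnModel(feats.m, 2, table.terms, tiny_config(hidden_dim=16), seed=4)
        sm = predict(model, feats, norm, graph.nodes[:5])
        direct = gnn_scores(feats.rows(graph.nodes), norm.matrix, model)
        assert np.allclose(sm.values, direct[:5])
        assert all(sm.strata[p] == "STRI" for p in graph.nodes[:5])

    def test_off_graph_protein_copies_best_homolog_row(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        proteins = graph.nodes
        ext = SignatureMatrix(proteins + ["query"], feats.vocabulary,
                              sparse.vstack([feats.matrix, feats.matrix[:1]]))
        homology = HomologyTable()
        homology.add("query", proteins[0], 80.0)
        homology.add("query", proteins[3], 120.0)
        norm = normalized_adjacency(graph)
        model = GnnModel(feats.m, 2, table.terms, tiny_config(hidden_dim=16), seed=4)
        sm = predict(model, ext, norm, ["query"], homology)
        assert sm.strata["query"] == "HOMO"
        assert np.allclose(sm.row("query"), predict(model, ext, norm, [proteins[3]]).row(proteins[3]))

    def test_no_homolog_gives_flagged_zero_row(self, toy_training_problem):
        feats, graph, table = toy_training_problem
        ext = SignatureMatrix(graph.nodes + ["orphan"], feats.vocabulary,
                              sparse.vstack([feats.matrix, feats.matrix[:1]]))
        norm = normalized_adjacency(graph)
        model = GnnModel(feats.m, 2, table.terms, tiny_config(hidden_dim=16), seed=4)
        sm = predict(model, ext, norm, ["orphan"], HomologyTable())
        assert sm.strata["orphan"] == "NONE"
        assert np.all(sm.row("orphan") == 0)


class TestSubgraphConsistency:
    def test_seed_rows_match_full_graph_forward(self):
        rng = np.random.default_rng(43)
        for trial in range(10):
            n = int(rng.integers(10, 25))
            g = random_graph(rng, n, p=0.25, prefix=f"t{trial}_")
            norm = normalized_adjacency(g)
            feats = make_features(rng, g.nodes, 6)
            model = GnnModel(6, 3, ["a", "b", "c"], tiny_config(hidden_dim=5),
                             seed=int(rng.integers(1e6)))
            full = gnn_scores(feats.matrix, norm.matrix, model)
            seeds = [g.nodes[i] for i in rng.choice(n, size=3, replace=False)]
            sub = batch_neighborhood(norm, seeds, hops=2)
            local = gnn_scores(feats.rows(sub.included), sub.local_matrix, model)
            for s, pos in zip(seeds, sub.seed_positions):
                assert np.allclose(local[pos], full[g.nodes.index(s)], atol=1e-6)


class TestEnsembleAndAblation:
    def test_mean_of_identical_matrices_is_identity(self):
        sm = ScoreMatrix(["p"], ["t"], [[0.4]])
        out = ensemble_average([sm, sm, sm])
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_zero_one_pair_averages_half(self):
        a = ScoreMatrix(["p"], ["t"], [[0.0]])
        b = ScoreMatrix(["p"], ["t"], [[1.0]])
        assert ensemble_average([a, b]).values[0, 0] == pytest.approx(0.5)

    def test_random_triple_matches_loop_oracle(self):
        rng = np.random.default_rng(47)
        mats = [ScoreMatrix(["p1", "p2"], ["t1", "t2"], rng.random((2, 2))) for _ in range(3)]
        out = ensemble_average(mats)
        for i in range(2):
            for j in range(2):
                assert out.values[i, j] == pytest.approx(
                    sum(m.values[i, j] for m in mats) / 3)

    def test_axis_mismatch_is_hard_error(self):
        a = ScoreMatrix(["p"], ["t"], [[0.1]])
        b = ScoreMatrix(["q"], ["t"], [[0.1]])
        with pytest.raises(ValueError):
            ensemble_average([a, b])

    def test_ablation_ignores_the_graph(self):
        rng = np.random.default_rng(53)
        cfg = tiny_config(hidden_dim=6, n_gcn_layers=0)
        model = GnnModel(5, 2, ["a", "b"], cfg, seed=1, extra_fc=True)
        x = sparse.csr_matrix((rng.random((4, 5)) < 0.5).astype(float))
        assert np.array_equal(dnn_interpro_forward(x, model),
                              dnn_interpro_forward(x, model))
        # all-zero weights => scores 0.5
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        assert np.all(dnn_interpro_forward(x, model) == 0.5)

    def test_ablation_matches_dense_oracle(self):
        rng = np.random.default_rng(59)
        cfg = tiny_config(hidden_dim=4, n_gcn_layers=0)
        model = GnnModel(5, 2, ["a", "b"], cfg, seed=2, extra_fc=True)
        x = (rng.random((3, 5)) < 0.5).astype(float)
        p = model.params
        h0 = np.maximum(x @ p["W0"] + p["b0"], 0)
        h1 = np.maximum(h0 @ p["Wh"] + p["bh"], 0)
        want = 1 / (1 + np.exp(-(h1 @ p["Wo"].T + p["bo"])))
        assert np.allclose(dnn_interpro_forward(sparse.csr_matrix(x), model), want, atol=1e-12)


def test_checkpoint_roundtrip(tmp_path, toy_training_problem):
    feats, graph, table = toy_training_problem
    norm = normalized_adjacency(graph)
    cfg = tiny_config(hidden_dim=16, epochs=2)
    model, _ = train(feats, norm, table, config=cfg, seed=6)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.terms == model.terms
    for k in model.params:
        assert np.array_equal(loaded.params[k], model.params[k])


def test_feature_column_permutation_invariance(toy_training_problem):
    """Permuting vocabulary columns together with the input-layer rows leaves
    the composed forward unchanged."""
    feats, graph, table = toy_training_problem
    rng = np.random.default_rng(61)
    norm = normalized_adjacency(graph)
    model = GnnModel(feats.m, 2, table.terms, tiny_config(hidden_dim=16), seed=8)
    base = gnn_scores(feats.rows(graph.nodes), norm.matrix, model)
    perm = rng.permutation(feats.m)
    x_perm = feats.matrix[:, perm]
    model.params["W0"] = model.params["W0"][perm]
    permuted = gnn_scores(x_perm, norm.matrix, model)
    assert np.allclose(base, permuted, atol=1e-12)
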