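import numpy as np
import pytest

from multiprot.autodiff import Adam, Tensor
from multiprot.encoders import (GraphEncoder, LoraAdapter, MLMBatch,
                                ProteinGraph, Transformer, TransformerConfig,
                                build_protein_graph, dihedral_angle,
                                gnn_encode, lora_forward, make_mlm_batch,
                                mlm_loss, transformer_encode)
from multiprot.io_formats import Atom
from multiprot.synthetic import GeneratorConfig, generate_corpus


def ca_atoms(positions):
    return [Atom("CA", i, "C", *map(float, p)) for i, p in enumerate(positions)]


# ---------------------------------------------------------------------------
# Transformer
# ---------------------------------------------------------------------------

class TestTransformer:
    def test_zero_layers_is_embedding_plus_positional(self):
        cfg = TransformerConfig(vocab_size=5, d_model=4, n_layers=0,
                                n_heads=2, d_ff=8, max_len=6)
        t = Transformer(cfg, seed=0)
        tokens = np.array([1, 3, 0])
        out = transformer_encode(tokens, t)
        expected = t.embedding.data[tokens] + t.positional.data[:3]
        assert np.allclose(out, expected)

    def test_padding_does_not_affect_valid_positions(self):
        cfg = TransformerConfig(vocab_size=6, d_model=8, n_layers=2,
                                n_heads=2, d_ff=16, max_len=10)
        t = Transformer(cfg, seed=1)
        tokens = np.array([1, 2, 3])
        base = transformer_encode(tokens, t, np.ones(3, dtype=bool))
        for pad_tok in (0, 5):
            padded = np.concatenate([tokens, [pad_tok, pad_tok]])
            mask = np.array([1, 1, 1, 0, 0], dtype=bool)
            out = transformer_encode(padded, t, mask)
            assert np.abs(out[:3] - base).max() < 1e-6

    def test_single_layer_hand_oracle(self):
        # width 2, one head, two tokens: mirror the printed equations in
        # plain numpy, with hand-set parameters
        cfg = TransformerConfig(vocab_size=3, d_model=2, n_layers=1,
                                n_heads=1, d_ff=2, max_len=4)
        t = Transformer(cfg, seed=0)
        E = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        P = np.zeros((4, 2))
        Wq = np.array([[1.0, 0.0], [0.0, 1.0]])
        Wk = np.array([[0.0, 1.0], [1.0, 0.0]])
        Wv = np.array([[2.0, 0.0], [0.0, 2.0]])
        Wo = np.eye(2)
        W1 = np.array([[1.0, -1.0], [1.0, 1.0]])
        b1 = np.array([0.1, -0.1])
        W2 = np.eye(2)
        b2 = np.zeros(2)
        t.embedding.data = E.copy()
        t.positional.data = P.copy()
        layer = t.layers[0]
        for name, val in (("Wq", Wq), ("Wk", Wk), ("Wv", Wv), ("Wo", Wo),
                          ("W1", W1), ("W2", W2)):
            layer[name].base.data = val.copy()
        layer["b1"].data = b1.copy()
        layer["b2"].data = b2.copy()

        tokens = np.array([0, 1])
        out = transformer_encode(tokens, t)

        # oracle
        x0 = E[tokens] + P[:2]
        Q, K, V = x0 @ Wq, x0 @ Wk, x0 @ Wv
        scores = Q @ K.T / np.sqrt(2.0)
        attn = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn /= attn.sum(axis=1, keepdims=True)
        h = (attn @ V) @ Wo
        expected = np.maximum(0.0, h @ W1 + b1) @ W2 + b2
        assert np.allclose(out, expected, atol=1e-12)

    def test_token_out_of_range(self):
        cfg = TransformerConfig(vocab_size=3, d_model=4, n_layers=1,
                                n_heads=1, d_ff=4, max_len=4)
        t = Transformer(cfg, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            transformer_encode(np.array([0, 3]), t)

    def test_length_exceeds_max(self):
        cfg = TransformerConfig(vocab_size=3, d_model=4, n_layers=0,
                                n_heads=1, d_ff=4, max_len=2)
        t = Transformer(cfg, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            transformer_encode(np.array([0, 1, 2]), t)

    def test_seed_reproducibility(self):
        cfg = TransformerConfig(vocab_size=5, d_model=4, n_layers=1,
                                n_heads=2, d_ff=8, max_len=6)
        a, b = Transformer(cfg, seed=3), Transformer(cfg, seed=3)
        for k, v in a.state_dict().items():
            assert np.array_equal(v, b.state_dict()[k]), k

    def test_state_dict_round_trip(self):
        cfg = TransformerConfig(vocab_size=5, d_model=4, n_layers=1,
                                n_heads=2, d_ff=8, max_len=6)
        a, b = Transformer(cfg, seed=3), Transformer(cfg, seed=4)
        b.load_state_dict(a.state_dict())
        tokens = np.array([0, 4, 2])
        assert np.array_equal(transformer_encode(tokens, a),
                              transformer_encode(tokens, b))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TransformerConfig(vocab_size=4, d_model=6, n_heads=4)


# ---------------------------------------------------------------------------
# Dihedral and graph construction
# ---------------------------------------------------------------------------

class TestDihedral:
    def test_reference_value(self):
        assert dihedral_angle((1, 0, 0), (0, 0, 0), (0, 1, 0),
                              (0, 1, 1)) == pytest.approx(np.pi / 2)

    def test_planar_zigzag_magnitude_pi(self):
        ang = dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert abs(ang) == pytest.approx(np.pi)

    def test_reversal_preserves_angle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 3
            a = dihedral_angle(*p)
            b = dihedral_angle(*p[::-1])
            assert a == pytest.approx(b, abs=1e-9)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 3
            a = dihedral_angle(*p)
            mirrored = p * np.array([1.0, 1.0, -1.0])
            b = dihedral_angle(*mirrored)
            if abs(abs(a) - np.pi) > 1e-6:  # ±π is its own mirror image
                assert b == pytest.approx(-a, abs=1e-9)

    def test_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ang = dihedral_angle(*rng.normal(size=(4, 3)))
            assert -np.pi < ang <= np.pi


class TestBuildGraph:
    def test_edge_within_cutoff(self):
        g = build_protein_graph(ca_atoms([[0, 0, 0], [5, 0, 0]]), cutoff=10)
        assert sorted(map(tuple, g.edges)) == [(0, 1), (1, 0)]

    def test_no_edge_beyond_cutoff(self):
        g = build_protein_graph(ca_atoms([[0, 0, 0], [12, 0, 0]]), cutoff=10)
        assert len(g.edges) == 0

    def test_edges_match_brute_force(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(size=(20, 3)) * 6
        g = build_protein_graph(ca_atoms(pos), cutoff=8.0)
        expected = set()
        for i in range(20):
            for j in range(20):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= 8.0:
                    expected.add((i, j))
        assert set(map(tuple, g.edges)) == expected
        # symmetry and endpoint distances
        for (i, j), d in zip(g.edges, g.edge_dist):
            assert (j, i) in expected
            assert d <= 8.0

    def test_fewer_than_two_residues(self):
        with pytest.raises(ValueError):
            build_protein_graph(ca_atoms([[0, 0, 0]]))

    def test_missing_ca_rejected(self):
        atoms = ca_atoms([[0, 0, 0], [3, 0, 0]])
        atoms[1] = Atom("CB", 1, "C", 3.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="CA"):
            build_protein_graph(atoms)

    def test_insufficient_atoms_flagged_not_fabricated(self):
        # Cα-only chain: frames come from Cα triples, ends are invalid;
        # no side-chain atoms, so every chi angle is flagged invalid
        g = build_protein_graph(
            ca_atoms([[0, 0, 0], [3.8, 0, 0], [5, 3, 0], [2, 5, 1]]),
            cutoff=10)
        assert not g.chi_valid.any()
        assert g.tau_valid[1].all()
        assert not g.tau_valid[-1].any()

    def test_angles_in_range(self, tiny_corpus):
        rec = tiny_corpus.records[0]
        g = build_protein_graph(rec.structure, cutoff=10)
        assert np.all(g.tau[g.tau_valid] > -np.pi)
        assert np.all(g.tau[g.tau_valid] <= np.pi)
        assert g.chi_valid[:, 0].any()  # chi1 computable from N/CA/CB/CG


# ---------------------------------------------------------------------------
# GNN encoder
# ---------------------------------------------------------------------------

def random_graph(seed=0, n=12):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(size=(n, 3)) * 2, axis=0)
    return build_protein_graph(ca_atoms(pos), cutoff=6.0,
                               residue_types=rng.integers(0, 20, size=n))


class TestGraphEncoder:
    def test_zero_message_zero_update_gives_mean_embedding(self):
        g = random_graph(0)
        enc = GraphEncoder(width=8, n_layers=1, level="amino_acid", seed=0)
        for layer in enc.layers:
            for p in layer.values():
                p.data[...] = 0.0
        out = gnn_encode(g, enc)
        expected = enc.embedding.data[g.residue_types].mean(axis=0)
        assert np.allclose(out, expected)

    @pytest.mark.parametrize("level", ["amino_acid", "backbone", "all_atom"])
    def test_rigid_motion_invariance(self, level, tiny_corpus):
        rec = tiny_corpus.records[1]
        enc = GraphEncoder(width=8, n_layers=2, level=level, seed=1)
        g1 = build_protein_graph(rec.structure, cutoff=10)
        out1 = gnn_encode(g1, enc)

        rng = np.random.default_rng(5)
        M = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(M)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1  # proper rotation
        t = rng.normal(size=3) * 10
        moved = [Atom(a.name, a.residue_index, a.element,
                      *(Q @ a.position + t)) for a in rec.structure]
        g2 = build_protein_graph(moved, cutoff=10)
        out2 = gnn_encode(g2, enc)
        assert np.abs(out1 - out2).max() < 1e-5

    def test_node_permutation_invariance(self):
        g = random_graph(2)
        enc = GraphEncoder(width=8, n_layers=2, level="amino_acid", seed=2)
        out1 = gnn_encode(g, enc)

        perm = np.random.default_rng(3).permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = ProteinGraph(
            n_nodes=g.n_nodes, ca=g.ca[perm],
            edges=np.array([[inv[i], inv[j]] for i, j in g.edges]),
            edge_dist=g.edge_dist, cutoff=g.cutoff, tau=g.tau[perm],
            tau_valid=g.tau_valid[perm], chi=g.chi[perm],
            chi_valid=g.chi_valid[perm],
            residue_types=g.residue_types[perm])
        out2 = gnn_encode(g2, enc)
        assert np.abs(out1 - out2).max() < 1e-8

    def test_one_layer_two_node_hand_oracle(self):
        # two nodes, one undirected edge; mirror the message/update
        # arithmetic in plain numpy
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        g = build_protein_graph(ca_atoms(pos), cutoff=5.0,
                                residue_types=np.array([0, 1]))
        enc = GraphEncoder(width=2, n_layers=1, level="amino_acid",
                           n_radial=2, seed=0, cutoff=5.0)
        out = gnn_encode(g, enc)

        h = enc.embedding.data[[0, 1]]
        rbf = enc._radial(g.edge_dist)
        layer = enc.layers[0]
        agg = np.zeros((2, 2))
        for e, (src, dst) in enumerate(g.edges):
            x = np.concatenate([h[src], rbf[e]])
            m = np.maximum(0.0, x @ layer["Wm1"].data + layer["bm1"].data)
            m = m @ layer["Wm2"].data + layer["bm2"].data
            agg[dst] += m
        upd = np.tanh(np.concatenate([h, agg], axis=1) @ layer["Wu"].data
                      + layer["bu"].data)
        expected = (h + upd).mean(axis=0)
        assert np.allclose(out, expected, atol=1e-12)

    def test_empty_graph_rejected(self):
        enc = GraphEncoder(width=4, n_layers=1, seed=0)
        g = random_graph(1)
        g.n_nodes = 0
        with pytest.raises(ValueError):
            enc.forward(g)

    def test_batch_matches_individual(self):
        graphs = [random_graph(s) for s in range(3)]
        enc = GraphEncoder(width=8, n_layers=2, seed=4, level="amino_acid")
        batch = enc.forward(graphs).data
        singles = np.stack([gnn_encode(g, enc) for g in graphs])
        assert np.allclose(batch, singles, atol=1e-10)


# ---------------------------------------------------------------------------
# LoRA
# ---------------------------------------------------------------------------

class TestLora:
    def test_alpha_zero_is_base(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 3))
        ad = LoraAdapter(W, rank=2, alpha=0.0, seed=1)
        x = rng.normal(size=4)
        assert np.allclose(lora_forward(ad, x), x @ W)

    def test_zero_factor_is_base(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 3))
        ad = LoraAdapter(W, rank=2, alpha=3.0, seed=1)
        ad.A.data[...] = 0.0
        x = rng.normal(size=4)
        assert np.array_equal(lora_forward(ad, x), x @ W)

    def test_worked_example(self):
        W = np.eye(2)
        ad = LoraAdapter(W, rank=1, alpha=2.0, seed=0)
        ad.A.data = np.array([[1.0], [0.0]])
        ad.B.data = np.array([[0.0, 1.0]])
        out = lora_forward(ad, np.array([1.0, 0.0]))
        assert np.allclose(out, [1.0, 2.0])

    def test_merged_equals_factored(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(6, 5))
        ad = LoraAdapter(W, rank=2, alpha=1.5, seed=3)
        ad.B.data = rng.normal(size=ad.B.shape)
        x = rng.normal(size=(4, 6))
        merged = x @ ad.effective_weight().data
        assert np.abs(lora_forward(ad, x) - merged).max() < 1e-6

    def test_rank_bound_enforced(self):
        with pytest.raises(ValueError):
            LoraAdapter(np.eye(3), rank=3)

    def test_w_frozen_under_training(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(4, 4))
        ad = LoraAdapter(W, rank=2, alpha=1.0, seed=5)
        ad.B.data = rng.normal(size=ad.B.shape)
        opt = Adam(ad.trainable_parameters(), lr=0.05)
        x = Tensor(rng.normal(size=(3, 4)))
        before = ad.W.data.copy()
        for _ in range(20):
            loss = (ad.forward(x) ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.array_equal(ad.W.data, before)
        assert not np.allclose(ad.A.data, 0.0)


# ---------------------------------------------------------------------------
# MLM
# ---------------------------------------------------------------------------

class TestMlm:
    def test_uniform_prediction_is_log_v(self):
        V = 7
        pred = np.full((5, V), 1.0 / V)
        batch = MLMBatch(np.zeros(5, dtype=int), np.array([2]), np.array([3]))
        assert mlm_loss(pred, batch) == pytest.approx(np.log(V))

    def test_perfect_prediction_is_zero(self):
        pred = np.zeros((4, 5))
        tokens = np.array([1, 2, 3, 4])
        pred[np.arange(4), tokens] = 1.0
        batch = MLMBatch(tokens, np.arange(4), tokens)
        assert mlm_loss(pred, batch) == pytest.approx(0.0)

    def test_worked_example_sum_and_mean(self):
        pred = np.full((2, 4), 0.01)
        pred[0, 1] = 0.5
        pred[1, 2] = 0.25
        batch = MLMBatch(np.zeros(2, dtype=int), np.array([0, 1]),
                         np.array([1, 2]))
        expected = np.log(2) + np.log(4)
        assert mlm_loss(pred, batch) == pytest.approx(expected)
        assert mlm_loss(pred, batch, reduction="mean") == \
            pytest.approx(expected / 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mlm_loss(np.ones((2, 2)), MLMBatch(np.zeros(2, dtype=int),
                                               np.array([], dtype=int),
                                               np.array([], dtype=int)))

    def test_make_mlm_batch(self):
        rng = np.random.default_rng(0)
        tokens = np.arange(10)
        batch = make_mlm_batch(tokens, 0.3, mask_token_id=99, rng=rng)
        assert len(batch.masked_positions) == 3
        assert np.all(batch.tokens[batch.masked_positions] == 99)
        assert np.array_equal(batch.original_tokens,
                              tokens[batch.masked_positions])
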