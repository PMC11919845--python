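"""Protein encoder: residue embedding, multi-scale CNN, WGCN, fusion."""

import numpy as np
import pytest

from dtiblocks.autodiff import Tensor
from dtiblocks.target_encoder import (LookupEmbedder, ProteinRecord,
                                      TargetEncoderConfig, TargetGraph,
                                      build_residue_graph, embed_residues,
                                      encode_target, fuse_target,
                                      init_target_encoder, multiscale_cnn,
                                      wgcn_layer)


# -- residue embedding ----------------------------------------------------

def test_lookup_embedder_semantics():
    emb = LookupEmbedder(seed=0)
    m = embed_residues("ACD", emb)
    assert m.shape == (3, 30)
    m2 = embed_residues("AADA", emb)
    np.testing.assert_array_equal(m2[0], m2[1])        # repeated letters
    np.testing.assert_array_equal(m2[0], m2[3])
    np.testing.assert_array_equal(embed_residues("AAAA", emb),
                                  np.tile(m[0], (4, 1)))


def test_unknown_letter_maps_to_x():
    emb = LookupEmbedder(seed=0)
    np.testing.assert_array_equal(embed_residues("B", emb),
                                  embed_residues("X", emb))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        embed_residues("", LookupEmbedder())


# -- multi-scale CNN ------------------------------------------------------

def test_cnn_preserves_length(rng):
    cfg = TargetEncoderConfig(channels=8)
    params = init_target_encoder(rng, cfg)
    for L in (7, 30, 101):
        out = multiscale_cnn(rng.normal(size=(L, 30)), params)
        assert out.shape == (L, 8)


def test_window_one_identity_kernel_is_pointwise():
    c = 5
    params = {
        "conv": [{"W": Tensor(np.eye(c)), "b": Tensor(np.zeros(c)), "window": 1}],
        "proj_W": Tensor(np.eye(c)),
        "proj_b": Tensor(np.zeros(c)),
    }
    x = np.abs(np.random.default_rng(0).normal(size=(6, c)))  # nonneg: ReLU inert
    np.testing.assert_allclose(multiscale_cnn(x, params).data, x)


def test_zero_input_zero_bias_gives_zero(rng):
    cfg = TargetEncoderConfig(channels=4)
    params = init_target_encoder(rng, cfg)
    out = multiscale_cnn(np.zeros((10, 30)), params)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


# -- residue graph --------------------------------------------------------

def _record(seq, cmap):
    return ProteinRecord(target_id="t", sequence=seq, contact_map=cmap)


def test_identity_contact_map_keeps_only_backbone():
    n = 6
    g = build_residue_graph(_record("A" * n, np.eye(n)), threshold=0.5)
    pairs = set(zip(g.src.tolist(), g.dst.tolist()))
    expected = {(i, i + 1) for i in range(n - 1)} | {(i + 1, i) for i in range(n - 1)}
    assert pairs == expected
    assert np.all(g.weight == 1.0)


def test_contact_above_threshold_becomes_edge():
    n = 10
    m = np.zeros((n, n))
    m[2, 7] = m[7, 2] = 0.9
    g = build_residue_graph(_record("A" * n, m), threshold=0.5)
    pairs = dict(zip(zip(g.src.tolist(), g.dst.tolist()), g.weight))
    assert pairs[(2, 7)] == 0.9 and pairs[(7, 2)] == 0.9


def test_threshold_one_keeps_backbone_only(rng):
    n = 8
    m = rng.uniform(0, 0.99, size=(n, n))
    m = (m + m.T) / 2
    g = build_residue_graph(_record("A" * n, m), threshold=1.0)
    assert set(map(tuple, np.stack([g.src, g.dst]).T.tolist())) == \
        {(i, i + 1) for i in range(n - 1)} | {(i + 1, i) for i in range(n - 1)}


def test_asymmetric_map_rejected():
    m = np.zeros((3, 3))
    m[0, 2] = 0.9
    with pytest.raises(ValueError, match="symmetric"):
        build_residue_graph(_record("AAA", m), threshold=0.5)


# -- WGCN -----------------------------------------------------------------

def _wgcn_params(W1, W2, b=None):
    W1 = np.asarray(W1, float)
    return {"W1": Tensor(W1), "W2": Tensor(np.asarray(W2, float)),
            "b": Tensor(np.zeros(W1.shape[1]) if b is None else b)}


def test_wgcn_no_edges_reduces_to_self_term(rng):
    g = TargetGraph(n_nodes=4, src=np.array([], dtype=np.intp),
                    dst=np.array([], dtype=np.intp), weight=np.array([]))
    x = Tensor(rng.normal(size=(4, 3)))
    p = _wgcn_params(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)))
    np.testing.assert_allclose(wgcn_layer(g, x, p).data,
                               np.maximum(x.data @ p["W1"].data, 0))


def test_wgcn_two_node_hand_calc(rng):
    # single edge, M=1, both degrees 1 -> c_ij = 1
    g = TargetGraph(n_nodes=2, src=np.array([0, 1]), dst=np.array([1, 0]),
                    weight=np.array([1.0, 1.0]))
    x = rng.normal(size=(2, 3))
    W1, W2 = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    out = wgcn_layer(g, Tensor(x), _wgcn_params(W1, W2))
    np.testing.assert_allclose(out.data[0], np.maximum(x[0] @ W1 + x[1] @ W2, 0),
                               atol=1e-12)
    np.testing.assert_allclose(out.data[1], np.maximum(x[1] @ W1 + x[0] @ W2, 0),
                               atol=1e-12)


def test_wgcn_linear_in_contact_weights(rng):
    n = 5
    m = rng.uniform(0.6, 1.0, size=(n, n))
    m = (m + m.T) / 2
    rec = _record("A" * n, m)
    g = build_residue_graph(rec, threshold=0.0)
    g_half = TargetGraph(n_nodes=n, src=g.src, dst=g.dst, weight=0.5 * g.weight,
                         degree=g.degree)
    x = Tensor(rng.normal(size=(n, 3)))
    p = _wgcn_params(np.zeros((3, 4)), rng.normal(size=(3, 4)))
    full = wgcn_layer(g, x, p, activation=None).data
    half = wgcn_layer(g_half, x, p, activation=None).data
    np.testing.assert_allclose(half, 0.5 * full, atol=1e-12)


def test_wgcn_matches_bruteforce_double_loop(rng):
    """Dense all-ones off-diagonal map equals degree-normalised aggregation,
    checked pre-activation against an explicit double loop."""
    for n in (3, 6, 10):
        m = np.ones((n, n))
        rec = _record("A" * n, m)
        g = build_residue_graph(rec, threshold=0.5)
        x = rng.normal(size=(n, 4))
        W1, W2 = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        got = wgcn_layer(g, Tensor(x), _wgcn_params(W1, W2), activation=None).data
        deg = np.full(n, n - 1.0)
        expected = x @ W1
        for i in range(n):
            for j in range(n):
                if i != j:
                    expected[i] += (1.0 / np.sqrt(deg[i] * deg[j])) * x[j] @ W2
        np.testing.assert_allclose(got, expected, atol=1e-10)


# -- fusion and full encoder ---------------------------------------------

def test_fusion_unit_norm_and_degenerate_graph(rng):
    cfg = TargetEncoderConfig(channels=6)
    params = init_target_encoder(rng, cfg)
    t_seq = Tensor(rng.normal(size=(9, 6)))
    # graph channel absent: embedding = max-pool of L2(Tseq Ws) Wt
    got = fuse_target(t_seq, None, params).data
    proj = t_seq.data @ params["Ws"].data
    norm = proj / np.linalg.norm(proj, axis=1, keepdims=True)
    np.testing.assert_allclose(got, (norm @ params["Wt"].data).max(axis=0), atol=1e-12)


def test_fusion_identical_channels_double(rng):
    cfg = TargetEncoderConfig(channels=4)
    params = init_target_encoder(rng, cfg)
    params["Wg"] = params["Ws"]
    t = Tensor(rng.normal(size=(5, 4)))
    single = fuse_target(t, None, params).data
    both = fuse_target(t, t, params).data
    np.testing.assert_allclose(both, 2.0 * single, atol=1e-12)


def test_sequence_only_configuration_runs(rng):
    cfg = TargetEncoderConfig(channels=8, use_graph=False)
    params = init_target_encoder(rng, cfg)
    rec = ProteinRecord("t", "ACDEFGHIKLMNPQRSTVWY")
    emb = encode_target(rec, params, cfg)
    assert emb.shape == (8,)
    assert np.all(np.isfinite(emb.data))


def test_residue_order_sensitivity(rng):
    """Unlike the drug branch, shuffling the sequence changes the embedding."""
    cfg = TargetEncoderConfig(channels=8, use_graph=False)
    params = init_target_encoder(rng, cfg)
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    shuffled = "".join(rng.permutation(list(seq)))
    assert shuffled != seq
    a = encode_target(ProteinRecord("a", seq), params, cfg).data
    b = encode_target(ProteinRecord("b", shuffled), params, cfg).data
    assert np.abs(a - b).max() > 1e-8
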