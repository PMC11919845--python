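"""Drug encoder: message passing, enhancement, gating, permutation invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtiblocks import autodiff as ad
from dtiblocks.autodiff import Tensor
from dtiblocks.chem_graph import MolecularGraph, smiles_to_graph
from dtiblocks.drug_encoder import (DrugEncoderConfig, GNNBlockConfig, GatingParams,
                                    encode_drug, feature_enhance, gating_update,
                                    gnn_block_forward, gnn_layer,
                                    init_drug_encoder, init_gating)
from dtiblocks.synthetic_data import SyntheticSpec, generate_drugs


def gcn_params(W1, W2, b=None):
    W1, W2 = np.asarray(W1, float), np.asarray(W2, float)
    return {"type": "gcn", "W1": Tensor(W1), "W2": Tensor(W2),
            "b": Tensor(np.zeros(W1.shape[1]) if b is None else np.asarray(b, float))}


def zero_gating(c: int) -> GatingParams:
    z = lambda *s: Tensor(np.zeros(s))
    return GatingParams(W1r=z(c, c), W2r=z(c, c), br=z(c),
                        W1z=z(c, c), W2z=z(c, c), bz=z(c),
                        W1h=z(c, c), W2h=z(c, c), bh=z(c))


# -- gnn_layer ------------------------------------------------------------

def test_isolated_node_sees_only_itself(rng):
    x = Tensor(rng.normal(size=(1, 3)))
    p = gcn_params(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
    out = gnn_layer(x, np.zeros((2, 0), dtype=np.intp), p)
    np.testing.assert_allclose(out.data, np.maximum(x.data @ p["W1"].data, 0))


def test_two_node_identity_layer_hand_calc():
    x = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    edges = np.array([[0, 1], [1, 0]])
    p = gcn_params(np.eye(2), np.eye(2))
    out = gnn_layer(x, edges, p, activation=None)
    np.testing.assert_allclose(out.data, [[1.0, 1.0], [1.0, 1.0]])


@pytest.mark.parametrize("gnn_type", ["gcn", "gat", "gin"])
def test_complete_graph_identical_features_stay_identical(rng, gnn_type):
    n, c = 5, 4
    x = Tensor(np.tile(rng.normal(size=(1, c)), (n, 1)))
    src, dst = np.nonzero(~np.eye(n, dtype=bool))
    edges = np.stack([src, dst])
    from dtiblocks.drug_encoder import init_gnn_layer
    p = init_gnn_layer(np.random.default_rng(1), c, c, gnn_type)
    out = gnn_layer(x, edges, p)
    np.testing.assert_allclose(out.data, np.tile(out.data[:1], (n, 1)), atol=1e-12)


def test_channel_mismatch_raises(rng):
    p = gcn_params(np.eye(3), np.eye(3))
    with pytest.raises(ValueError, match="channel mismatch"):
        gnn_layer(Tensor(rng.normal(size=(2, 4))), np.zeros((2, 0), dtype=np.intp), p)


# -- blocks and enhancement ----------------------------------------------

def test_block_doubles_last_layer_channels(rng):
    c = 6
    layers = [gcn_params(rng.normal(size=(c, c)), rng.normal(size=(c, c))),
              gcn_params(rng.normal(size=(c, 2 * c)), rng.normal(size=(c, 2 * c)))]
    x = Tensor(rng.normal(size=(4, c)))
    edges = np.array([[0, 1], [1, 0]])
    pen, expd = gnn_block_forward(x, edges, layers)
    assert pen.shape == (4, c)
    assert expd.shape == (4, 2 * c)
    assert expd.shape[1] == 2 * pen.shape[1]


def test_zero_weight_block_gives_zero_expansion(rng):
    c = 3
    layers = [gcn_params(np.zeros((c, c)), np.zeros((c, c))),
              gcn_params(np.zeros((c, 2 * c)), np.zeros((c, 2 * c)))]
    x = Tensor(rng.normal(size=(5, c)))
    _, expd = gnn_block_forward(x, np.zeros((2, 0), dtype=np.intp), layers)
    np.testing.assert_array_equal(expd.data, 0.0)


def test_block_requires_two_layers():
    with pytest.raises(ValueError):
        GNNBlockConfig(n_layers=1)


def test_feature_enhance_identity_at_zero_scale(rng):
    pen = Tensor(rng.normal(size=(4, 3)))
    expd = Tensor(rng.normal(size=(4, 6)))
    np.testing.assert_array_equal(feature_enhance(pen, expd, 0.0).data, pen.data)


def test_feature_enhance_saturated_gate_closes(rng):
    pen = Tensor(rng.normal(size=(4, 3)))
    expd_data = rng.normal(size=(4, 6))
    expd_data[:, 3:] = -1e6
    out = feature_enhance(pen, Tensor(expd_data), 1.0)
    np.testing.assert_allclose(out.data, pen.data, atol=1e-6)


def test_feature_enhance_hand_case():
    # value half [2,2], gate half [0,0] -> GLU = [1,1]; plus penultimate [1,1]
    out = feature_enhance(Tensor(np.array([[1.0, 1.0]])),
                          Tensor(np.array([[2.0, 2.0, 0.0, 0.0]])), 1.0)
    np.testing.assert_allclose(out.data, [[2.0, 2.0]])


def test_feature_enhance_rejects_bad_widths(rng):
    with pytest.raises(ValueError):
        feature_enhance(Tensor(rng.normal(size=(2, 3))),
                        Tensor(rng.normal(size=(2, 5))), 1.0)


# -- gating ---------------------------------------------------------------

@settings(deadline=None, max_examples=25, derandomize=True,
          database=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_gating_limits(seed):
    rng = np.random.default_rng(seed)
    c = 4
    prev = Tensor(rng.normal(size=(3, c)))
    new = Tensor(rng.normal(size=(3, c)))
    gp = init_gating(rng, c)
    open_z = GatingParams(**{**{k: getattr(gp, k) for k in
                                ("W1r", "W2r", "br", "W1z", "W2z",
                                 "W1h", "W2h", "bh")},
                             "bz": Tensor(np.full(c, 1e6))})
    cand = ad.tanh(new @ gp.W1h
                   + ad.sigmoid(new @ gp.W1r + prev @ gp.W2r + gp.br.reshape(1, -1))
                   * (prev @ gp.W2h) + gp.bh.reshape(1, -1))
    np.testing.assert_allclose(gating_update(prev, new, open_z).data,
                               cand.data, atol=1e-9)
    closed_z = GatingParams(**{**{k: getattr(gp, k) for k in
                                  ("W1r", "W2r", "br", "W1z", "W2z",
                                   "W1h", "W2h", "bh")},
                               "bz": Tensor(np.full(c, -1e6))})
    np.testing.assert_allclose(gating_update(prev, new, closed_z).data,
                               prev.data, atol=1e-9)


def test_gating_zero_parameters_closed_form(rng):
    # R = Z = sigmoid(0) = 0.5, candidate = tanh(0) = 0 -> output = 0.5 * prev
    prev = Tensor(rng.normal(size=(5, 3)))
    new = Tensor(rng.normal(size=(5, 3)))
    out = gating_update(prev, new, zero_gating(3))
    np.testing.assert_allclose(out.data, 0.5 * prev.data, atol=1e-12)


# -- full encoder ---------------------------------------------------------

@pytest.fixture(scope="module")
def small_encoder():
    cfg = DrugEncoderConfig(channels=8, n_blocks=2, dropout=0.0)
    params = init_drug_encoder(np.random.default_rng(5), cfg)
    return params, cfg


def test_permutation_invariance(small_encoder):
    params, cfg = small_encoder
    drugs = generate_drugs(SyntheticSpec(n_drugs=30, seed=11))
    rng = np.random.default_rng(2)
    for row in drugs.itertuples():
        g = smiles_to_graph(row.smiles, row.drug_id)
        emb = encode_drug(g, params, cfg).data
        perm = rng.permutation(g.num_atoms)
        emb_p = encode_drug(g.permuted(perm), params, cfg).data
        np.testing.assert_allclose(emb, emb_p, atol=1e-5)


def test_single_atom_embedding_is_its_state(small_encoder):
    params, cfg = small_encoder
    g = smiles_to_graph("C", "methane")
    capture = []
    emb = encode_drug(g, params, cfg, capture=capture)
    np.testing.assert_array_equal(emb.data, capture[-1].data[0])


def test_duplicated_component_embedding_unchanged(small_encoder):
    params, cfg = small_encoder
    single = smiles_to_graph("CCO", "ethanol")
    double = smiles_to_graph("CCO.CCO", "two-ethanols")
    assert double.num_atoms == 2 * single.num_atoms
    np.testing.assert_allclose(encode_drug(single, params, cfg).data,
                               encode_drug(double, params, cfg).data, atol=1e-12)


def test_channel_width_constant_across_blocks(small_encoder):
    params, cfg = small_encoder
    capture = []
    encode_drug(smiles_to_graph("c1ccccc1CC(=O)O", "x"), params, cfg,
                capture=capture)
    assert len(capture) == cfg.n_blocks + 1
    assert all(s.shape[1] == cfg.channels for s in capture)


def test_encoder_degenerates_to_plain_stack_when_gating_bypassed():
    """With d=0, update gate forced open, reset path silenced and an identity
    candidate map, the encoder equals a plain stacked GNN with tanh between
    blocks, sharing the same layer weights."""
    cfg = DrugEncoderConfig(channels=6, n_blocks=2, dropout=0.0,
                            enhancement_scale=0.0)
    params = init_drug_encoder(np.random.default_rng(9), cfg)
    c = cfg.channels
    params["gating"] = GatingParams(
        W1r=Tensor(np.zeros((c, c))), W2r=Tensor(np.zeros((c, c))),
        br=Tensor(np.zeros(c)),
        W1z=Tensor(np.zeros((c, c))), W2z=Tensor(np.zeros((c, c))),
        bz=Tensor(np.full(c, 1e9)),                    # Z = 1: full update
        W1h=Tensor(np.eye(c)), W2h=Tensor(np.zeros((c, c))),
        bh=Tensor(np.zeros(c)))
    g = smiles_to_graph("CCOc1ccccc1", "ref")
    emb = encode_drug(g, params, cfg).data

    # reference: plain pipeline of the same layers, tanh between blocks
    x = Tensor(g.node_features)
    ei = g.edge_index()
    pen, _ = gnn_block_forward(x, ei, params["initial"])
    state = pen
    for layers in params["blocks"]:
        pen, _ = gnn_block_forward(state, ei, layers)
        state = ad.tanh(pen)
    np.testing.assert_allclose(emb, state.max(axis=0).data, atol=1e-7)
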