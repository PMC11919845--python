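"""Drug graph encoder: stacked GNN blocks with feature enhancement and gating.

The encoder is a two-stage pipeline over the molecular graph:

1. an initial fixed 3-layer GNN block lifts the 64-dim indicator atom
   features to the hidden width ``C``;
2. ``L`` further blocks of ``N`` GNN layers each deepen the receptive field,
   every block followed by *feature enhancement* (the block's last layer
   doubles its output channels, a gated linear unit refines the expanded
   vector, and a residual adds it back onto the penultimate layer's output,
   scaled by ``d``) and by GRU-style *gating units* that filter the block's
   output against its input state.  The gating weights are shared across all
   blocks, which is why every block must keep the hidden width ``C``.

A per-channel max over atoms reads out the graph embedding, making the
encoder invariant to atom relabelling.

Message passing follows ``x_i' = act(F1(x_i) + F2(aggregate_{j in N(i)} x_j))``
where the aggregate is a plain neighbour sum for GCN/GIN semantics and an
attention-weighted sum for GAT (single head, so channels are preserved).
The ``gat_gcn`` variant uses GAT for all layers of a block except the last,
which is GCN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_graph import FEATURE_DIM, MolecularGraph

__all__ = [
    "GNNBlockConfig", "DrugEncoderConfig", "GatingParams",
    "init_gnn_layer", "init_block", "init_gating", "init_drug_encoder",
    "gnn_layer", "gnn_block_forward", "feature_enhance", "gating_update",
    "encode_drug", "encode_drug_batch",
]

GNN_TYPES = ("gcn", "gat", "gin", "gat_gcn")


@dataclass
class GNNBlockConfig:
    """One block of ``n_layers`` GNN layers; the last layer doubles channels."""
    n_layers: int = 2
    channels: int = 128
    gnn_type: str = "gat_gcn"
    enhancement_scale: float = 1.0

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("a GNN block needs n_layers >= 2 (penultimate layer undefined otherwise)")
        if self.gnn_type not in GNN_TYPES:
            raise ValueError(f"unknown gnn_type {self.gnn_type!r}; choose from {GNN_TYPES}")
        if self.enhancement_scale < 0:
            raise ValueError("enhancement_scale must be >= 0")


@dataclass
class DrugEncoderConfig:
    channels: int = 128
    n_blocks: int = 5
    n_layers: int = 2
    gnn_type: str = "gat_gcn"
    enhancement_scale: float = 1.0
    dropout: float = 0.2

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("need at least one GNN block")
        self.block = GNNBlockConfig(self.n_layers, self.channels, self.gnn_type,
                                    self.enhancement_scale)
        # fixed 3-layer initial block lifting 64 -> C
        self.initial_block = GNNBlockConfig(3, self.channels, self.gnn_type,
                                            self.enhancement_scale)


@dataclass
class GatingParams:
    """GRU-style reset/update gate weights, shared across all blocks."""
    W1r: Tensor
    W2r: Tensor
    br: Tensor
    W1z: Tensor
    W2z: Tensor
    bz: Tensor
    W1h: Tensor
    W2h: Tensor
    bh: Tensor

    def named(self, prefix: str = "gating") -> dict[str, Tensor]:
        return {f"{prefix}.{k}": getattr(self, k)
                for k in ("W1r", "W2r", "br", "W1z", "W2z", "bz", "W1h", "W2h", "bh")}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _layer_type(block_type: str, layer: int, n_layers: int) -> str:
    if block_type == "gat_gcn":
        return "gcn" if layer == n_layers - 1 else "gat"
    return block_type


def init_gnn_layer(rng: np.random.Generator, cin: int, cout: int, gnn_type: str) -> dict:
    p = {"type": gnn_type, "b": _zeros(cout)}
    if gnn_type == "gin":
        p["W1"] = _glorot(rng, cin, cout)           # shared self/neighbour map
    else:
        p["W1"] = _glorot(rng, cin, cout)
        p["W2"] = _glorot(rng, cin, cout)
    if gnn_type == "gat":
        p["att_src"] = Tensor(rng.uniform(-0.1, 0.1, size=(cout,)), requires_grad=True)
        p["att_dst"] = Tensor(rng.uniform(-0.1, 0.1, size=(cout,)), requires_grad=True)
    return p


def init_block(rng: np.random.Generator, cin: int, cfg: GNNBlockConfig) -> list[dict]:
    """Layer parameter list for one block: cin -> C -> ... -> C -> 2C."""
    layers = []
    c = cin
    for i in range(cfg.n_layers):
        cout = 2 * cfg.channels if i == cfg.n_layers - 1 else cfg.channels
        layers.append(init_gnn_layer(rng, c, cout, _layer_type(cfg.gnn_type, i, cfg.n_layers)))
        c = cfg.channels
    return layers


def init_gating(rng: np.random.Generator, channels: int) -> GatingParams:
    c = channels
    return GatingParams(
        W1r=_glorot(rng, c, c), W2r=_glorot(rng, c, c), br=_zeros(c),
        W1z=_glorot(rng, c, c), W2z=_glorot(rng, c, c), bz=_zeros(c),
        W1h=_glorot(rng, c, c), W2h=_glorot(rng, c, c), bh=_zeros(c),
    )


def init_drug_encoder(rng: np.random.Generator, cfg: DrugEncoderConfig) -> dict:
    params = {
        "initial": init_block(rng, FEATURE_DIM, cfg.initial_block),
        "blocks": [init_block(rng, cfg.channels, cfg.block) for _ in range(cfg.n_blocks)],
        "gating": init_gating(rng, cfg.channels),
    }
    return params


def named_drug_params(params: dict, prefix: str = "drug") -> dict[str, Tensor]:
    flat: dict[str, Tensor] = {}

    def add_layers(layers, tag):
        for i, layer in enumerate(layers):
            for k, v in layer.items():
                if isinstance(v, Tensor):
                    flat[f"{prefix}.{tag}.l{i}.{k}"] = v
    add_layers(params["initial"], "init")
    for b, layers in enumerate(params["blocks"]):
        add_layers(layers, f"block{b}")
    flat.update(params["gating"].named(f"{prefix}.gating"))
    return flat


# -- forward ops ----------------------------------------------------------

def _segment_softmax(scores: Tensor, seg: np.ndarray, n: int) -> Tensor:
    # shift by the per-segment max (a constant w.r.t. gradients: softmax is
    # shift-invariant, so treating the shift as data is exact)
    if scores.data.size == 0:
        return scores
    m = np.full(n, -np.inf)
    np.maximum.at(m, seg, scores.data)
    z = ad.exp(scores - Tensor(m[seg]))
    denom = ad.segment_sum(z, seg, n)
    return z / ad.gather(denom, seg)


def gnn_layer(state: Tensor, edge_index: np.ndarray, params: dict,
              gnn_type: str | None = None, activation=ad.relu) -> Tensor:
    """One message-passing layer; ``activation=None`` leaves it linear."""
    gnn_type = gnn_type or params["type"]
    n = state.shape[0]
    if state.shape[1] != params["W1"].shape[0]:
        raise ValueError(f"channel mismatch: state has {state.shape[1]}, "
                         f"layer expects {params['W1'].shape[0]}")
    src, dst = edge_index[0], edge_index[1]
    if np.any(src >= n) or np.any(dst >= n):
        raise ValueError("edge index out of range")
    if gnn_type == "gat":
        t = state @ params["W2"]
        ts = ad.gather(t, src)
        e = ad.leaky_relu((ts * params["att_src"].reshape(1, -1)).sum(axis=1)
                          + (ad.gather(t, dst) * params["att_dst"].reshape(1, -1)).sum(axis=1))
        alpha = _segment_softmax(e, dst, n)
        agg = ad.segment_sum(ts * alpha.reshape(-1, 1), dst, n)
        pre = state @ params["W1"] + agg + params["b"].reshape(1, -1)
    elif gnn_type == "gin":
        nb = ad.segment_sum(ad.gather(state, src), dst, n)
        pre = (state + nb) @ params["W1"] + params["b"].reshape(1, -1)
    else:  # gcn
        nb = ad.segment_sum(ad.gather(state, src), dst, n)
        pre = state @ params["W1"] + nb @ params["W2"] + params["b"].reshape(1, -1)
    return activation(pre) if activation is not None else pre


def gnn_block_forward(state: Tensor, edge_index: np.ndarray,
                      layers: list[dict]) -> tuple[Tensor, Tensor]:
    """Run a block's layers; return (penultimate [C], expanded [2C]).

    Hidden layers use ReLU; the channel-doubling last layer stays linear
    because the gated linear unit downstream supplies its nonlinearity.
    """
    if len(layers) < 2:
        raise ValueError("block needs >= 2 layers")
    h = state
    for layer in layers[:-1]:
        h = gnn_layer(h, edge_index, layer, activation=ad.relu)
    penultimate = h
    expanded = gnn_layer(h, edge_index, layers[-1], activation=None)
    return penultimate, expanded


def feature_enhance(penultimate: Tensor, expanded: Tensor, d: float) -> Tensor:
    """Expansion-then-refinement: ``penultimate + d * GLU(expanded)``."""
    c2 = expanded.shape[-1]
    if c2 % 2:
        raise ValueError("expanded state must have an even channel count")
    c = c2 // 2
    if penultimate.shape[-1] != c:
        raise ValueError("expanded must have exactly twice the channels of penultimate")
    value = expanded[:, :c]
    gate = expanded[:, c:]
    return penultimate + (value * ad.sigmoid(gate)) * d


def gating_update(prev: Tensor, new: Tensor, gp: GatingParams) -> Tensor:
    """GRU-style filter of a block's output ``new`` against its input ``prev``."""
    if prev.shape != new.shape:
        raise ValueError("prev and new states must share a shape")
    r = ad.sigmoid(new @ gp.W1r + prev @ gp.W2r + gp.br.reshape(1, -1))
    z = ad.sigmoid(new @ gp.W1z + prev @ gp.W2z + gp.bz.reshape(1, -1))
    cand = ad.tanh(new @ gp.W1h + r * (prev @ gp.W2h) + gp.bh.reshape(1, -1))
    return (1.0 - z) * prev + z * cand


def _dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def _encode_nodes(x: Tensor, edge_index: np.ndarray, params: dict,
                  cfg: DrugEncoderConfig, training: bool,
                  rng: np.random.Generator | None,
                  capture: list | None,
                  perturb: dict[int, np.ndarray] | None = None) -> Tensor:
    # ``perturb`` adds a constant offset to a block's state at its capture
    # point (block index -> offset), which lets finite-difference probes
    # verify the gradients reported for captured states.
    d = cfg.enhancement_scale

    def checkpoint(state: Tensor, block_idx: int) -> Tensor:
        if perturb is not None and block_idx in perturb:
            state = state + Tensor(perturb[block_idx])
        if capture is not None:
            capture.append(state)
        return state

    pen, expd = gnn_block_forward(x, edge_index, params["initial"])
    state = feature_enhance(pen, expd, d)
    if training and cfg.dropout > 0:
        state = _dropout(state, cfg.dropout, rng)
    state = checkpoint(state, 0)
    for b, layers in enumerate(params["blocks"], start=1):
        pen, expd = gnn_block_forward(state, edge_index, layers)
        enhanced = feature_enhance(pen, expd, d)
        if training and cfg.dropout > 0:
            enhanced = _dropout(enhanced, cfg.dropout, rng)
        state = gating_update(state, enhanced, params["gating"])
        state = checkpoint(state, b)
    return state


def encode_drug(graph: MolecularGraph, params: dict, cfg: DrugEncoderConfig,
                training: bool = False, rng: np.random.Generator | None = None,
                capture: list | None = None,
                perturb: dict[int, np.ndarray] | None = None) -> Tensor:
    """Encode one molecule to a ``C``-vector (per-channel max over atoms).

    ``capture``, if given, collects the per-block node states (initial block
    first, then each gated block) for diversity/attribution analyses.
    """
    if graph.num_atoms < 1:
        raise ValueError("cannot encode an empty molecular graph")
    x = Tensor(graph.node_features)
    state = _encode_nodes(x, graph.edge_index(), params, cfg, training, rng,
                          capture, perturb)
    return state.max(axis=0)


def encode_drug_batch(graphs: list[MolecularGraph], params: dict,
                      cfg: DrugEncoderConfig, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
    """Encode a batch by concatenating graphs and pooling per segment."""
    feats = np.concatenate([g.node_features for g in graphs], axis=0)
    seg = np.concatenate([np.full(g.num_atoms, i, dtype=np.intp)
                          for i, g in enumerate(graphs)])
    offs = np.cumsum([0] + [g.num_atoms for g in graphs])
    cols = []
    for off, g in zip(offs[:-1], graphs):
        cols.append(g.edge_index() + off)
    edge_index = np.concatenate(cols, axis=1) if cols else np.zeros((2, 0), dtype=np.intp)
    state = _encode_nodes(Tensor(feats), edge_index, params, cfg, training, rng, None)
    return ad.segment_max(state, seg, len(graphs))
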