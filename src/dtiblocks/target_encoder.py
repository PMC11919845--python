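"""Protein encoder: multi-scale sequence CNN fused with a contact-graph WGCN.

A protein enters twice:

* as a residue sequence over the 21-letter alphabet (20 amino acids + X),
  embedded per residue as a 30-dim vector and encoded by three stacked 1-D
  convolutions with growing windows (default 3, 5, 7) whose per-layer
  outputs are concatenated channel-wise and projected to ``C`` channels;
* as a residue-level graph whose edges carry residue-residue contact
  probabilities, encoded by three weighted graph-convolution (WGCN) layers:
  ``h_i' = relu(h_i W1 + sum_j (M_ij / c_ij) h_j W2)`` with
  ``c_ij = sqrt(deg_i) sqrt(deg_j)`` over the unweighted neighbour counts.

The two channels are fused per residue, ``(L2(Tseq Ws) + L2(Tgraph Wg)) Wt``
with row-wise L2 normalisation, and max-pooled over residues.

The default residue embedder is a learned 21x30 lookup table so the package
runs fully offline; any pretrained protein language model can stand behind
the same contract by supplying a per-residue ``(L, 30)`` matrix (adapter
path via ``ProteinRecord.residue_embeddings``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AA_ALPHABET", "ProteinRecord", "TargetGraph", "TargetEncoderConfig",
    "sequence_to_indices", "LookupEmbedder", "embed_residues",
    "build_residue_graph", "multiscale_cnn", "wgcn_layer", "fuse_target",
    "init_target_encoder", "encode_target",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"   # 20 amino acids + unknown
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
EMBED_DIM = 30


@dataclass
class ProteinRecord:
    """One target protein: sequence plus optional structure-derived extras."""
    target_id: str
    sequence: str
    residue_embeddings: np.ndarray | None = None   # (L, 30) if precomputed
    contact_map: np.ndarray | None = None          # (L, L) probabilities

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.target_id!r} has an empty sequence")
        if self.residue_embeddings is not None and \
                self.residue_embeddings.shape[0] != len(self.sequence):
            raise ValueError("residue embedding rows must match sequence length")


@dataclass
class TargetGraph:
    """Residue graph with contact-probability edge weights."""
    n_nodes: int
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray          # in (0, 1]
    node_features: np.ndarray | None = None
    # unweighted neighbour count per node, for the WGCN normaliser
    degree: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.degree is None:
            deg = np.zeros(self.n_nodes, dtype=np.float64)
            np.add.at(deg, self.dst, 1.0)
            self.degree = deg


@dataclass
class TargetEncoderConfig:
    channels: int = 128
    windows: tuple[int, ...] = (3, 5, 7)
    n_wgcn_layers: int = 3
    contact_threshold: float = 0.5
    max_len: int = 1000
    use_graph: bool = True
    embed_dim: int = EMBED_DIM


def sequence_to_indices(sequence: str) -> np.ndarray:
    """Map residues to alphabet indices; anything non-standard becomes X."""
    return np.array([_AA_INDEX.get(a, _X_INDEX) for a in sequence.upper()],
                    dtype=np.intp)


class LookupEmbedder:
    """Context-free 21 -> 30 residue embedding table (seeded random init)."""

    def __init__(self, seed: int = 0, table: np.ndarray | None = None):
        if table is None:
            rng = np.random.default_rng(seed)
            table = rng.normal(0.0, 1.0, size=(len(AA_ALPHABET), EMBED_DIM))
        self.table = np.asarray(table, dtype=np.float64)

    def __call__(self, sequence: str) -> np.ndarray:
        return self.table[sequence_to_indices(sequence)]


def embed_residues(sequence: str, embedder) -> np.ndarray:
    """Embed a sequence to an (L, 30) matrix via any embedder callable."""
    if len(sequence) == 0:
        raise ValueError("cannot embed an empty sequence")
    out = np.asarray(embedder(sequence), dtype=np.float64)
    if out.shape != (len(sequence), EMBED_DIM):
        raise ValueError(f"embedder returned shape {out.shape}, "
                         f"expected {(len(sequence), EMBED_DIM)}")
    return out


def build_residue_graph(record: ProteinRecord, threshold: float = 0.5) -> TargetGraph:
    """Threshold the contact map into a weighted residue graph.

    Off-diagonal entries with ``M_ij >= threshold`` become edges of weight
    ``M_ij``; consecutive residues (i, i+1) are always connected with weight
    1.0 (a backbone floor) so the graph stays connected under sparse maps.
    """
    if record.contact_map is None:
        raise ValueError(f"protein {record.target_id!r} has no contact map")
    m = np.asarray(record.contact_map, dtype=np.float64)
    n = len(record.sequence)
    if m.shape != (n, n):
        raise ValueError("contact map shape must be (L, L)")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"contact map for {record.target_id!r} is not symmetric")
    w = np.where(m >= threshold, m, 0.0)
    np.fill_diagonal(w, 0.0)
    if n > 1:
        idx = np.arange(n - 1)
        w[idx, idx + 1] = 1.0       # backbone floor
        w[idx + 1, idx] = 1.0
    src, dst = np.nonzero(w)
    return TargetGraph(n_nodes=n, src=src.astype(np.intp), dst=dst.astype(np.intp),
                       weight=w[src, dst], node_features=record.residue_embeddings)


# -- learnable parameters -------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


def init_target_encoder(rng: np.random.Generator, cfg: TargetEncoderConfig) -> dict:
    c, e = cfg.channels, cfg.embed_dim
    params: dict = {
        "embed_table": Tensor(rng.normal(0, 1.0, size=(len(AA_ALPHABET), e)),
                              requires_grad=True),
        "conv": [], "wgcn": [],
    }
    cin = e
    for w in cfg.windows:
        params["conv"].append({
            "W": _glorot(rng, w * cin, c),
            "b": Tensor(np.zeros(c), requires_grad=True),
            "window": w,
        })
        cin = c
    params["proj_W"] = _glorot(rng, c * len(cfg.windows), c)
    params["proj_b"] = Tensor(np.zeros(c), requires_grad=True)
    cin = e
    for _ in range(cfg.n_wgcn_layers):
        params["wgcn"].append({
            "W1": _glorot(rng, cin, c),
            "W2": _glorot(rng, cin, c),
            "b": Tensor(np.zeros(c), requires_grad=True),
        })
        cin = c
    params["Ws"] = _glorot(rng, c, c)
    params["Wg"] = _glorot(rng, c, c)
    params["Wt"] = _glorot(rng, c, c)
    return params


def named_target_params(params: dict, prefix: str = "target") -> dict[str, Tensor]:
    flat = {f"{prefix}.embed_table": params["embed_table"],
            f"{prefix}.proj_W": params["proj_W"], f"{prefix}.proj_b": params["proj_b"],
            f"{prefix}.Ws": params["Ws"], f"{prefix}.Wg": params["Wg"],
            f"{prefix}.Wt": params["Wt"]}
    for i, layer in enumerate(params["conv"]):
        flat[f"{prefix}.conv{i}.W"] = layer["W"]
        flat[f"{prefix}.conv{i}.b"] = layer["b"]
    for i, layer in enumerate(params["wgcn"]):
        for k in ("W1", "W2", "b"):
            flat[f"{prefix}.wgcn{i}.{k}"] = layer[k]
    return flat


# -- forward ops ----------------------------------------------------------

def _conv1d_same(x: Tensor, W: Tensor, b: Tensor, window: int) -> Tensor:
    """Same-padded 1-D convolution along rows via im2col + matmul."""
    L, cin = x.shape
    pad = (window - 1) // 2
    zeros = Tensor(np.zeros((pad, cin)))
    xp = ad.concatenate([zeros, x, zeros], axis=0) if pad else x
    idx = np.arange(L)[:, None] + np.arange(window)[None, :]   # (L, window)
    windows = ad.gather(xp, idx)                               # (L, window, cin)
    return windows.reshape(L, window * cin) @ W + b.reshape(1, -1)


def multiscale_cnn(embeddings: Tensor | np.ndarray, params: dict) -> Tensor:
    """Three stacked same-padded 1-D convolutions; outputs concatenated and
    linearly projected to ``C`` channels.  Length is preserved throughout."""
    x = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    outs = []
    h = x
    for layer in params["conv"]:
        h = ad.relu(_conv1d_same(h, layer["W"], layer["b"], layer["window"]))
        outs.append(h)
    combined = ad.concatenate(outs, axis=1)
    return combined @ params["proj_W"] + params["proj_b"].reshape(1, -1)


def wgcn_layer(graph: TargetGraph, states: Tensor, params: dict,
               activation=ad.relu) -> Tensor:
    """Weighted graph convolution (contact probability / degree normalised)."""
    if states.shape[0] != graph.n_nodes:
        raise ValueError("state rows must equal node count")
    pre = states @ params["W1"]
    if len(graph.src):
        coeff = graph.weight / (np.sqrt(graph.degree[graph.src]) *
                                np.sqrt(graph.degree[graph.dst]))
        msg = ad.gather(states, graph.src) * Tensor(coeff[:, None])
        agg = ad.segment_sum(msg, graph.dst, graph.n_nodes)
        pre = pre + agg @ params["W2"]
    pre = pre + params["b"].reshape(1, -1)
    return activation(pre) if activation is not None else pre


def _l2_rows(x: Tensor) -> Tensor:
    """Row-wise L2 normalisation; all-zero rows pass through unchanged."""
    norm = ad.sqrt(ad.clip_min((x * x).sum(axis=1, keepdims=True), 1e-24))
    return x / norm


def fuse_target(t_seq: Tensor, t_graph: Tensor | None, params: dict) -> Tensor:
    """Fuse the channels and max-pool over residues into the embedding."""
    fused = _l2_rows(t_seq @ params["Ws"])
    if t_graph is not None:
        if t_graph.shape[0] != t_seq.shape[0]:
            raise ValueError("sequence and graph channels disagree on length")
        fused = fused + _l2_rows(t_graph @ params["Wg"])
    fused = fused @ params["Wt"]
    return fused.max(axis=0)


def encode_target(record: ProteinRecord, params: dict, cfg: TargetEncoderConfig,
                  graph: TargetGraph | None = None) -> Tensor:
    """Encode one protein to a ``C``-vector.

    ``graph`` may be passed pre-built (and is required when
    ``cfg.use_graph``); sequences longer than ``cfg.max_len`` must be
    truncated by the caller before graph construction.
    """
    seq = record.sequence[: cfg.max_len]
    if record.residue_embeddings is not None:
        emb = Tensor(record.residue_embeddings[: cfg.max_len])
    else:
        emb = ad.gather(params["embed_table"], sequence_to_indices(seq))
    t_seq = multiscale_cnn(emb, params)
    t_graph = None
    if cfg.use_graph:
        if graph is None:
            graph = build_residue_graph(record, cfg.contact_threshold)
        h = emb
        for layer in params["wgcn"]:
            h = wgcn_layer(graph, h, layer)
        t_graph = h
    return fuse_target(t_seq, t_graph, params)
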