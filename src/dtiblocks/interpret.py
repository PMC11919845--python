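"""Interpretability: per-block feature diversity and gradient attribution.

*Feature diversity* quantifies over-smoothing.  For the node-feature matrix
of one block, ``d_ij`` is the Euclidean distance between node vectors,
``DS_i`` the mean distance of node i to every other node, and ``DS_G`` the
mean of the ``DS_i``.  A healthy deep encoder keeps ``DS_G`` away from zero
at every depth; collapse to zero means all atoms have become
indistinguishable.

*Gradient-weighted attribution* explains a single prediction.  For the
captured node-state matrix ``H(n)`` of block n, the channel weight
``alpha_k(n)`` is the mean over atoms of dP/dH[:, k], and the per-atom
importance is ``W(n) = sum_k alpha_k(n) H[:, k]`` (no rectification is
applied, so negative importances are reported as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chem_graph import MolecularGraph

__all__ = ["DiversityReport", "AttributionMap", "graph_diversity",
           "diversity_by_block", "grad_attribution"]


@dataclass
class DiversityReport:
    """Per-block diversity of a drug's node features (block 0 = initial)."""
    per_node: list[np.ndarray]        # DS_i vectors, one per block
    per_graph: list[float]            # DS_G per block

    @property
    def n_blocks(self) -> int:
        return len(self.per_graph)


@dataclass
class AttributionMap:
    """Per-block node-importance vectors for one drug-target prediction."""
    drug_id: str
    target_id: str
    probability: float
    channel_weights: list[np.ndarray]   # alpha(n) per block
    node_importance: list[np.ndarray]   # W(n) per block, one value per atom


def graph_diversity(node_features: np.ndarray) -> tuple[np.ndarray, float]:
    """(DS_i per node, DS_G) for one feature matrix; needs >= 2 nodes."""
    x = np.asarray(node_features, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("feature diversity is undefined for a single node")
    d = squareform(pdist(x, metric="euclidean"))
    ds_i = d.sum(axis=1) / (n - 1)
    return ds_i, float(ds_i.mean())


def diversity_by_block(results, graph: MolecularGraph) -> DiversityReport:
    """Capture every block's post-gating node state and score its diversity.

    ``results`` is a fitted (or freshly initialised) :class:`DTIResults`-like
    object exposing ``model`` and ``params``.
    """
    from .drug_encoder import encode_drug
    capture: list = []
    encode_drug(graph, results.params["drug"], results.model.drug_config,
                capture=capture)
    per_node, per_graph = [], []
    for state in capture:
        ds_i, ds_g = graph_diversity(state.data)
        per_node.append(ds_i)
        per_graph.append(ds_g)
    return DiversityReport(per_node=per_node, per_graph=per_graph)


def grad_attribution(results, drug_id: str, target_id: str,
                     use_logit: bool = False) -> AttributionMap:
    """Gradient-weighted node importance per block for one pair."""
    model = results.model
    graph = model.dataset.drugs[drug_id]
    if graph.num_atoms == 0:
        raise ValueError("cannot attribute over an empty graph")
    capture: list = []
    p = model.forward_single(results.params, drug_id, target_id,
                             capture=capture, return_logit=use_logit)
    p.backward(np.ones_like(p.data))
    alphas, importances = [], []
    for state in capture:
        grad = state.grad if state.grad is not None else np.zeros_like(state.data)
        alpha = grad.mean(axis=0)                  # (C,)
        alphas.append(alpha)
        importances.append(state.data @ alpha)     # (|V|,)
    val = float(np.ravel(p.data)[0])
    prob = val if not use_logit else float(1.0 / (1.0 + np.exp(-val)))
    return AttributionMap(drug_id=drug_id, target_id=target_id,
                          probability=prob, channel_weights=alphas,
                          node_importance=importances)
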