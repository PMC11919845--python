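"""Drug-target interaction model: joint encoders, MLP head, training loop.

The public surface follows the Model/Results convention: build a
:class:`DTIModel` from a :class:`DTIDataset` plus encoder configuration,
call :meth:`DTIModel.fit` with train/validation indices and a
:class:`TrainConfig`, and receive a :class:`DTIResults` carrying the fitted
parameters, per-epoch history, and evaluation / ranking / attribution
methods.

The classifier concatenates the drug and target embeddings and applies a
three-layer MLP (ReLU + dropout after the first two layers) ending in a
sigmoid; training minimises binary cross-entropy with Adam, keeping the
parameters of the epoch with the best validation AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .autodiff import Tensor, Adam
from .chem_graph import MolecularGraph
from .drug_encoder import (DrugEncoderConfig, init_drug_encoder, named_drug_params,
                           encode_drug_batch, encode_drug)
from .target_encoder import (TargetEncoderConfig, ProteinRecord, TargetGraph,
                             init_target_encoder, named_target_params,
                             build_residue_graph, encode_target)

__all__ = ["DTIPair", "DTIDataset", "TrainConfig", "DTIModel", "DTIResults",
           "predict", "bce_loss", "init_head"]

_EPS = 1e-7


@dataclass
class DTIPair:
    drug_id: str
    target_id: str
    label: int


class DTIDataset:
    """Labelled drug-target pairs with resolvable entity tables."""

    def __init__(self, pairs: pd.DataFrame, drugs: dict[str, MolecularGraph],
                 targets: dict[str, ProteinRecord]):
        required = {"drug_id", "target_id", "label"}
        if not required.issubset(pairs.columns):
            raise ValueError(f"pairs table needs columns {sorted(required)}")
        missing_d = set(pairs["drug_id"]) - set(drugs)
        missing_t = set(pairs["target_id"]) - set(targets)
        if missing_d:
            raise ValueError(f"pairs reference unknown drugs, e.g. {sorted(missing_d)[:3]}")
        if missing_t:
            raise ValueError(f"pairs reference unknown targets, e.g. {sorted(missing_t)[:3]}")
        bad = set(pairs["label"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")
        self.pairs = pairs.reset_index(drop=True)
        self.drugs = drugs
        self.targets = targets

    def __len__(self):
        return len(self.pairs)


@dataclass
class TrainConfig:
    """Optimisation settings; one master seed drives all randomness."""
    batch_size: int = 64
    learning_rate: float = 5e-4
    dropout: float = 0.2
    max_epochs: int = 50
    patience: int = 20
    seed: int = 0
    undersample: bool = False

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.patience) <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("batch_size, learning_rate, max_epochs, patience must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


# -- prediction head ------------------------------------------------------

def init_head(rng: np.random.Generator, in_dim: int,
              widths: tuple[int, int] = (512, 128)) -> dict:
    def glorot(a, b):
        lim = np.sqrt(6.0 / (a + b))
        return Tensor(rng.uniform(-lim, lim, size=(a, b)), requires_grad=True)
    w1, w2 = widths
    return {
        "W1": glorot(in_dim, w1), "b1": Tensor(np.zeros(w1), requires_grad=True),
        "W2": glorot(w1, w2), "b2": Tensor(np.zeros(w2), requires_grad=True),
        "W3": glorot(w2, 1), "b3": Tensor(np.zeros(1), requires_grad=True),
    }


def predict(drug_emb: Tensor, target_emb: Tensor, head: dict,
            training: bool = False, rng: np.random.Generator | None = None,
            dropout: float = 0.2, return_logit: bool = False) -> Tensor:
    """Interaction probability from concatenated embeddings (row-batched)."""
    if drug_emb.ndim == 1:
        drug_emb = drug_emb.reshape(1, -1)
    if target_emb.ndim == 1:
        target_emb = target_emb.reshape(1, -1)
    h = ad.concatenate([drug_emb, target_emb], axis=1)
    for wk, bk in (("W1", "b1"), ("W2", "b2")):
        h = ad.relu(h @ head[wk] + head[bk].reshape(1, -1))
        if training and dropout > 0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * Tensor(mask)
    logit = (h @ head["W3"] + head["b3"].reshape(1, -1)).reshape(-1)
    return logit if return_logit else ad.sigmoid(logit)


def bce_loss(y, y_hat):
    """Binary cross-entropy; predictions are clamped to [eps, 1-eps].

    Accepts floats/arrays (returns an ndarray/float) or autodiff tensors
    (returns a scalar Tensor of the mean loss).
    """
    if isinstance(y_hat, Tensor):
        y = Tensor(np.asarray(y, dtype=np.float64))
        p = ad.clip_min(y_hat, _EPS)
        q = ad.clip_min(1.0 - y_hat, _EPS)
        return (-(y * ad.log(p) + (1.0 - y) * ad.log(q))).mean()
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), _EPS, 1.0 - _EPS)
    out = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(out) if out.ndim == 0 else out


# -- model / results ------------------------------------------------------

class DTIModel:
    """DTI predictor built from a dataset and encoder configuration."""

    def __init__(self, dataset: DTIDataset,
                 drug_config: DrugEncoderConfig | None = None,
                 target_config: TargetEncoderConfig | None = None,
                 head_widths: tuple[int, int] = (512, 128)):
        self.dataset = dataset
        self.drug_config = drug_config or DrugEncoderConfig()
        self.target_config = target_config or TargetEncoderConfig(
            channels=self.drug_config.channels)
        self.head_widths = head_widths
        self._target_graphs: dict[str, TargetGraph] = {}

    # dataset-level caches -------------------------------------------------
    def _graph_for(self, target_id: str) -> TargetGraph | None:
        if not self.target_config.use_graph:
            return None
        if target_id not in self._target_graphs:
            rec = self.dataset.targets[target_id]
            if rec.contact_map is None:
                raise ValueError(f"target {target_id!r} lacks a contact map but the "
                                 "graph channel is enabled")
            rec = self._truncated(rec)
            self._target_graphs[target_id] = build_residue_graph(
                rec, self.target_config.contact_threshold)
        return self._target_graphs[target_id]

    def _truncated(self, rec: ProteinRecord) -> ProteinRecord:
        ml = self.target_config.max_len
        if len(rec.sequence) <= ml:
            return rec
        return ProteinRecord(
            rec.target_id, rec.sequence[:ml],
            None if rec.residue_embeddings is None else rec.residue_embeddings[:ml],
            None if rec.contact_map is None else rec.contact_map[:ml, :ml])

    # parameters -----------------------------------------------------------
    def init_params(self, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        in_dim = self.drug_config.channels + self.target_config.channels
        return {"drug": init_drug_encoder(rng, self.drug_config),
                "target": init_target_encoder(rng, self.target_config),
                "head": init_head(rng, in_dim, self.head_widths)}

    @staticmethod
    def named_params(params: dict) -> dict[str, Tensor]:
        flat = named_drug_params(params["drug"])
        flat.update(named_target_params(params["target"]))
        flat.update({f"head.{k}": v for k, v in params["head"].items()})
        return flat

    # forward --------------------------------------------------------------
    def _forward_pairs(self, params: dict, rows: pd.DataFrame, training: bool,
                       rng: np.random.Generator | None) -> Tensor:
        drug_ids = rows["drug_id"].tolist()
        target_ids = rows["target_id"].tolist()
        uniq_d = sorted(set(drug_ids))
        uniq_t = sorted(set(target_ids))
        d_pos = {d: i for i, d in enumerate(uniq_d)}
        t_pos = {t: i for i, t in enumerate(uniq_t)}
        d_emb = encode_drug_batch([self.dataset.drugs[d] for d in uniq_d],
                                  params["drug"], self.drug_config,
                                  training=training, rng=rng)
        t_rows = []
        for t in uniq_t:
            rec = self._truncated(self.dataset.targets[t])
            emb = encode_target(rec, params["target"], self.target_config,
                                graph=self._graph_for(t))
            t_rows.append(emb.reshape(1, -1))
        t_emb = ad.concatenate(t_rows, axis=0)
        de = ad.gather(d_emb, np.array([d_pos[d] for d in drug_ids]))
        te = ad.gather(t_emb, np.array([t_pos[t] for t in target_ids]))
        return predict(de, te, params["head"], training=training, rng=rng,
                       dropout=self.drug_config.dropout)

    def forward_single(self, params: dict, drug_id: str, target_id: str,
                       capture: list | None = None,
                       return_logit: bool = False,
                       perturb: dict | None = None) -> Tensor:
        """One pair, eval mode, with optional per-block drug-state capture."""
        d_emb = encode_drug(self.dataset.drugs[drug_id], params["drug"],
                            self.drug_config, capture=capture, perturb=perturb)
        rec = self._truncated(self.dataset.targets[target_id])
        t_emb = encode_target(rec, params["target"], self.target_config,
                              graph=self._graph_for(target_id))
        return predict(d_emb, t_emb, params["head"], training=False,
                       return_logit=return_logit)

    # fitting ---------------------------------------------------------------
    def fit(self, train_idx, val_idx, config: TrainConfig | None = None,
            verbose: bool = False) -> "DTIResults":
        cfg = config or TrainConfig()
        train_idx = np.asarray(train_idx)
        val_idx = np.asarray(val_idx)
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValueError("train and validation splits must be non-empty")
        if set(train_idx) & set(val_idx):
            raise ValueError("train and validation splits overlap")
        rng = np.random.default_rng(cfg.seed)
        params = self.init_params(int(rng.integers(2 ** 31)))
        flat = self.named_params(params)
        opt = Adam(flat, lr=cfg.learning_rate)

        if cfg.undersample:
            train_idx = _undersample(self.dataset.pairs, train_idx, rng)

        val_rows = self.dataset.pairs.iloc[val_idx]
        history: list[dict] = []
        best = {"auroc": -np.inf, "epoch": -1, "params": None}
        since_best = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_idx))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = train_idx[order[start:start + cfg.batch_size]]
                rows = self.dataset.pairs.iloc[batch]
                opt.zero_grad()
                y_hat = self._forward_pairs(params, rows, training=True, rng=rng)
                loss = bce_loss(rows["label"].to_numpy(), y_hat)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss.data}")
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_scores = self.predict_with(params, val_rows)
            val_auroc = roc_auc_score(val_rows["label"].to_numpy(), val_scores) \
                if val_rows["label"].nunique() == 2 else np.nan
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_auroc": float(val_auroc)})
            if verbose:
                print(f"epoch {epoch}: loss={np.mean(losses):.4f} val_auroc={val_auroc:.4f}")
            if np.isfinite(val_auroc) and val_auroc > best["auroc"]:
                best = {"auroc": float(val_auroc), "epoch": epoch,
                        "params": {k: v.data.copy() for k, v in flat.items()}}
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best["params"] is not None:
            for k, v in flat.items():
                v.data = best["params"][k]
        return DTIResults(self, params, cfg, history,
                          best_epoch=best["epoch"], best_val_auroc=best["auroc"])

    def predict_with(self, params: dict, rows: pd.DataFrame,
                     batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(rows), batch_size):
            chunk = rows.iloc[start:start + batch_size]
            out.append(self._forward_pairs(params, chunk, training=False,
                                           rng=None).data)
        return np.concatenate(out) if out else np.zeros(0)


def _undersample(pairs: pd.DataFrame, idx: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Balance the training indices to a 1:1 class ratio by downsampling."""
    labels = pairs.iloc[idx]["label"].to_numpy()
    pos = idx[labels == 1]
    neg = idx[labels == 0]
    n = min(len(pos), len(neg))
    if n == 0:
        return idx
    keep = np.concatenate([rng.choice(pos, n, replace=False),
                           rng.choice(neg, n, replace=False)])
    rng.shuffle(keep)
    return keep


class DTIResults:
    """Fitted model: parameters, training history, evaluation utilities."""

    def __init__(self, model: DTIModel, params: dict, config: TrainConfig,
                 history: list[dict], best_epoch: int = -1,
                 best_val_auroc: float = np.nan):
        self.model = model
        self.params = params
        self.config = config
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_auroc = best_val_auroc

    # prediction ----------------------------------------------------------
    def predict_pairs(self, pairs: pd.DataFrame | list) -> np.ndarray:
        if isinstance(pairs, list):
            pairs = pd.DataFrame(pairs, columns=["drug_id", "target_id"])
        return self.model.predict_with(self.params, pairs)

    def predict_indices(self, idx) -> np.ndarray:
        return self.model.predict_with(self.params,
                                       self.model.dataset.pairs.iloc[np.asarray(idx)])

    def evaluate(self, idx) -> "MetricsReport":
        from .splits_metrics import evaluate, MetricsReport  # circular-safe
        rows = self.model.dataset.pairs.iloc[np.asarray(idx)]
        return evaluate(self.predict_pairs(rows[["drug_id", "target_id"]]),
                        rows["label"].to_numpy())

    # persistence ----------------------------------------------------------
    def save(self, path: str):
        flat = self.model.named_params(self.params)
        meta = {
            "drug_config": {k: v for k, v in vars(self.model.drug_config).items()
                            if k not in ("block", "initial_block")},
            "target_config": vars(self.model.target_config).copy(),
            "head_widths": list(self.model.head_widths),
            "train_config": asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_auroc": self.best_val_auroc,
        }
        meta["target_config"]["windows"] = list(meta["target_config"]["windows"])
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **{k: v.data for k, v in flat.items()})

    @classmethod
    def load(cls, path: str, dataset: DTIDataset) -> "DTIResults":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            arrays = {k: f[k] for k in f.files if k != "__meta__"}
        dc = {k: v for k, v in meta["drug_config"].items()}
        model = DTIModel(dataset,
                         drug_config=DrugEncoderConfig(**dc),
                         target_config=TargetEncoderConfig(
                             **{**meta["target_config"],
                                "windows": tuple(meta["target_config"]["windows"])}),
                         head_widths=tuple(meta["head_widths"]))
        params = model.init_params(0)
        flat = model.named_params(params)
        for k, v in flat.items():
            v.data = arrays[k]
        res = cls(model, params, TrainConfig(**meta["train_config"]),
                  meta["history"], meta["best_epoch"], meta["best_val_auroc"])
        return res

    # reporting ------------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        n_params = sum(v.data.size for v in m.named_params(self.params).values())
        lines = [
            "DTI model fit summary",
            "=" * 52,
            f"pairs: {len(m.dataset)}  drugs: {len(m.dataset.drugs)}  "
            f"targets: {len(m.dataset.targets)}",
            f"drug encoder: {m.drug_config.n_blocks} blocks x "
            f"{m.drug_config.n_layers} layers ({m.drug_config.gnn_type}), "
            f"C={m.drug_config.channels}, d={m.drug_config.enhancement_scale}",
            f"target encoder: windows {m.target_config.windows}, "
            f"{m.target_config.n_wgcn_layers} WGCN layers, "
            f"graph={'on' if m.target_config.use_graph else 'off'}",
            f"parameters: {n_params}",
            f"epochs run: {len(self.history)}  best epoch: {self.best_epoch}  "
            f"best val AUROC: {self.best_val_auroc:.4f}",
        ]
        if self.history:
            lines.append(f"final train loss: {self.history[-1]['train_loss']:.4f}")
        return "\n".join(lines)
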