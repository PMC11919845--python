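"""Self-contained synthetic DTI benchmarks with a planted interaction rule.

The generator emits a drug library (fragment-grammar SMILES), a target
library (random sequences with walk-derived contact maps) and a labelled
pair table.  The clean interaction rule is a conjunction: a pair is positive
iff the drug contains a marker substructure (default: a carboxylic acid,
SMARTS ``C(=O)O``) AND the target contains a marker residue motif (default
a 5-mer substring).  The conjunction forces a predictor to use both the
chemistry branch and the protein branch; an OR-rule variant exists for
ablation-style experiments.

Contact maps emulate structure-prediction output: residues are placed by a
self-avoiding walk on the 3-D unit lattice and the contact probability is
``M_ij = exp(-dist_ij / lambda)``, symmetric with entries in (0, 1].
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_graph import smiles_to_graph
from .dti_model import DTIDataset
from .target_encoder import ProteinRecord

__all__ = ["SyntheticSpec", "generate_drugs", "generate_targets",
           "generate_pairs", "generate_dataset"]

# fragment grammar: each piece starts and ends on an atom with free valence,
# closes its own rings, and avoids oxygen-terminal atoms so the acid motif
# cannot arise by accidental concatenation (verified anyway).
_FRAGMENTS = [
    "C", "CC", "CCC", "CN", "CCN", "C(C)C", "CS", "C=C", "COC", "CNC",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "C(=O)N",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    n_drugs: int = 300
    n_targets: int = 100
    n_pairs: int = 1000
    pos_fraction: float = 0.5
    drug_motif: str = "C(=O)O"          # SMARTS-matchable substructure
    protein_motif: str = "HKWCE"        # residue substring
    drug_motif_fraction: float = 0.5
    target_motif_fraction: float = 0.5
    label_noise: float = 0.0
    contact_decay: float = 3.0          # lambda, lattice units
    min_len: int = 50
    max_len: int = 300
    rule: str = "and"                   # "and" | "or"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.pos_fraction < 1.0:
            raise ValueError("pos_fraction must lie in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.contact_decay <= 0:
            raise ValueError("contact_decay must be positive")
        if self.rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")


def _assemble_smiles(rng: np.random.Generator, with_motif: bool,
                     motif: str, pattern) -> str:
    for _ in range(100):
        n_frag = int(rng.integers(2, 7))
        base = "".join(rng.choice(_FRAGMENTS) for _ in range(n_frag))
        smiles = base + motif if with_motif else base
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if mol.HasSubstructMatch(pattern) == with_motif:
            return smiles
    raise RuntimeError("fragment grammar failed to produce a valid molecule")


def generate_drugs(spec: SyntheticSpec) -> pd.DataFrame:
    """SMILES library; exactly round(fraction * n) molecules carry the motif."""
    rng = np.random.default_rng(spec.seed)
    pattern = Chem.MolFromSmarts(spec.drug_motif)
    if pattern is None:
        raise ValueError(f"invalid drug motif pattern {spec.drug_motif!r}")
    n_motif = int(round(spec.drug_motif_fraction * spec.n_drugs))
    flags = np.zeros(spec.n_drugs, dtype=bool)
    flags[rng.choice(spec.n_drugs, size=n_motif, replace=False)] = True
    rows = []
    for i in range(spec.n_drugs):
        smiles = _assemble_smiles(rng, bool(flags[i]), spec.drug_motif, pattern)
        rows.append({"drug_id": f"D{i:04d}", "smiles": smiles,
                     "has_motif": bool(flags[i])})
    return pd.DataFrame(rows)


def _self_avoiding_walk(rng: np.random.Generator, n: int,
                        max_attempts: int = 1000) -> np.ndarray:
    """Kinetic-growth self-avoiding walk on the 3-D unit lattice."""
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for _ in range(max_attempts):
        pos = np.zeros((n, 3), dtype=np.int64)
        seen = {(0, 0, 0)}
        ok = True
        for i in range(1, n):
            cands = [tuple(pos[i - 1] + s) for s in steps]
            free = [c for c in cands if c not in seen]
            if not free:
                ok = False
                break
            nxt = free[int(rng.integers(len(free)))]
            pos[i] = nxt
            seen.add(nxt)
        if ok:
            return pos
    raise RuntimeError(f"self-avoiding walk failed after {max_attempts} attempts")


def _contact_map(rng: np.random.Generator, n: int, decay: float) -> np.ndarray:
    pos = _self_avoiding_walk(rng, n)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return np.exp(-dist / decay)


def generate_targets(spec: SyntheticSpec) -> tuple[dict[str, ProteinRecord], pd.DataFrame]:
    """Random sequences (length 50-300) with synthetic contact maps."""
    rng = np.random.default_rng(spec.seed + 1)
    n_motif = int(round(spec.target_motif_fraction * spec.n_targets))
    flags = np.zeros(spec.n_targets, dtype=bool)
    flags[rng.choice(spec.n_targets, size=n_motif, replace=False)] = True
    records: dict[str, ProteinRecord] = {}
    rows = []
    for i in range(spec.n_targets):
        while True:
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            seq = "".join(rng.choice(list(_AA20), size=length))
            if spec.protein_motif not in seq:
                break
        if flags[i]:
            at = int(rng.integers(0, length - len(spec.protein_motif) + 1))
            seq = seq[:at] + spec.protein_motif + seq[at + len(spec.protein_motif):]
        tid = f"T{i:04d}"
        cmap = _contact_map(rng, length, spec.contact_decay)
        records[tid] = ProteinRecord(target_id=tid, sequence=seq, contact_map=cmap)
        rows.append({"target_id": tid, "sequence": seq, "has_motif": bool(flags[i])})
    return records, pd.DataFrame(rows)


def _clean_label(drug_motif: bool, target_motif: bool, rule: str) -> int:
    if rule == "and":
        return int(drug_motif and target_motif)
    return int(drug_motif or target_motif)


def generate_pairs(drugs: pd.DataFrame, targets: pd.DataFrame,
                   spec: SyntheticSpec) -> pd.DataFrame:
    """Sample unique labelled pairs hitting ``pos_fraction`` exactly pre-noise."""
    if len(drugs) == 0 or len(targets) == 0:
        raise ValueError("drug and target libraries must be non-empty")
    rng = np.random.default_rng(spec.seed + 2)
    d_flag = drugs["has_motif"].to_numpy()
    t_flag = targets["has_motif"].to_numpy()
    clean = np.array([[_clean_label(d, t, spec.rule) for t in t_flag]
                      for d in d_flag])
    pos_cells = np.argwhere(clean == 1)
    neg_cells = np.argwhere(clean == 0)
    n_pos = int(round(spec.pos_fraction * spec.n_pairs))
    n_neg = spec.n_pairs - n_pos
    if n_pos > len(pos_cells) or n_neg > len(neg_cells):
        raise ValueError(
            f"requested pos_fraction unreachable: need {n_pos} positives / "
            f"{n_neg} negatives, libraries offer {len(pos_cells)} / {len(neg_cells)}")
    chosen_pos = pos_cells[rng.choice(len(pos_cells), size=n_pos, replace=False)]
    chosen_neg = neg_cells[rng.choice(len(neg_cells), size=n_neg, replace=False)]
    cells = np.concatenate([chosen_pos, chosen_neg])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    flips = rng.random(spec.n_pairs) < spec.label_noise
    labels = np.where(flips, 1 - labels, labels)
    df = pd.DataFrame({
        "drug_id": drugs["drug_id"].to_numpy()[cells[:, 0]],
        "target_id": targets["target_id"].to_numpy()[cells[:, 1]],
        "label": labels,
    })
    return df.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))
                     ).reset_index(drop=True)


def generate_dataset(spec: SyntheticSpec
                     ) -> tuple[DTIDataset, pd.DataFrame, pd.DataFrame]:
    """Full benchmark: (dataset, drug table, target table)."""
    drugs = generate_drugs(spec)
    records, targets = generate_targets(spec)
    pairs = generate_pairs(drugs, targets, spec)
    graphs = {r.drug_id: smiles_to_graph(r.smiles, r.drug_id)
              for r in drugs.itertuples()}
    return DTIDataset(pairs, graphs, records), drugs, targets
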