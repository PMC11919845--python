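"""SMILES -> molecular graph conversion with indicator atom features.

Atoms become nodes carrying a 64-dimensional indicator feature vector built
from five atomic properties: element symbol, formal charge, heavy-atom
degree, aromaticity and ring membership.  Bonds become pairs of directed
edges.  Hydrogens stay implicit; the graph is over heavy atoms only, which
matches the degree semantics used by the featurizer.

Feature layout (64 = 49 + 6 + 7 + 1 + 1):

=========  =====  =============================================
block      slots  meaning
=========  =====  =============================================
symbol     49     one-hot over ``ELEMENT_VOCAB`` + trailing "other"
charge     6      one-hot over {-2, -1, 0, +1, +2} + "other"
degree     7      one-hot over {0..5} + ">=6"
aromatic   1      binary flag
ring       1      binary flag
=========  =====  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["MolecularGraph", "featurize_atom", "smiles_to_graph",
           "ELEMENT_VOCAB", "FEATURE_DIM"]

# 48 elements common in drug-like and biologically relevant molecules;
# everything else routes to the trailing "other" slot.
ELEMENT_VOCAB = [
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "H", "Li", "Na", "K", "Mg", "Ca", "Fe", "Zn",
    "Cu", "Mn", "Co", "Ni", "Mo", "Cr", "V", "W", "Pt", "Pd",
    "Au", "Ag", "Hg", "Al", "As", "Sb", "Sn", "Pb", "Bi", "Ba",
    "Sr", "Cs", "Rb", "Be", "Ti", "Zr", "Cd", "Ga",
]
_SYMBOL_SLOTS = len(ELEMENT_VOCAB) + 1          # 49 (+ "other")
_CHARGE_LEVELS = [-2, -1, 0, 1, 2]              # + "other" -> 6
_CHARGE_SLOTS = len(_CHARGE_LEVELS) + 1
_DEGREE_SLOTS = 7                               # 0..5, >=6
FEATURE_DIM = _SYMBOL_SLOTS + _CHARGE_SLOTS + _DEGREE_SLOTS + 2  # 64

_SYMBOL_INDEX = {s: i for i, s in enumerate(ELEMENT_VOCAB)}
_CHARGE_INDEX = {c: i for i, c in enumerate(_CHARGE_LEVELS)}


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug molecule.

    ``edges`` stores directed pairs; every bond contributes (i, j) and (j, i).
    """

    drug_id: str
    smiles: str
    node_features: np.ndarray            # (num_atoms, 64)
    edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]

    def edge_index(self) -> np.ndarray:
        """Edges as a (2, E) int array (source row, destination row)."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.intp)
        return np.asarray(self.edges, dtype=np.intp).T

    def permuted(self, perm: np.ndarray) -> "MolecularGraph":
        """Relabel atoms by ``perm`` (new index of old atom i is perm[i])."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        feats = self.node_features[inv]
        edges = [(int(perm[i]), int(perm[j])) for i, j in self.edges]
        return MolecularGraph(self.drug_id, self.smiles, feats, edges)


def featurize_atom(symbol: str, formal_charge: int, degree: int,
                   is_aromatic: bool, is_in_ring: bool) -> np.ndarray:
    """Build the 64-dim indicator vector for one atom.

    Out-of-vocabulary symbols and charges route to their "other" slot;
    degrees of 6 or more share the final degree slot.
    """
    v = np.zeros(FEATURE_DIM)
    v[_SYMBOL_INDEX.get(symbol, _SYMBOL_SLOTS - 1)] = 1.0
    off = _SYMBOL_SLOTS
    v[off + _CHARGE_INDEX.get(formal_charge, _CHARGE_SLOTS - 1)] = 1.0
    off += _CHARGE_SLOTS
    v[off + min(int(degree), _DEGREE_SLOTS - 1)] = 1.0
    off += _DEGREE_SLOTS
    v[off] = float(bool(is_aromatic))
    v[off + 1] = float(bool(is_in_ring))
    return v


def smiles_to_graph(smiles: str, drug_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises ``ValueError`` naming the offending string when RDKit cannot
    parse it or the molecule has no heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES {smiles!r} yields an empty molecule")
    feats = np.stack([
        featurize_atom(a.GetSymbol(), a.GetFormalCharge(), a.GetDegree(),
                       a.GetIsAromatic(), a.IsInRing())
        for a in mol.GetAtoms()
    ])
    edges: list[tuple[int, int]] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
    return MolecularGraph(drug_id=drug_id, smiles=smiles,
                          node_features=feats, edges=edges)
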