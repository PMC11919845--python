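"""Dataset split strategies and evaluation / screening metrics.

Three families of splits of increasing difficulty for a DTI benchmark:

* ``random``      - pair-level shuffle split;
* ``unseen_*``    - 20% of drugs (or targets) are held out with *all* their
  pairs as the test set, so test entities never appear in training;
* ``cluster_*``   - entities are clustered by chemical (Tanimoto over ECFP4
  fingerprints) or sequence (global-alignment identity) similarity with
  average-linkage hierarchical clustering, and whole clusters are assigned
  to the test side, minimising cross-set similarity.

Classification metrics (AUROC, AUPR, ACC/PR/RE/F1 at threshold 0.5) are
computed with scikit-learn.  Virtual-screening metrics follow the standard
definitions: enrichment factor EF_x% compares the active fraction in the
top x% of a ranked library with the library-wide fraction, and ROC
enrichment Re(t) is TPR/FPR read off the ROC curve at FPR = t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import (roc_auc_score, average_precision_score, roc_curve,
                             accuracy_score, precision_score, recall_score, f1_score)

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = ["SplitSpec", "MetricsReport", "RankingResult",
           "split_pairs", "tanimoto", "ecfp4_bits",
           "drug_similarity_matrix", "target_similarity_matrix",
           "cluster_entities", "evaluate", "rank_candidates",
           "enrichment_factor", "roc_enrichment"]

STRATEGIES = ("random", "unseen_drug", "unseen_target", "cluster_drug", "cluster_target")


@dataclass
class SplitSpec:
    strategy: str = "random"
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if min(self.fractions) <= 0 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


@dataclass
class MetricsReport:
    auroc: float
    aupr: float
    acc: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auroc", "aupr", "acc", "precision", "recall", "f1")}


# -- similarity -----------------------------------------------------------

def ecfp4_bits(smiles: str, n_bits: int = 2048) -> frozenset[int]:
    """On-bit indices of the radius-2 hashed circular (ECFP4) fingerprint."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def tanimoto(fp_a, fp_b) -> float:
    """|A n B| / |A u B| over bit sets; 0.0 when both are empty."""
    a, b = set(fp_a), set(fp_b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def drug_similarity_matrix(smiles_list: list[str]) -> np.ndarray:
    fps = [ecfp4_bits(s) for s in smiles_list]
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])
    return sim


def target_similarity_matrix(sequences: list[str]) -> np.ndarray:
    """Pairwise global-alignment identity (BLOSUM62, gap open 10 / extend 0.5),
    normalised by alignment length."""
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    n = len(sequences)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(sequences[i], sequences[j])[0]
            a, b = aln[0], aln[1]
            ident = sum(x == y and x != "-" for x, y in zip(a, b))
            sim[i, j] = sim[j, i] = ident / len(a)
    return sim


def cluster_entities(similarity: np.ndarray, target_test_fraction: float,
                     min_clusters: int | None = None) -> np.ndarray:
    """Average-linkage clusters on distance ``1 - similarity``.

    The dendrogram is cut at the smallest height that yields at least
    ``ceil(1 / target_test_fraction)`` clusters (or ``min_clusters`` when
    given), so the test side can be assembled from whole clusters.
    Returns integer labels (0-based).
    """
    similarity = np.asarray(similarity, dtype=np.float64)
    n = similarity.shape[0]
    if not np.allclose(similarity, similarity.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    k = min_clusters or int(np.ceil(1.0 / target_test_fraction))
    if n <= k:
        return np.arange(n)
    dist = 1.0 - similarity
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    heights = z[:, 2]
    # n - m clusters remain after m merges; allow at most n - k merges
    cut = heights[n - k] - 1e-12 if n - k < len(heights) else heights[-1] + 1.0
    labels = fcluster(z, t=max(cut, 0.0), criterion="distance") - 1
    if labels.max() == 0:
        raise ValueError("all entities fall in one cluster; a cluster split "
                         "is impossible (entities are too similar)")
    return labels


# -- splits ---------------------------------------------------------------

def _shuffle_split(idx: np.ndarray, fractions, rng) -> tuple[np.ndarray, ...]:
    idx = rng.permutation(idx)
    n = len(idx)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def split_pairs(pairs: pd.DataFrame, spec: SplitSpec,
                drug_table: dict[str, str] | None = None,
                target_table: dict[str, str] | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition pair rows into (train, val, test) index arrays.

    ``drug_table`` maps drug_id -> SMILES (needed for cluster_drug);
    ``target_table`` maps target_id -> sequence (needed for cluster_target).
    """
    rng = np.random.default_rng(spec.seed)
    all_idx = np.arange(len(pairs))
    ftrain, fval, ftest = spec.fractions

    if spec.strategy == "random":
        return _shuffle_split(all_idx, spec.fractions, rng)

    col = "drug_id" if "drug" in spec.strategy else "target_id"
    entities = np.array(sorted(pairs[col].unique()))

    if spec.strategy.startswith("unseen"):
        n_test_ent = max(1, int(round(ftest * len(entities))))
        test_entities = set(rng.choice(entities, size=n_test_ent, replace=False))
    else:  # cluster_*
        if col == "drug_id":
            if drug_table is None:
                raise ValueError("cluster_drug needs drug_table (id -> SMILES)")
            sim = drug_similarity_matrix([drug_table[e] for e in entities])
        else:
            if target_table is None:
                raise ValueError("cluster_target needs target_table (id -> sequence)")
            sim = target_similarity_matrix([target_table[e] for e in entities])
        # finer granularity than the minimal cut so the pair-level test
        # fraction can be approached within a few percentage points
        labels = cluster_entities(sim, ftest,
                                  min_clusters=int(np.ceil(5.0 / ftest)))
        cluster_ids = rng.permutation(np.unique(labels))
        pair_count = pairs[col].value_counts()
        target = ftest * len(pairs)
        test_entities: set = set()
        n_test_pairs = 0
        for c in cluster_ids:
            members = entities[labels == c]
            size = int(sum(pair_count.get(e, 0) for e in members))
            # closest achievable: skip clusters that would overshoot more
            # than they help
            if abs(n_test_pairs + size - target) <= abs(n_test_pairs - target):
                test_entities.update(members)
                n_test_pairs += size
            if n_test_pairs >= target:
                break

    in_test = pairs[col].isin(test_entities).to_numpy()
    test_idx = all_idx[in_test]
    rest = all_idx[~in_test]
    rest = rng.permutation(rest)
    n_train = int(round(len(rest) * ftrain / (ftrain + fval)))
    return rest[:n_train], rest[n_train:], test_idx


# -- metrics --------------------------------------------------------------

def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to evaluate")
    pred = (scores >= threshold).astype(int)
    return MetricsReport(
        auroc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        acc=float(accuracy_score(labels, pred)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
    )


def enrichment_factor(labels_sorted: np.ndarray, top_fraction: float) -> float:
    """EF at ``top_fraction`` for labels ordered by decreasing score."""
    labels_sorted = np.asarray(labels_sorted)
    n = len(labels_sorted)
    n_actives = int(labels_sorted.sum())
    if n_actives == 0:
        raise ValueError("EF undefined: library contains no actives")
    top = int(np.ceil(top_fraction * n))
    return (labels_sorted[:top].sum() / top) / (n_actives / n)


def roc_enrichment(scores: np.ndarray, labels: np.ndarray, fpr_threshold: float) -> float:
    """TPR / FPR at the requested FPR, linearly interpolated on the ROC curve."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.interp(fpr_threshold, fpr, tpr) / fpr_threshold)


@dataclass
class RankingResult:
    """Ranked candidate library for one query entity."""
    query_id: str
    candidates: pd.DataFrame          # columns: candidate_id, score, label; sorted
    ef: dict[float, float] = field(default_factory=dict)
    re: dict[float, float] = field(default_factory=dict)
    auroc: float = np.nan


def rank_candidates(results, query_id: str, candidate_ids: list[str],
                    labels: dict[str, int] | None = None,
                    query_kind: str = "target",
                    ef_fractions: tuple[float, ...] = (0.01, 0.05, 0.10),
                    re_fprs: tuple[float, ...] = (0.01, 0.05)) -> RankingResult:
    """Score a candidate library against one query and rank it.

    ``query_kind`` is "target" (rank drugs against a protein) or "drug"
    (rank proteins against a compound).  With ``labels`` provided the
    screening metrics (EF, Re, AUROC) are computed; without labels only the
    ranking is returned.  Ties in score are broken by candidate id so the
    ordering is stable and reproducible.
    """
    if query_kind not in ("target", "drug"):
        raise ValueError("query_kind must be 'target' or 'drug'")
    if query_kind == "target":
        pairs = [(c, query_id) for c in candidate_ids]
    else:
        pairs = [(query_id, c) for c in candidate_ids]
    scores = results.predict_pairs(pairs)
    df = pd.DataFrame({"candidate_id": candidate_ids, "score": scores})
    if labels is not None:
        df["label"] = [int(labels[c]) for c in candidate_ids]
    df = df.sort_values(["score", "candidate_id"],
                        ascending=[False, True], kind="stable").reset_index(drop=True)
    out = RankingResult(query_id=query_id, candidates=df)
    if labels is not None:
        y = df["label"].to_numpy()
        if y.sum() == 0:
            raise ValueError("EF undefined: library contains no actives")
        out.ef = {f: float(enrichment_factor(y, f)) for f in ef_fractions}
        if y.sum() < len(y):
            out.re = {f: roc_enrichment(df["score"].to_numpy(), y, f) for f in re_fprs}
            out.auroc = float(roc_auc_score(y, df["score"].to_numpy()))
    return out
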