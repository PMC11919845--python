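"""Readers and writers for the package's plain-text formats.

Canonical tabular format is TSV (SMILES may contain commas in extensions,
so CSV is unsafe).  Contact maps and residue-embedding matrices are dense
numeric matrix files, whitespace- or comma-delimited, one file per protein
named ``<target_id>.<ext>``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem_graph import smiles_to_graph
from .dti_model import DTIDataset
from .target_encoder import AA_ALPHABET, ProteinRecord

log = logging.getLogger("dtiblocks")

__all__ = ["read_pairs", "write_pairs", "read_fasta", "write_fasta",
           "read_drug_table", "read_contact_map", "load_contacts",
           "read_config", "load_dataset"]

_STANDARD = set(AA_ALPHABET)


def read_pairs(path) -> pd.DataFrame:
    """Read a drug-target pair table (TSV, header required).

    Validates ids, labels and duplicate pairs; errors name the offending
    line numbers (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    needed = {"drug_id", "target_id", "label"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: pair table must have columns {sorted(needed)}")
    bad = df[~df["label"].isin([0, 1])]
    if len(bad):
        line = bad.index[0] + 2
        raise ValueError(f"{path}: line {line}: label must be 0 or 1, "
                         f"got {bad['label'].iloc[0]!r}")
    empty = df[(df["drug_id"].str.len() == 0) | (df["target_id"].str.len() == 0)]
    if len(empty):
        raise ValueError(f"{path}: line {empty.index[0] + 2}: empty id")
    dup = df.duplicated(subset=["drug_id", "target_id"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (drug, target) pairs at lines {lines[:10]}")
    df["label"] = df["label"].astype(int)
    return df


def write_pairs(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: sequence}; ids are the first header token, sequences are
    upper-cased and non-standard letters mapped to X (count logged)."""
    seqs: dict[str, str] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        cleaned = "".join(c if c in _STANDARD else "X" for c in seq)
        n_mapped += sum(a != b for a, b in zip(seq, cleaned))
        seqs[rec.id] = cleaned
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    if n_mapped:
        log.warning("%s: mapped %d non-standard residue letters to X", path, n_mapped)
    return seqs


def write_fasta(seqs: dict[str, str], path):
    with open(path, "w") as fh:
        for k, s in seqs.items():
            fh.write(f">{k}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")


def read_drug_table(path) -> pd.DataFrame:
    """Drug table: TSV with drug_id + smiles columns, or a headerless SMILES
    list (one per line, optional leading tab-separated id)."""
    with open(path) as fh:
        first = fh.readline()
    if "smiles" in first.lower():
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "drug_id" not in df.columns or "smiles" not in df.columns:
            raise ValueError(f"{path}: need drug_id and smiles columns")
        return df[[c for c in df.columns]]
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                rows.append({"drug_id": f"D{i:04d}", "smiles": parts[0]})
            else:
                rows.append({"drug_id": parts[0], "smiles": parts[1]})
    if not rows:
        raise ValueError(f"{path}: no SMILES found")
    return pd.DataFrame(rows)


def read_contact_map(path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    m = np.loadtxt(path, delimiter=delim)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: contact map must be square, got {m.shape}")
    return m


def load_contacts(contacts_dir, target_ids) -> dict[str, np.ndarray]:
    """Load per-target contact maps keyed by filename stem = target_id."""
    contacts_dir = Path(contacts_dir)
    out = {}
    for tid in target_ids:
        hits = sorted(contacts_dir.glob(f"{tid}.*"))
        if not hits:
            raise FileNotFoundError(
                f"no contact map for target {tid!r} in {contacts_dir}")
        out[tid] = read_contact_map(hits[0])
    return out


_CONFIG_KEYS = {
    "channels": int, "n_blocks": int, "n_layers_per_block": int,
    "gnn_type": str, "enhancement_scale": float, "dropout": float,
    "contact_threshold": float, "max_len": int, "use_target_graph": bool,
    "batch_size": int, "learning_rate": float, "max_epochs": int,
    "patience": int, "seed": int, "undersample": bool,
}


def read_config(path) -> dict:
    """Plain-text ``key = value`` configuration; unknown keys are rejected."""
    cfg: dict = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}: line {ln}: unknown key {key!r}")
            typ = _CONFIG_KEYS[key]
            cfg[key] = val.lower() in ("1", "true", "yes") if typ is bool else typ(val)
    return cfg


def load_dataset(pairs_path, smiles_path, fasta_path,
                 contacts_dir=None, require_contacts=False) -> DTIDataset:
    """Assemble a :class:`DTIDataset` from the on-disk formats."""
    pairs = read_pairs(pairs_path)
    drug_df = read_drug_table(smiles_path)
    seqs = read_fasta(fasta_path)
    contacts = {}
    if contacts_dir is not None:
        contacts = load_contacts(contacts_dir, sorted(set(pairs["target_id"])))
    elif require_contacts:
        raise ValueError("the target graph channel is enabled but no contacts "
                         "directory was given")
    graphs = {r.drug_id: smiles_to_graph(r.smiles, r.drug_id)
              for r in drug_df.itertuples()}
    targets = {}
    for tid in sorted(set(pairs["target_id"])):
        if tid not in seqs:
            raise ValueError(f"target {tid!r} missing from FASTA")
        targets[tid] = ProteinRecord(target_id=tid, sequence=seqs[tid],
                                     contact_map=contacts.get(tid))
    return DTIDataset(pairs, graphs, targets)
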