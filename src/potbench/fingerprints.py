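"""Circular topological fingerprints and the Tanimoto similarity/kernel.

Compounds are represented by extended-connectivity (Morgan) atom environments
of bond diameter 4 (radius 2), hashed to integer feature identifiers and
folded to a fixed-length binary vector by modulo mapping.  The Tanimoto
coefficient on the folded bit vectors serves both as a similarity measure and
as a positive semi-definite kernel for support vector regression.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FeatureSet",
    "SmilesParseError",
    "compute_ecfp4",
    "fold_modulo",
    "fingerprint_smiles",
    "fingerprint_matrix",
    "tanimoto",
    "tanimoto_kernel",
    "fingerprint_table",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class FeatureSet:
    """Multiset of hashed atom-environment identifiers for one molecule."""

    features: Counter = field(default_factory=Counter)

    def distinct(self) -> set[int]:
        return set(self.features)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def compute_ecfp4(smiles: str, radius: int = 2) -> FeatureSet:
    """Hashed circular atom environments of radius 0..``radius`` bonds.

    Radius 2 corresponds to bond diameter 4 (ECFP4-style).  The feature
    identifiers come from the canonical molecule, so two SMILES spellings of
    the same structure give identical feature sets.
    """
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    counts = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    return FeatureSet(Counter({int(k): int(v) for k, v in counts.items()}))


def fold_modulo(feature_set: FeatureSet, n_bits: int = 1024) -> np.ndarray:
    """Fold a variably-sized feature set to ``n_bits`` presence bits.

    Bit ``f mod n_bits`` is set for every feature identifier ``f``; counts are
    discarded (binary fingerprint).  Order of feature iteration is irrelevant.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    bits = np.zeros(n_bits, dtype=np.uint8)
    for f in feature_set.features:
        bits[f % n_bits] = 1
    return bits


def fingerprint_smiles(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Convenience: ECFP4 feature extraction + modulo folding."""
    return fold_modulo(compute_ecfp4(smiles, radius=radius), n_bits=n_bits)


def fingerprint_matrix(
    smiles_list: list[str], n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Stack folded fingerprints into an (n_molecules, n_bits) uint8 array."""
    if not smiles_list:
        return np.zeros((0, n_bits), dtype=np.uint8)
    return np.stack([fingerprint_smiles(s, n_bits, radius) for s in smiles_list])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length bit vectors.

    Two all-zero vectors are identical objects and return 1.0 by convention
    (degenerate for real molecules, which always set at least one bit).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def tanimoto_kernel(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Tanimoto kernel matrix between the rows of A and B.

    Vectorized via K = <a,b> / (|a| + |b| - <a,b>) on binary vectors; empty
    pairs (union zero) map to 1.0, matching :func:`tanimoto`.
    """
    A = np.asarray(A, dtype=np.float64)
    B = A if B is None else np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return K


def fingerprint_table(
    records: list[tuple[str, str]], n_bits: int = 1024, radius: int = 2
) -> pd.DataFrame:
    """Fingerprints for (compound_id, smiles) pairs as a delimited-friendly table.

    The ``bits`` column holds the fingerprint as a 0/1 character string.
    """
    rows = []
    for cid, smi in records:
        fp = fingerprint_smiles(smi, n_bits, radius)
        rows.append((cid, "".join(map(str, fp.tolist()))))
    return pd.DataFrame(rows, columns=["compound_id", "bits"])
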