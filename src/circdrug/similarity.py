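"""Similarity networks for circRNAs and drugs.

Four square similarity matrices feed the model:

* **CSS** — circRNA sequence similarity, the Levenshtein indel ratio
  between host-gene sequences;
* **CGS** — circRNA Gaussian interaction-profile (GIP) kernel similarity
  computed from rows of the association matrix;
* **DSS** — drug structure similarity, the Tanimoto coefficient between
  topological path fingerprints;
* **DGS** — drug GIP kernel similarity computed from columns of the
  association matrix.

CSS/CGS and DSS/DGS are fused element-wise into comprehensive matrices
CS and DS: the arithmetic mean where the primary (sequence or structure)
similarity is non-zero, otherwise the GIP value alone.  The fused
matrices are then binarized at thresholds ``cth``/``dth`` (strictly
greater than) and given self-loops, producing the adjacency graphs the
auto-encoder operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SequenceRecord
from .errors import StructureParseError, ValidationError

__all__ = [
    "SimilarityMatrix",
    "BinaryGraph",
    "levenshtein_ratio",
    "sequence_similarity",
    "smiles_to_fingerprint",
    "tanimoto",
    "drug_structure_similarity",
    "gip_kernel",
    "fuse",
    "binarize",
    "read_similarity",
    "write_similarity",
]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {vals.shape} != ({n},{n})")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValidationError("similarity matrix is not symmetric")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValidationError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        self.values = np.clip(vals, 0.0, 1.0)


@dataclass
class BinaryGraph:
    """Thresholded adjacency with self-loops; input graph for the GATE."""

    ids: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        adj = np.asarray(self.adjacency)
        n = len(self.ids)
        if adj.shape != (n, n):
            raise ValidationError(f"adjacency shape {adj.shape} != ({n},{n})")
        if not np.isin(adj, (0, 1)).all():
            raise ValidationError("adjacency must be binary")
        if not (adj == adj.T).all():
            raise ValidationError("adjacency must be symmetric")
        if not (np.diag(adj) == 1).all():
            raise ValidationError("adjacency must have self-loops (unit diagonal)")
        self.adjacency = adj.astype(np.int8)

    def neighbor_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.adjacency]

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge arrays (src aggregates over dst), self-loops included."""
        src, dst = np.nonzero(self.adjacency)
        return src, dst


def _lcs_length(a: str, b: str) -> int:
    # Bit-parallel LCS length; O(len(a)*len(b)/wordsize) with bigint words.
    m = len(a)
    if m == 0 or len(b) == 0:
        return 0
    match: dict[str, int] = {}
    for i, ch in enumerate(a):
        match[ch] = match.get(ch, 0) | (1 << i)
    full = (1 << m) - 1
    v = full
    for ch in b:
        u = v & match.get(ch, 0)
        v = ((v + u) | (v - u)) & full
    return m - bin(v).count("1")


def levenshtein_ratio(a: str, b: str) -> float:
    """Indel similarity ratio of two strings.

    Returns ``(|a|+|b| - D2) / (|a|+|b|)`` where ``D2`` is the edit
    distance with insertion/deletion cost 1 and substitution cost 2 —
    the ``ratio`` of the classic Levenshtein package.  Equivalently
    ``2*LCS(a,b) / (|a|+|b|)``.  Defined as 1.0 for two empty strings.
    """
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return 2.0 * _lcs_length(a, b) / total


def sequence_similarity(seqs: list[SequenceRecord]) -> SimilarityMatrix:
    """Pairwise Levenshtein-ratio matrix over host-gene sequences (CSS)."""
    if len(seqs) == 0:
        raise ValidationError("need at least one sequence")
    n = len(seqs)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = levenshtein_ratio(seqs[i].sequence, seqs[j].sequence)
            values[i, j] = values[j, i] = r
    return SimilarityMatrix(tuple(s.id for s in seqs), values)


def smiles_to_fingerprint(smiles: str, n_bits: int = 2048, drug_id: str | None = None) -> np.ndarray:
    """Hashed topological path fingerprint of a SMILES string.

    Uses the Daylight-style path enumeration fingerprint with ``n_bits``
    bits (default 2048).  Canonicalisation in the parser makes the result
    independent of how the SMILES is written.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for drug {drug_id!r}" if drug_id else ""
        raise StructureParseError(f"could not parse structure {smiles!r}{label}")
    bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.int8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def tanimoto(f1: np.ndarray, f2: np.ndarray) -> float:
    """Tanimoto coefficient |on(f1) ∩ on(f2)| / |on(f1) ∪ on(f2)|.

    Defined as 0.0 when both fingerprints are all-zero.
    """
    f1 = np.asarray(f1)
    f2 = np.asarray(f2)
    if f1.shape != f2.shape:
        raise ValidationError(f"fingerprint lengths differ: {f1.shape} vs {f2.shape}")
    inter = int(np.logical_and(f1, f2).sum())
    union = int(np.logical_or(f1, f2).sum())
    return inter / union if union else 0.0


def drug_structure_similarity(fingerprints: np.ndarray, ids=None) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over fingerprints (DSS); diagonal forced to 1."""
    fps = np.asarray(fingerprints)
    if fps.ndim != 2 or fps.shape[0] == 0:
        raise ValidationError("need a non-empty 2-D fingerprint matrix")
    if not np.isin(fps, (0, 1)).all():
        raise ValidationError("fingerprints must be binary")
    f = fps.astype(np.float64)
    inter = f @ f.T
    on = f.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    if ids is None:
        ids = tuple(str(i) for i in range(fps.shape[0]))
    return SimilarityMatrix(tuple(ids), sim)


def gip_kernel(profiles: np.ndarray, ids=None) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    ``K(i,j) = exp(-gamma * ||IP(i) - IP(j)||^2)`` with bandwidth
    ``gamma = 1 / mean_i ||IP(i)||^2`` (multiplier 1).  When every profile
    is all-zero the kernel is undefined and the identity matrix is
    returned by convention.
    """
    p = np.asarray(profiles)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValidationError("need a non-empty 2-D profile matrix")
    if not np.isin(p, (0, 1)).all():
        raise ValidationError("interaction profiles must be binary")
    if ids is None:
        ids = tuple(str(i) for i in range(p.shape[0]))
    norms2 = p.sum(axis=1).astype(np.float64)  # binary: squared norm = row sum
    mean_norm2 = norms2.mean()
    if mean_norm2 == 0.0:
        return SimilarityMatrix(tuple(ids), np.eye(p.shape[0]))
    gamma = 1.0 / mean_norm2
    f = p.astype(np.float64)
    sqdist = norms2[:, None] + norms2[None, :] - 2.0 * (f @ f.T)
    np.maximum(sqdist, 0.0, out=sqdist)
    k = np.exp(-gamma * sqdist)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(tuple(ids), k)


def fuse(s_primary: SimilarityMatrix, s_gip: SimilarityMatrix) -> SimilarityMatrix:
    """Comprehensive similarity: mean where the primary is non-zero, else GIP."""
    if s_primary.ids != s_gip.ids:
        raise ValidationError("fuse: id orders differ between the two matrices")
    a, b = s_primary.values, s_gip.values
    fused = np.where(a != 0, (a + b) / 2.0, b)
    return SimilarityMatrix(s_primary.ids, fused)


def binarize(s: SimilarityMatrix, threshold: float) -> BinaryGraph:
    """Adjacency ``a_ij = 1`` iff ``s_ij > threshold`` (strict); self-loops added."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    adj = (s.values > threshold).astype(np.int8)
    np.fill_diagonal(adj, 1)
    return BinaryGraph(s.ids, adj)


def read_similarity(path) -> SimilarityMatrix:
    import pandas as pd

    from .data_io import _delimiter

    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    return SimilarityMatrix(tuple(str(i) for i in df.index), df.to_numpy())


def write_similarity(sim: SimilarityMatrix, path) -> None:
    import pandas as pd

    from .data_io import _delimiter

    pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids)).to_csv(
        path, sep=_delimiter(path)
    )
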