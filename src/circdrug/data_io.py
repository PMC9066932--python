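"""Reading, writing and assembly of the three external inputs.

The pipeline consumes (a) circRNA host-gene sequences in FASTA, (b) drug
structures as an id/SMILES table or a precomputed binary fingerprint
matrix, and (c) a binary circRNA-drug association matrix, either as a
labelled CSV matrix or as an edge list of positive pairs.  This module
parses each format, validates the documented invariants, and aligns the
three components into a single :class:`Dataset` keyed by the association
matrix's id order.

Delimiters are inferred from the file extension: ``.tsv``/``.tab`` means
tab, anything else comma.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ValidationError

_VALID_BASES = frozenset("ACGTN")


def _delimiter(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


@dataclass(frozen=True)
class SequenceRecord:
    """A host-gene nucleotide sequence for one circRNA."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record has empty id")
        if len(self.sequence) == 0:
            raise ValidationError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"sequence for {self.id!r} contains invalid characters "
                f"{sorted(bad)}; allowed alphabet is A,C,G,T,N"
            )


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by id, optionally carrying a SMILES string."""

    id: str
    smiles: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("drug record has empty id")


@dataclass
class AssociationMatrix:
    """Binary circRNA x drug association matrix A (rows = circRNAs)."""

    circ_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.circ_ids = tuple(self.circ_ids)
        self.drug_ids = tuple(self.drug_ids)
        vals = np.asarray(self.values)
        if vals.shape != (len(self.circ_ids), len(self.drug_ids)):
            raise ValidationError(
                f"association matrix shape {vals.shape} does not match "
                f"{len(self.circ_ids)} circRNAs x {len(self.drug_ids)} drugs"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("association matrix must be binary (0/1)")
        for name, ids in (("circ", self.circ_ids), ("drug", self.drug_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids in association matrix")
        self.values = vals.astype(np.int8)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.circ_ids, self.drug_ids, self.values.copy())


@dataclass
class Dataset:
    """Aligned sequences, drug structures/fingerprints and associations.

    ``drugs`` (SMILES records) and ``fingerprints`` are alternatives; at
    least one must be present.  After :func:`assemble_dataset` all
    components follow the association matrix's id order.
    """

    sequences: list[SequenceRecord]
    associations: AssociationMatrix
    drugs: list[DrugRecord] | None = None
    fingerprints: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def circ_ids(self) -> tuple[str, ...]:
        return self.associations.circ_ids

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return self.associations.drug_ids


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; id = header token before whitespace."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else ""
            if rid in seen:
                raise ValidationError(f"duplicate sequence id {rid!r} in {path}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq.upper().replace(" ", "")))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_associations(
    path,
    format: str = "matrix",
    circ_ids=None,
    drug_ids=None,
) -> AssociationMatrix:
    """Read an association matrix.

    ``matrix`` expects a labelled CSV/TSV with circRNA ids in the first
    column and drug ids in the header.  ``edgelist`` expects two columns
    (circ_id, drug_id) of positive pairs; the universe is taken from
    ``circ_ids``/``drug_ids`` when given, otherwise inferred as the sorted
    union of the listed ids.
    """
    sep = _delimiter(path)
    if format == "matrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return AssociationMatrix(
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
            df.to_numpy(),
        )
    if format == "edgelist":
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValidationError("edge list needs two columns: circ_id,drug_id")
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if circ_ids is None:
            circ_ids = sorted({c for c, _ in pairs})
        if drug_ids is None:
            drug_ids = sorted({d for _, d in pairs})
        c_index = {c: i for i, c in enumerate(circ_ids)}
        d_index = {d: j for j, d in enumerate(drug_ids)}
        values = np.zeros((len(circ_ids), len(drug_ids)), dtype=np.int8)
        for c, d in pairs:
            if c not in c_index or d not in d_index:
                raise ValidationError(
                    f"edge ({c!r}, {d!r}) references an id outside the universe"
                )
            values[c_index[c], d_index[d]] = 1
        return AssociationMatrix(tuple(circ_ids), tuple(drug_ids), values)
    raise ValidationError(f"unknown association format {format!r}")


def write_associations(assoc: AssociationMatrix, path) -> None:
    pd.DataFrame(
        assoc.values, index=list(assoc.circ_ids), columns=list(assoc.drug_ids)
    ).to_csv(path, sep=_delimiter(path))


def read_smiles_table(path) -> list[DrugRecord]:
    """Read an id,smiles CSV/TSV (header row required)."""
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "smiles" not in cols:
        raise ValidationError("SMILES table needs columns 'id' and 'smiles'")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row[cols["id"]])
        if rid in seen:
            raise ValidationError(f"duplicate drug id {rid!r} in {path}")
        seen.add(rid)
        records.append(DrugRecord(rid, str(row[cols["smiles"]])))
    return records


def read_fingerprints(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a binary fingerprint matrix CSV (first column = drug id)."""
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    mat = df.to_numpy()
    if not np.isin(mat, (0, 1)).all():
        raise ValidationError("fingerprint matrix must be binary (0/1)")
    ids = tuple(str(i) for i in df.index)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate drug ids in fingerprint matrix")
    return ids, mat.astype(np.int8)


def write_fingerprints(ids, matrix, path) -> None:
    pd.DataFrame(
        np.asarray(matrix, dtype=np.int8),
        index=list(ids),
        columns=[str(b) for b in range(np.asarray(matrix).shape[1])],
    ).to_csv(path, sep=_delimiter(path))


def assemble_dataset(sequences, drugs, associations: AssociationMatrix) -> Dataset:
    """Align components to the association matrix's id order.

    ``drugs`` is either a list of :class:`DrugRecord` or an
    ``(ids, fingerprint_matrix)`` pair.  Ids present in the association
    matrix but missing a sequence or structure raise
    :class:`ValidationError` naming them.
    """
    seq_by_id = {}
    for rec in sequences:
        if rec.id in seq_by_id:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seq_by_id[rec.id] = rec
    missing = [c for c in associations.circ_ids if c not in seq_by_id]
    if missing:
        raise ValidationError(f"missing sequences for circRNA ids: {missing}")
    ordered_seqs = [seq_by_id[c] for c in associations.circ_ids]

    if isinstance(drugs, tuple) and len(drugs) == 2:
        fp_ids, fp_mat = drugs
        index = {d: i for i, d in enumerate(fp_ids)}
        missing = [d for d in associations.drug_ids if d not in index]
        if missing:
            raise ValidationError(f"missing fingerprints for drug ids: {missing}")
        order = [index[d] for d in associations.drug_ids]
        return Dataset(
            sequences=ordered_seqs,
            associations=associations,
            fingerprints=np.asarray(fp_mat)[order],
        )

    drug_by_id = {}
    for rec in drugs:
        if rec.id in drug_by_id:
            raise ValidationError(f"duplicate drug id {rec.id!r}")
        drug_by_id[rec.id] = rec
    missing = [d for d in associations.drug_ids if d not in drug_by_id]
    if missing:
        raise ValidationError(f"missing structures for drug ids: {missing}")
    return Dataset(
        sequences=ordered_seqs,
        associations=associations,
        drugs=[drug_by_id[d] for d in associations.drug_ids],
    )
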