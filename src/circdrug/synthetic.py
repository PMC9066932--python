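"""Seeded synthetic datasets with planted block structure.

Real circRNA-drug sensitivity data couples three signals: circRNAs with
similar host-gene sequences tend to share drug associations, and drugs
with similar structures tend to share circRNA associations.  The
generator plants exactly that coupling so the end-to-end pipeline has a
recoverable signal:

* circRNAs are split into ``n_blocks`` groups; each group descends from
  one random ancestor sequence with i.i.d. per-base substitutions at
  ``mut_rate``;
* drugs are split into ``n_blocks`` groups; each group perturbs one
  prototype fingerprint (bit density ``fp_density``) by flipping each
  bit with probability ``fp_flip``;
* circRNA blocks are matched one-to-one to drug blocks by a random
  bijection; an association is Bernoulli(``p_in``) for matched block
  pairs and Bernoulli(``p_out``) otherwise.

One global seed drives three independent sub-streams (sequences,
fingerprints, associations), so e.g. changing ``n_drug`` never perturbs
the sequences.  Synthetic drugs are emitted as fingerprint matrices
rather than SMILES; a few real SMILES strings are kept as parser
fixtures in :data:`EXAMPLE_SMILES`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .data_io import (
    AssociationMatrix,
    Dataset,
    SequenceRecord,
    write_associations,
    write_fasta,
    write_fingerprints,
)
from .errors import ValidationError

__all__ = ["SyntheticConfig", "generate", "write_synthetic", "permute_associations",
           "EXAMPLE_SMILES"]

#: Real, chemically valid SMILES usable as structure-parser fixtures.
EXAMPLE_SMILES = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "glucose": "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the benchmark conditions."""

    n_circ: int = 120
    n_drug: int = 80
    n_blocks: int = 4
    seq_len: int = 400
    mut_rate: float = 0.05
    fp_bits: int = 512
    fp_density: float = 0.1
    fp_flip: float = 0.02
    p_in: float = 0.6
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("mut_rate", "fp_density", "fp_flip", "p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("n_circ", "n_drug", "n_blocks", "seq_len", "fp_bits"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_blocks > min(self.n_circ, self.n_drug):
            raise ValidationError("n_blocks exceeds min(n_circ, n_drug)")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for pos in hits:  # substitute with one of the three *other* bases
        choices = _BASES[_BASES != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return out


def generate(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a dataset plus ground-truth block labels.

    Returns ``(dataset, truth)`` where ``truth`` has keys
    ``circ_blocks``, ``drug_blocks`` (block index per entity) and
    ``block_match`` (circ block -> matched drug block).
    """
    rng_seq = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rng_fp = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_assoc = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    circ_blocks = np.arange(config.n_circ) % config.n_blocks
    drug_blocks = np.arange(config.n_drug) % config.n_blocks

    ancestors = [
        _BASES[rng_seq.integers(4, size=config.seq_len)]
        for _ in range(config.n_blocks)
    ]
    sequences = [
        SequenceRecord(
            f"circ_{i:04d}",
            "".join(_mutate(ancestors[circ_blocks[i]], config.mut_rate, rng_seq)),
        )
        for i in range(config.n_circ)
    ]

    prototypes = (rng_fp.random((config.n_blocks, config.fp_bits))
                  < config.fp_density).astype(np.int8)
    flips = rng_fp.random((config.n_drug, config.fp_bits)) < config.fp_flip
    fingerprints = np.where(flips, 1 - prototypes[drug_blocks], prototypes[drug_blocks])

    block_match = rng_assoc.permutation(config.n_blocks)
    matched = block_match[circ_blocks][:, None] == drug_blocks[None, :]
    probs = np.where(matched, config.p_in, config.p_out)
    values = (rng_assoc.random((config.n_circ, config.n_drug)) < probs).astype(np.int8)

    assoc = AssociationMatrix(
        tuple(s.id for s in sequences),
        tuple(f"drug_{j:03d}" for j in range(config.n_drug)),
        values,
    )
    dataset = Dataset(sequences=sequences, associations=assoc,
                      fingerprints=fingerprints.astype(np.int8))
    truth = {
        "circ_blocks": circ_blocks.tolist(),
        "drug_blocks": drug_blocks.tolist(),
        "block_match": block_match.tolist(),
    }
    return dataset, truth


def permute_associations(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Randomly permute the cells of A (null control: same density, no signal)."""
    rng = np.random.default_rng(seed)
    flat = assoc.values.ravel().copy()
    rng.shuffle(flat)
    return AssociationMatrix(assoc.circ_ids, assoc.drug_ids,
                             flat.reshape(assoc.values.shape))


def write_synthetic(dataset: Dataset, truth: dict, config: SyntheticConfig,
                    outdir) -> dict:
    """Write FASTA + fingerprint CSV + association CSV + JSON sidecar."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sequences": os.path.join(outdir, "sequences.fasta"),
        "fingerprints": os.path.join(outdir, "fingerprints.csv"),
        "associations": os.path.join(outdir, "associations.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(dataset.sequences, paths["sequences"])
    write_fingerprints(dataset.drug_ids, dataset.fingerprints, paths["fingerprints"])
    write_associations(dataset.associations, paths["associations"])
    with open(paths["truth"], "w") as fh:
        json.dump({"config": asdict(config), **truth}, fh, indent=1)
    return paths
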