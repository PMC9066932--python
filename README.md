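# circdrug

Predicting **circRNA–drug sensitivity associations** with a graph
attention auto-encoder.

Circular RNAs (circRNAs) modulate how cancer cell lines respond to
drugs, and screening every circRNA–drug pair experimentally is
infeasible. Given three inputs —

1. host-gene nucleotide sequences of circRNAs (FASTA),
2. drug structures (an `id,smiles` table, or a precomputed binary
   fingerprint matrix), and
3. a binary association matrix `A` (rows = circRNAs, columns = drugs),

this package ranks unobserved pairs by how likely the circRNA's
expression affects sensitivity to the drug. It is aimed at
computational biologists triaging candidate circRNA–drug links before
wet-lab validation.

## Method

**Similarity networks.** Four matrices are built:

- `CSS` — circRNA sequence similarity, the Levenshtein indel ratio
  `(|a|+|b| − D₂)/(|a|+|b|)` between host-gene sequences (`D₂` = edit
  distance with substitution cost 2);
- `DSS` — drug structure similarity, Tanimoto coefficients between
  2048-bit topological path fingerprints (RDKit);
- `CGS`/`DGS` — Gaussian interaction-profile (GIP) kernels
  `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` over rows/columns of `A`, with
  bandwidth `γ = 1 / mean‖IP‖²`.

Each side is fused element-wise — `(primary + GIP)/2` where the primary
similarity is non-zero, else the GIP value — and binarized at cutoffs
`cth = 0.7` (circRNA) and `dth = 0.6` (drug), with self-loops added.

**Graph attention auto-encoder (GATE).** On each binary graph, encoder
layers (128 → 64 units) aggregate neighbour representations with
softmax-normalised attention

    c_ij = sigmoid(v_s' W h_i + v_r' W h_j),
    α_ij = softmax_{j∈N(i)}(c_ij),
    h_i  = Σ_{j∈N(i)} α_ij · W h_j,

and a mirrored decoder reconstructs the node attributes (rows/columns
of `A`). Training minimises the attribute reconstruction error
`Σᵢ‖xᵢ − x̂ᵢ‖₂` plus `λ` times a structure term
`−Σᵢ Σ_{j∈N(i)} log σ(hᵢ'hⱼ)` with full-batch Adam (learning rate 1e-3,
`λ = 1`).

**Classifier.** The 64-d circRNA and drug embeddings of a pair are
concatenated (128-d) and scored by a 128/64/32-unit ReLU network with a
sigmoid output, trained with Adam (1e-4), Glorot-uniform weights and
zero biases.

**Evaluation.** Known positives plus an equal number of uniformly
sampled negative cells are split into stratified k folds; per fold, the
test positives are masked out of `A` before the GIP kernels and node
features are computed (leakage guard, default on), and AUC, AUPR, F1,
accuracy, recall, specificity and precision are reported per fold and
as means.

A seeded synthetic generator plants coupled block structure (sequence
families ↔ fingerprint families ↔ association blocks) so the whole
pipeline is testable without downloads.

## Worked example

```python
from circdrug import synthetic, pipeline

dataset, truth = synthetic.generate(synthetic.SyntheticConfig())  # 120×80, 4 blocks
report = pipeline.run_cv(dataset, cv_cfg=pipeline.CVConfig(k=5, seed=0))
print({k: round(v, 4) for k, v in report.mean.items()})
```

prints (about a minute on one CPU):

```
{'auc': 0.8793, 'aupr': 0.8616, 'f1': 0.7901, 'accuracy': 0.8044,
 'recall': 0.7383, 'specificity': 0.8704, 'precision': 0.8509}
```

Mean test AUC 0.88 means: across held-out folds, a random true
association outscores a random non-association 88% of the time — the
planted sequence/structure/association coupling is recovered. On the
same data with the association labels randomly permuted the pipeline
scores at chance (AUC ≈ 0.49), confirming the signal comes from the
data and not from leakage.

The same flow is available from the shell:

```bash
circdrug synth --outdir data/ --seed 0
circdrug cv --fasta data/sequences.fasta --fingerprints data/fingerprints.csv \
            --associations data/associations.csv --k 5 --seed 0 --out report.json
circdrug rank --fasta data/sequences.fasta --fingerprints data/fingerprints.csv \
              --associations data/associations.csv --drug-id drug_000 --top-n 20
```

Other subcommands: `similarity` (write CSS/CGS/DSS/DGS/CS/DS and the
binarized graphs), `embed` (write node embeddings), `gridsearch`
(scan `cth`/`dth`), `denovo` (rank circRNAs for a structure-only drug
with no known associations).

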