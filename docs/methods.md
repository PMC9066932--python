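# Methods

## Problem and model

The package treats circRNA–drug sensitivity prediction as bipartite
link prediction. Each side of the bipartite graph gets its own
homogeneous similarity network; a graph attention auto-encoder (GATE)
learns a low-dimensional embedding per node on each side; a small
fully connected network scores (circRNA, drug) pairs from the
concatenated embeddings.

### Similarity construction

- **Sequence similarity (CSS).** For host-gene sequences `a`, `b` the
  score is the indel ratio `(|a|+|b| − D₂(a,b)) / (|a|+|b|)`, where
  `D₂` is the edit distance with insertion/deletion cost 1 and
  substitution cost 2. Since `D₂ = |a|+|b| − 2·LCS(a,b)`, it is
  computed as `2·LCS/(|a|+|b|)` with a bit-parallel LCS (bigint word
  operations, O(nm/w)); a quadratic dynamic-programming oracle checks
  it in the test suite. Two empty strings score 1.0 by convention.
- **Structure similarity (DSS).** Daylight-style hashed topological
  path fingerprints (2048 bits by default) and Tanimoto coefficients.
  The diagonal is forced to 1 and two all-zero fingerprints score 0
  off-diagonal (no shared substructure evidence).
- **GIP kernels (CGS, DGS).** `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` over
  binary interaction profiles (rows of `A` for circRNAs, columns for
  drugs), with `γ = 1 / ((1/n)Σᵢ‖IP(i)‖²)` (bandwidth multiplier 1).
  If every profile is all-zero the kernel is undefined and the
  identity matrix is returned.
- **Fusion and binarization.** Comprehensive similarity is the
  element-wise mean of primary and GIP similarity where the primary is
  non-zero, otherwise the GIP value alone. Binarization uses a strict
  `>` (ties at the threshold drop to 0, matching the rule "set to 1 if
  greater than the threshold") and then sets the diagonal to 1, since
  each node's neighbourhood includes itself. Defaults `cth = 0.7`,
  `dth = 0.6`.

### Auto-encoder

Two encoder layers (128, 64 units) and two mirrored decoder layers
with independent parameters (no weight tying). The printed decoder
weight shape in the source formulation cannot map d(k) → d(k−1); it is
implemented as d(k−1)×d(k), consistent with the attention-vector
dimensions. The per-layer activation is configurable and defaults to
the identity, which keeps the hand-evaluated scalar oracle exact; the
attention path already contains a sigmoid and softmax, so the model is
non-linear regardless.

The loss is `Σᵢ‖xᵢ − x̂ᵢ‖₂ − λ Σᵢ Σ_{j∈N(i)} log σ(hᵢ'hⱼ)` with the
*unsquared* Euclidean norm in the attribute term, `λ = 1`, and each
undirected edge counted once per direction (self-loops included), as
the per-node neighbour sums dictate. The gradient of the norm at an
exactly-zero residual row is guarded with an ε = 1e-12 denominator.
Optimisation is full-batch Adam at learning rate 1e-3 for 200 epochs
(optimizer and epoch count are this package's choices; the graphs are
small enough that full batch is exact and fast). Non-finite loss
raises an error naming the epoch.

**Node features.** circRNA features are the rows of the
(training-fold-masked) association matrix; drug features its columns.
This is the standard choice in comparable graph methods for sparse
bipartite data and keeps the feature space aligned with the GIP
kernels.

### Classifier

Hidden widths 128/64/32, ReLU; one sigmoid output; binary
cross-entropy (computed in logit space for stability); Adam at 1e-4;
Glorot-uniform weights, zero biases; 100 epochs of mini-batches of 32
with a seeded shuffle per epoch. Hidden activation, loss, epochs,
batch size and the 0.5 decision threshold for confusion-matrix metrics
are this package's choices, consistent with the stated
optimizer/initializer. Pair features are concatenations, circRNA
first.

Both networks run on a small reverse-mode autodiff core
(`circdrug/_autodiff.py`) written for this package: float64
throughout, no threading-dependent reductions, so identical seeds give
bitwise-identical models on a given platform.

### Cross-validation protocol

Negatives are sampled uniformly without replacement from the zero
cells of `A`, once globally, at a 1:1 ratio (the near-balanced
published accuracy/specificity trade-off implies a balanced design).
Positives and negatives are folded together with stratified k-fold
(shuffled, seeded). Per fold, with the leakage guard on (default), the
fold's test positives are zeroed in the working copy of `A` before the
GIP kernels and the node features are computed, so no test association
can inform the representation; a flag restores the permissive variant
for comparison with published full-matrix protocols. AUC is the
trapezoidal area under the ROC curve; AUPR is average precision (the
step-wise interpolation standard for precision–recall, which avoids
the optimistic bias of trapezoidal PR integration); confusion-matrix
metrics use threshold 0.5. Fold means are unweighted.

Rankings (per-drug case study and de-novo mode) break score ties by
circRNA id so results are reproducible. A de-novo drug — structure
known, no associations — joins the drug graph through structure
similarity alone (its GIP row does not exist, so its fused similarity
row falls back to DSS rather than being halved against a zero GIP,
which would disconnect it at `dth = 0.6`), and its auto-encoder input
features are drawn from a seeded standard uniform, mirroring the
random-assignment strategy for cold-start drugs.

## Synthetic benchmark

The generator plants the coupling the method exploits: circRNAs in the
same block descend from one ancestor sequence (i.i.d. substitutions at
`mut_rate`, always to a different base); drugs in the same block
perturb one prototype fingerprint (per-bit flips at `fp_flip`);
circRNA blocks are matched to drug blocks by a random bijection and
associations are Bernoulli(`p_in`) within matched block pairs,
Bernoulli(`p_out`) otherwise. Defaults: 120 circRNAs, 80 drugs, 4
blocks, 400-nt sequences, `mut_rate` 0.05, 512-bit fingerprints,
density 0.1, `fp_flip` 0.02, `p_in` 0.6, `p_out` 0.02, giving an
association density of ≈0.165 — sparse, but a planted signal strong
enough that recovery failures indicate pipeline defects rather than
noise. One global seed drives three independent sub-streams
(sequences, fingerprints, associations), so changing the drug count
leaves the sequences untouched.

What it does **not** emulate: realistic host-gene length variation and
homology structure, realistic fingerprint bit correlations, the degree
distribution of curated association data, or dose–response-derived
label noise. Passing the recovery benchmark therefore shows the
pipeline can extract a sequence/structure/association coupling end to
end; it does not certify performance on curated experimental data.

Expected generated density is `p_in/n_blocks + p_out(1 − 1/n_blocks)`
under balanced blocks; the test suite checks the empirical density
against this within binomial sampling error, and that within-block
similarity exceeds between-block similarity on both sides.

## Benchmark sizes and numerical choices

The recovery benchmark runs 5-fold cross-validation on the default
120×80 dataset (~2700 labelled pairs); the permuted-label null control
(cells of `A` shuffled, destroying the block coupling while preserving
density) runs the same protocol over three seeds and is expected to
sit at chance. The determinism check duplicates an end-to-end run at a
reduced 40×30 size — the bitwise-equality property it asserts does not
depend on problem size. Attention softmaxes act on sigmoid outputs
(range (0,1)), so no max-shift is needed; log-sigmoid and softplus use
the standard overflow-safe forms. Seeds for per-fold models are
derived from the run seed via `SeedSequence` children, kept below
2³¹.

## Known limitations

- Sequence similarity is all-pairs O(n²·nm/w); for thousands of
  circRNAs a banded or sketching approach would be needed.
- The GATE is full-batch; graphs beyond ~10⁴ nodes would need
  neighbourhood sampling.
- The de-novo mode inherits the cold-start weakness of
  random-assignment features: rankings for structure-only drugs are
  noticeably noisier than for drugs with known associations.
- With the leakage guard off, GIP kernels see test-fold positives;
  that variant exists only to mirror published full-matrix protocols
  and overstates generalisation.
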