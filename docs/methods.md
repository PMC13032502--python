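# Methods

## Problem and model

`lncgraph` treats lncRNA–disease association prediction as transductive node
classification. Known associations form a binary matrix `A` (rows lncRNAs,
columns diseases); the method scores unobserved cells by embedding both
entity sides, lifting every candidate pair to a *pair node*, and classifying
pair nodes with a graph neural network that sees two complementary graph
structures over the same nodes.

### Similarity layer

* **GIP kernel** on association profiles:
  `GIP(i,j) = exp(−‖A_i − A_j‖²/σ²)`. The bandwidth is profile-normalized by
  default, `σ² = mean_i ‖A_i‖²` — the standard convention for this kernel —
  because it is scale-free across datasets of different density; a fixed σ
  is available in the config. The kernel is computed on the lncRNA side
  only; a disease-side GIP exists behind a config flag (off by default).
  All-empty profiles make the normalized bandwidth undefined and are
  rejected.
* **Jaccard** over shared omic partner sets, one similarity view per link
  table (lncRNA–mRNA/RBP/protein; disease–metabolite/circRNA). Two empty
  partner sets score 0, including on the diagonal: an entity with no
  recorded partners carries no evidence of similarity, not perfect
  similarity.
* **Disease semantic similarity** is a pluggable input: a precomputed matrix
  can be supplied directly (dedicated semantic measures are typically
  dataset products). The built-in stand-in is ancestor-set Jaccard on the
  IS_A ontology, with each term counted among its own ancestors so the
  diagonal is 1 and deeper shared ancestry scores higher. Min–max
  normalization of the off-diagonal is applied to the semantic matrix only;
  the kernel and Jaccard views are already in [0, 1] by construction. A
  constant off-diagonal maps to zeros rather than dividing by zero.

### Diffusion and compression

Each similarity matrix is column-normalized into a transition matrix
(zero columns — isolated entities — become uniform columns), and random walk
with restart iterates `r ← cWr + (1−c)e` to an L1 fixed point. Defaults:
`c = 0.5` (the walk/restart balance is a free parameter here), tolerance
1e-6, max 1000 iterations; the iterative fixed point is verified against the
closed form `(1−c)(I−cW)⁻¹e` in the tests. Per-view profiles are
concatenated (entities × n_views·n_entities); concatenation is the
information-preserving aggregation, and the autoencoder that follows does
the mixing.

The denoising autoencoder is a single hidden layer with masking corruption
(rate 0.1), ReLU encoder, linear decoder, MSE loss, full-batch Adam at 1e-3,
500 epochs, trained separately per entity side. **The bottleneck is
deliberately tight: `hidden_dim = 4` by default.** Entity embeddings feed a
transductive pair-node model, and any embedding direction that encodes
*entity identity* rather than shared latent structure lets the network
memorize training pairs instead of generalizing; empirically, pair-level
held-out performance degrades quickly once the bottleneck grows past the
number of latent programs in the data. For data with richer latent
structure, raise `dae.hidden_dim` accordingly. The raw-RWR ablation bypasses
the autoencoder and optionally truncates by deterministic SVD to the same
width.

### Pair graphs

Pair nodes are the labeled pairs (positives plus sampled negatives) plus any
explicitly requested candidate pairs — not the full nL·nD grid, which would
be quadratic and mostly unlabeled. The interconnected graph (CG) joins two
pairs iff they share the lncRNA or the disease; the feature graph (RFG)
joins each node to its k = 5 most cosine-similar nodes (ties broken by
ascending node index for determinism) and is union-symmetrized, since the
encoder assumes undirected graphs. Self-loops are not stored: the GCN
normalization `D̃^{−1/2}(A+I)D̃^{−1/2}` adds them once, and storing them too
would double the self-weighting. Graph construction never reads labels, so
test pairs participate as nodes with their labels withheld (transductive
evaluation).

Pair features are the concatenation `[emb_L ‖ emb_D]`, column z-scored
before graph construction and encoding: raw diffusion profiles share a large
common baseline that drives all pairwise cosines toward 1 (making the kNN
graph uninformative) and shrinks early gradients.

### Encoder, fusion, head

Per view: GCN(32) → GAT(16, single head, self-inclusive neighborhoods,
LeakyReLU(0.2) attention logits, ELU output) → GCN(16), with the per-node
representation the concatenation of the first and last layer outputs
(K = 48). Attention logits follow the standard additive form
`a_src·Wh_j + a_dst·Wh_i`; the per-neighborhood softmax is shifted by the
segment maximum, an exact transformation. View fusion scores each view with
`w = qᵀ tanh(W Hᵀ + b)` (attention dim 16) and softmax-normalizes the pair
`(w_CG, w_RFG)` per node; the fused vector is the α-weighted sum, and the
α values are exposed for interpretation. The head is an MLP (32, 16) with
sigmoid output. Dropout 0.1 on layer inputs during training only.
Initialization is Glorot-uniform from the run seed. These widths are sized
for the bundled synthetic worlds; all are config-exposed.

The layers run on a small in-repo reverse-mode autodiff engine over float64
numpy arrays (`lncgraph.autodiff`); edge-wise message passing is expressed
as sparse-matrix products so no deep-learning framework is required, and
analytic gradients are verified against central finite differences.

Ablation variants rewire the stack under identical folds/seeds: `gcn`
(GCN–GCN), `gat` (GAT–GAT), `noatt` (fusion replaced by the element-wise
mean of the two views — the least-committal reading of "no attention"),
`cg`/`rfg` (single view, no fusion), `rwr` (no autoencoder).

### Training and evaluation

Binary cross-entropy on labeled pair nodes, full-batch Adam at 5e-3, up to
200 epochs with early stopping on the AUC of a stratified 20% validation
slice of the training pairs (patience 25, best weights restored). The
validation slice is larger than the conventional 10% because with a few
hundred training pairs a smaller slice makes the stopping signal too noisy
to be useful.

Negatives are sampled uniformly from zero cells at a 1:1 ratio, once
globally, then folded together with the positives (per-fold resampling is a
config switch). Stratified k-fold (5 or 10) partitions the labeled pairs;
within each fold the GIP kernel is recomputed with the test-fold positive
cells zeroed, so no training input depends on test labels. Metrics: AUC
(midrank ties), AUPR (step-wise average precision, no interpolation),
precision/recall/F1/MCC at threshold 0.5 (no operating point is canonical
for this task; 0.5 is the sigmoid midpoint). Both ranking metrics are
oracle-checked against explicit pairwise counting and threshold sweeps.

## Synthetic benchmark

The generator plants a block model: lncRNAs and diseases are assigned
round-robin to `n_blocks` blocks; association cells are Bernoulli(0.6)
within matched blocks and Bernoulli(0.02) across, then each cell is flipped
with probability 0.1 (symmetric label noise). Omic link tables share
partners within blocks (rate 0.6 against a 0.05 background, disjoint
partner namespaces per view), and the ontology is a random single-rooted
tree whose per-block subtrees group the diseases. The default world is
60 lncRNAs × 40 diseases × 4 blocks. Everything is deterministic given the
world seed; the pre-noise matrix is retained in memory (`bundle.truth`) for
recovery measurements but is never written as an input or used in training.

Two consequences of the symmetric noise are worth stating explicitly.
First, against the *observed* (flipped) labels the best achievable AUC for
any predictor without access to the flips is ≈ 0.744 under these rates —
the flips are independent of everything observable — and the pipeline
converges to that ceiling. Genuine method quality is therefore measured as
*recovery*: AUC of held-out-pair scores against the pre-noise labels
(ceiling ≈ 0.894 for a block-perfect predictor; the full pipeline reaches
≈ 0.87–0.90 across seeds, ahead of the CG-only ablation). Second, a binary
"same block" baseline scores ≈ 0.894/0.744 on the clean/noisy labels only
after midrank tie handling; bounds asserted in the tests account for that.

What the benchmark does not emulate: real similarity-network topology
(scale-free degree, hub diseases), curated-database ascertainment bias,
lncRNA sequence or expression signal, and ontology depth heterogeneity.
Passing tests demonstrate that the implementation is correct and that the
method recovers planted low-rank block structure under label noise — not
that it attains any particular performance on curated benchmark data.

## Numerical choices and edge cases

* All neural computation in float64; similarity symmetry enforced to 1e-12,
  transition-column sums to 1e-10, probability mass conservation to 1e-8.
* Cosine kNN ties and all orderings are broken lexicographically (IDs) or by
  node index, so identical configs reproduce bitwise-identical outputs.
* Degenerate inputs rejected with diagnostics: empty worlds, blocks with no
  members, zero-norm feature rows, k ≥ node count, single-class metric
  inputs, diseases missing from the ontology, non-converged diffusion.
* Duplicate edges in input files are de-duplicated with a logged warning;
  entity universes are declared in file headers so isolated entities survive
  round trips.

## Known limitations

* The attention-fusion benefit over single-view variants is small on the
  synthetic worlds (the two views are largely redundant there); the
  ablation machinery is the point, not the margin.
* Training is full-batch and dense along the feature dimension; worlds
  beyond ~10⁴ pair nodes would need mini-batching or sparsity in the
  feature graph construction (currently O(P²) cosine).
* The semantic-similarity stand-in is intentionally simple; supply a
  precomputed disease similarity matrix for serious use.
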