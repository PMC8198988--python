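# Methods

## Problem and model

`gatcda` predicts unobserved circRNA–disease associations from a sparse
binary association matrix **Y** ∈ {0,1}^(nc×nd) (rows: circRNAs, columns:
diseases) and three sources of side information: a circRNA–miRNA interaction
network (circRNAs act as miRNA sponges, so shared miRNA partners are
functional evidence), a disease–mRNA interaction network, and a precomputed
symptom-based disease similarity matrix DSS on a [0,1] scale. The pipeline
has three stages.

### 1. Similarity features

**Network similarity (CNS, DNS).** Each partner node k (miRNA or mRNA) with
degree deg_k > 0 carries a contribution

    nc_k = −ln( deg_k / Σ_j deg_j ),

the information content of its relative interaction frequency: rare partners
are stronger evidence of functional relatedness. The similarity of two
circRNAs (diseases) is the sum of nc_k over their shared miRNA (mRNA)
partners; the diagonal sums each entity's own partners. The formula admits a
second algebraic reading, (−ln deg_k)/Σ deg_j, which goes negative for
deg ≥ 2 and would break the non-negativity that the similarity sums assume;
it is kept behind `nc_interpretation="scaled"` for sensitivity analysis only.

**Information-entropy similarity (CES, DES).** For circRNA u with disease
partner set T_u, each disease i contributes a term −p_i log₂ p_i with
p_i = n_i / N, where n_i is disease i's total interaction count in Y and N
the total number of ones in Y. Note Σ p_i over one entity's partners is
generally < 1 — H(T_u) = Σ terms is a non-negative *pseudo-entropy*, used
exactly as defined without renormalisation. The pairwise similarity is the
Dice-style ratio

    CES(u,v) = 2 H(T_u ∩ T_v) / ( H(T_u) + H(T_v) ) ∈ [0,1].

When both entropies are zero (two isolated entities) the pair carries no
evidence either way: the value is 0 off the diagonal and 1 on it.

**Fusion.** ICS = β·CNS + (1−β)·CES for circRNAs and
IDS = α·(DNS + DSS) + (1−α)·DES for diseases, with adjusting parameters
α, β ∈ [0,1] (defaults 0.1/0.1, the best grid point under cross-validation).
DSS is bounded while DNS is an unbounded log-sum; no rescaling is applied by
default (`scale_similarities="minmax"` is available). The published
definition of the fusion carries a typographically duplicated trailing
CES/DES factor; the implementation follows the plain weighted sum that the
surrounding definition describes.

### 2. Graph attention encoder

Node features are the block-padded similarity rows: [ICS_row ‖ 0] for
circRNAs, [0 ‖ IDS_row] for diseases (common width F = nc + nd). Each row is
then L2-normalised (`feature_norm="l2"`): raw ICS/IDS rows have norms
spanning orders of magnitude, which destabilises attention training
(pilot runs: ≈ +0.07 AUC from normalisation alone). Whether to normalise was
a genuinely open design point; the raw features remain available with
`feature_norm="none"`.

The attention graph is the undirected bipartite graph of the *training*
associations plus a self-loop at every node, so entities whose edges are
held out still produce embeddings from their own features. Per layer and
head with projection W (F′×F) and attention vector a (2F′):

    e_ij = LeakyReLU( aᵀ [W f_i ‖ W f_j] ),   θ_ij = softmax_{j∈N(i)}(e_ij),
    f′_i = σ( (1/K) Σ_k Σ_j θᵏ_ij Wᵏ f_j ).

Heads are *averaged* before the nonlinearity (so K = 1 reduces exactly to
the single-head layer). Defaults: 2 layers (ELU on the hidden layer,
identity on the output), K = 2 heads, F′ = 32, LeakyReLU slope 0.2. The
final embeddings split into circRNA rows U and disease rows V, and all pairs
are scored bilinearly, S = U Vᵀ.

The forward and backward passes are written directly in numpy with
analytically derived gradients (segment softmax, scatter/gather message
passing); the backward pass is validated against central finite differences
(worst relative error ≤ 1e−4 in the shipped check).

### 3. Training

No canonical training objective exists for this architecture in the
literature it comes from, so the package uses the standard one for sparse
bipartite link prediction: mean binary cross-entropy of sigmoid(S) over the
observed positives plus uniformly re-sampled unknown cells (5 negatives per
positive per epoch by default), minimised with Adam (lr 5e−3, 300 epochs).
A fixed `random_state` makes runs bit-reproducible on one thread.

**Edge dropout.** At evaluation time, a scored pair's edge is by definition
absent from the graph; a model trained only on the full graph learns to rely
on observed edges and generalises poorly to such pairs. Each training epoch
therefore hides a random fraction (`edge_dropout`, default 0.9) of the
association edges from the attention graph (self-loops are never dropped),
re-sampled every epoch. In pilot cross-validation on the synthetic benchmark
this and the companion defaults (K=2, F′=32, feature dropout 0.1, 5:1
negatives) raised mean held-out AUC from ≈0.63 (with a conventional
K=4/F′=64/dropout 0.4/1:1 configuration) to ≈0.86. Classical full-graph
training is recovered with `edge_dropout=0`.

## Evaluation protocol

Positives are partitioned uniformly at random into five folds (sizes differ
by ≤ 1); per fold the model is refitted on Y with that fold zeroed. The
entropy similarities CES/DES and the attention graph are recomputed from the
*training* matrix inside `fit`, so held-out labels never leak into features —
asserted by a dedicated test. Fold positives are ranked against **all**
unknown cells of Y (a threshold-free, conservative full-ranking evaluation;
`negatives="sampled"` gives a 1:1 sampled alternative). Reported: ROC-AUC
(rank-based, ties averaged), AUPR (step-wise interpolation, no precision
envelope), and accuracy/precision under two documented threshold rules —
a score quantile matching the training prevalence, and sigmoid(score) ≥ 0.5 —
because no single threshold is canonical for ranking scores. The aggregate
is the exact mean over folds. `grid_search` repeats the full CV per (α, β)
pair; `rank_candidates` implements the case-study protocol: all of one
disease's positives are hidden, the model is retrained, and that disease's
circRNAs are ranked (ties broken lexicographically).

Under the full-ranking protocol with ~1% prevalence, precision at the
prevalence threshold is intrinsically low even for a well-ranked list
(~120 test-relevant cells among ~10,000 candidates); AUC/AUPR are the
meaningful summaries and accuracy is dominated by the negatives.

## Synthetic data

The generator plants a rank-r logistic latent-factor model:
u_i, v_j ~ N(0, I/r), P(Y_ij=1) = sigmoid(c + s·u_iᵀv_j) with the intercept
c calibrated by bisection to a target density. Auxiliary networks are
coupled to the same factors (edge preference sigmoid(c′ + s·u_iᵀw_m) for
miRNA factors w_m, analogously for mRNAs), so auxiliary neighbourhood
overlap correlates with the planted association structure — the assumption
the similarity features encode. DSS is the cosine similarity of the disease
factors plus symmetric N(0, 0.1) noise, clipped to [0,1] with unit diagonal.

Default shapes mirror the curated corpus the method targets: 624×102
associations at ~1.2% density (~768 positives), 142 miRNAs and 820 mRNAs
with auxiliary densities ~4% (the density of the covered sub-networks in
that corpus). The default signal/coupling strength is 8.0, chosen so the
planted structure is strongly identifiable — ranking cells by the *true*
generating probabilities yields AUC ≈ 0.99 — so failure to recover it
indicates a method defect rather than irreducible noise (at strength 3 the
same oracle ceiling is only ≈ 0.86, too close to any sensible recovery bar
to be diagnostic). The bilinear scorer is correctly specified for this
generative model, which is what makes recovery tests meaningful.

What the generator does **not** emulate: hub-dominated degree distributions,
disease ontology structure, database ascertainment bias, or sequence-level
miRNA binding. Passing the synthetic benchmark therefore shows the pipeline
recovers planted low-rank structure under its own model assumptions; it does
not certify performance on curated biological corpora.

Benchmark sizes used by the tests and the acceptance script — 200×50
associations (~120 positives) for the recovery benchmark and a 10-seed null
ensemble at 100 epochs — were chosen to keep a full run in tens of seconds
while leaving the recovery margin (AUC ≈ 0.86–0.90 vs the 0.8 bar and a null
mean ≈ 0.5) clearly resolvable.

## Numerical choices and degenerate inputs

- Attention softmax subtracts the per-neighbourhood maximum before
  exponentiation; BCE uses log1p/expm1-safe forms (`logaddexp`).
- All-zero auxiliary networks yield zero CNS/DNS (with a warning), never an
  error; a missing DSS defaults to the identity.
- Zero-entropy pairs: CES/DES = 0 off-diagonal, 1 on the diagonal.
- Similarity matrices are validated symmetric to 1e−9, non-negative, finite;
  input DSS tables are symmetrised as (M+Mᵀ)/2 only when max asymmetry
  ≤ 1e−6, else rejected.
- Entity names are whitespace-trimmed and case-folded, indices ordered
  lexicographically, so results are independent of input file ordering; no
  fuzzy identifier matching is attempted.
- Training aborts with a diagnostic if the loss becomes non-finite.
- Ties in candidate ranking are broken by circRNA name.

## Known limitations

- The encoder is transductive: scoring an entity requires it to be present
  (at least as an isolated node) at training time.
- Dense nc×nd scoring and dense similarity matrices bound practical problem
  sizes to ~10⁴ nodes.
- Accuracy/precision depend on the chosen threshold rule; both documented
  rules are reported, neither is canonical.
- Symptom-similarity computation from literature co-occurrence is out of
  scope; DSS is ingested as a precomputed matrix.
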