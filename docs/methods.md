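# Methods

## Problem and model

The observed data are a binary bipartite matrix `Y` (lncRNAs × diseases)
with `y_ij = 1` for curated associations. The task is to score unobserved
pairs. The model treats the two similarity graphs as the carriers of
information: entities that are similar — by interaction profile, by
ontology position, or by the diseases they share — should have similar
association patterns. Embeddings are learned so that the inner product of a
lncRNA and a disease embedding reconstructs `Y` (preference matrix trained
with binary cross-entropy), and a discriminative ensemble then classifies
concatenated embedding pairs. The two stages are deliberately separate: the
encoder is generative/reconstructive over the whole matrix, while the
ensemble is trained only on the labeled pair sample (positives plus sampled
negatives), which is what the cross-validation protocols actually score.

## Similarities

* **Interaction-profile kernel.** `K(i,j) = exp(−γ d²)` with
  `γ = γ′ / mean‖profile‖²` (`γ′ = 1` default). Normalizing by the mean
  squared profile norm makes the bandwidth scale-free in network density.
  An all-zero profile matrix is rejected (bandwidth undefined); individual
  zero rows are fine and simply have similarity `exp(−γ‖other‖²)` to others.
* **Disease semantic similarity.** Each disease contributes 1 to itself and
  `Δ^depth` (best path) to each ancestor, `Δ = 0.5`; similarity is the
  shared contribution mass divided by the two total masses. Diseases absent
  from the ontology are *undefined* off-diagonal rather than zero, so
  fusion can fall back to the kernel instead of diluting it.
* **lncRNA functional similarity.** Best-match average between associated
  disease sets under the semantic (or, without an ontology, kernel) disease
  similarity. Association-free lncRNAs are undefined off-diagonal with the
  value convention 0.
* **Fusion.** Arithmetic mean where both matrices are defined, kernel
  elsewhere. Every emitted matrix is validated: symmetric within 1e-9,
  entries in [0,1], unit diagonal.

## Encoder

* Layer stack per graph: GCN → GAT → GCN, propagation operator
  `A^{−1/2}(I+S)A^{−1/2}` on the *full weighted* similarity matrix — no
  kNN sparsification, since the graphs have at most a few hundred nodes.
* **Initial features** `H⁰ = S` (the similarity rows themselves): the
  method needs no external node features.
* **Attention.** Per head, logit
  `LeakyReLU(a_kᵀ[W_k H_i ‖ W_k H_j ‖ B_k S_ij])`, softmax over the
  neighborhood `{j : S_ij > 0} ∪ {i}` (self-inclusion prevents empty
  neighborhoods), heads averaged. The aggregation uses the neighbor
  features `H_j`, the standard attention formulation; `B_k` is one
  trainable scalar per head initialized at 1, matching the `2F+1` length of
  `a_k`. Negative slope 0.2.
* **Combiner.** `H¹` and `H³` are stacked as two channels and passed
  through a same-padded width-3 1-D convolution along the feature axis
  (2→1 channels); `H²` feeds the second GCN but not the combiner. The two
  graphs have separate convolution weights.
* **Training.** Adam (lr 1e-3), 200 epochs, full batch; loss is the stable
  logits form of BCE between `X_cᵀX_d` and `Y`. A non-finite loss raises
  with the epoch index. Everything is initialized from one seed
  (Glorot-uniform weight matrices), so runs are bit-reproducible.
* `U = X_cᵀX_d` is only the encoder's training signal; final scores come
  from the ensemble.

## Ensemble

* **Feed-forward member.** Hidden layers (128, 64) by default, ReLU,
  logistic output, Adam lr 1e-3, 200 epochs, full batch (deterministic —
  no minibatch shuffling).
* **Boosted-tree member.** From-scratch Newton boosting: start at raw score
  0 (probability 0.5); per round `g = p − y`, `h = p(1−p)`; trees grown
  best-first (leaf-wise) by exact greedy split search over all features and
  midpoints between distinct values, stopping at 31 leaves or non-positive
  gain; leaf weight `−Σg/(Σh+λ)`; shrinkage ν = 0.1, λ = 1, 100 rounds.
  Exact greedy search is preferred over histogram binning because the pair
  tables here are small; the histogram-based library backend
  (`backend="lightgbm"`) exists purely as a parity cross-check.
* **Vote.** `Score = 0.4·C_DNN + 0.6·C_trees`; label positive iff
  `Score > 0.5` strictly — a tie at exactly 0.5 is negative. The weights
  are configurable but have no tuning procedure.

## Evaluation protocols

* Negatives are sampled uniformly without replacement from zero entries,
  ratio 1:1 to positives, resampled per repeat — balanced training is
  assumed by the accuracy/F1 reporting.
* CV1/CV2 partition entities 80/20; every labeled pair touching a held-out
  entity is test-only. CV3 partitions the labeled pair list 80/20. A
  partition leaving either side single-class is resampled (logged, at most
  100 attempts).
* Before training, held-out associations are zeroed from `Y`: under
  CV1/CV2 the kernels and encoder therefore see no association signal from
  test entities (ontology semantic similarity, being
  association-independent, remains intact — this is what keeps "new
  lncRNA/new disease" prediction meaningful); under CV3 the held-out
  positive pairs are zeroed.
* Metrics: thresholded precision/recall/accuracy/F1 at the strict 0.5 cut,
  tie-aware AUC (average-rank / trapezoidal ROC) and step-integrated AUPR.
  Reports carry per-repeat rows plus mean ± std; 10 repeats by default.

## Synthetic study conditions

The generator plants a rank-r latent structure: nonnegative factors
(absolute Gaussians) `L (n×r)`, `R (m×r)`; `Y` is `L Rᵀ` thresholded at the
quantile matching the target density, then each entry is flipped with the
noise probability. Nonnegative factors were chosen so the planted block
structure is visible to the interaction-profile kernels — otherwise encoder
recovery would not be testable through the similarity pathway. Default
conditions: 40 lncRNAs × 60 diseases, rank 3, density 0.1 (240 positives),
noise 0. Ontologies are random layered DAGs (30 terms, branching ≤3,
depth 4), acyclic by construction.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated LDA databases, disease co-annotation bias, and
literature-driven missingness (absence of an edge in real data is not a
verified negative). Passing recovery tests therefore demonstrates that the
pipeline can extract planted low-rank association structure through the
similarity → encoder → ensemble pathway at realistic sparsity, not that it
attains any particular accuracy on curated human datasets.

## Numerical choices and degenerate inputs

* Kernel distances are clamped at 0 before exponentiation; similarity
  matrices are clipped into [0,1] after validation.
* Softmax logits are max-shifted per row; BCE is computed in log-sum-exp
  form.
* Prediction-table ordering breaks score ties by lexicographic lncRNA id,
  making ranked output byte-stable.
* Split-gain ties in the tree learner break toward the earlier node and
  feature; gains must exceed the incumbent by 1e-12 to replace it.
* An identity similarity matrix (no off-diagonal signal) degenerates the
  encoder to per-node transforms but stays finite; an all-zero adjacency
  in a GCN reduces the propagation operator to the identity.
* Problem sizes in the test suite and acceptance script (networks up to
  40×60, 5 repeats per condition) were chosen as the smallest scale at
  which planted-structure recovery is stable across seeds.

## Known limitations

* No identifier normalization across lncRNA/disease nomenclatures; id
  matching is case-sensitive exact string match.
* No probability calibration; soft-vote scores are convex combinations of
  member probabilities, not calibrated posteriors.
* No hyperparameter search; defaults are fixed and exposed.
* The from-scratch boosting trainer is exact-greedy and single-threaded;
  it is intended for desk-scale tables (thousands of rows), not
  genome-scale feature matrices.
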