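# Methods

`sdgae` predicts drug–target interactions (DTIs) from a heterogeneous
collection of binary interaction/association matrices and precomputed
similarity matrices. This note documents the model, its parameters, the
numerical choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Model overview

Given `m` drugs, `n` targets, a binary interaction matrix `Y ∈ {0,1}^{m×n}`
and side networks (drug–drug and target–target interactions, drug–disease,
drug–side-effect and target–disease associations, chemical-structure and
sequence similarities), the pipeline runs five stages:

1. **Similarity fusion.** Every binary association network yields a
   Jaccard-index similarity view between drugs (or targets); the fused
   similarity is the elementwise maximum over all views, including the
   precomputed chemical/sequence similarity:
   `S^D(i,j) = max(S_chem, S_DDI-Jaccard, S_disease, S_side-effect)(i,j)`,
   and analogously `S^T` from three target views.
2. **Densification (WKNKN).** Drugs/targets with no known interaction are
   isolated in the bipartite DTI graph, which defeats graph convolution.
   Each zero of `Y` is imputed from the interaction profiles of the K most
   similar *known* drugs with geometrically decaying weights
   `η^{a−1}·S^D(i,d_a)`, normalized by `Σ_a S^D(i,d_a)`, averaged with the
   symmetric target-side estimate, and floored by the original `Y`. The
   imputed values strictly inside (0,1) form the multiset `E`; thresholding
   `Y_dense` at the median of `E` gives the binary `Y_DTI` used for graph
   edges. Labels for the classifier always come from the original `Y`.
3. **Heterogeneous graph.** Block adjacency
   `Ã = [[A^D, Y_DTI],[Y_DTIᵀ, A^T]]` (drugs first), node features
   `X̃ = [[S^D, Y_dense],[Y_denseᵀ, S^T]]`, and the self-looped symmetric
   normalization `Ā = D̃^{-1/2}(Ã+I)D̃^{-1/2}`.
4. **Graph-convolutional autoencoder.** Two-layer encoder
   `Z = tanh(Ā·sigmoid(Ā X̃ W₁)·W₂)`, inner-product decoder
   `Â = sigmoid(Z Zᵀ)`, summed squared reconstruction error
   `L_rec = ‖Ã − Â‖²_F`. Two regularizers are added:
   * **Spatial consistency.** A mutual-p-nearest-neighbour graph `N`
     (1 mutual / 0.5 one-sided / 0 neither, self always in its own p-set)
     sparsifies the fused similarity, `Ŝ = N ⊙ S`; the loss is
     `λ_l(‖Z^D‖²_F + ‖Z^T‖²_F) + λ_d Σ_{i,r} Ŝ^D(i,r)‖z_i − z_r‖² + λ_t Σ_{j,q} Ŝ^T(j,q)‖z_j − z_q‖²`,
     keeping original-space neighbours close in the embedding space.
   * **Adversarial.** A small MLP discriminator (k → 64 → 32 → 1,
     leaky-ReLU 0.2, sigmoid head) is trained to tell embedding rows from
     i.i.d. standard-normal samples; the encoder receives the usual
     non-saturating generator loss. One discriminator step then one encoder
     step per epoch, both with Adam.
5. **Classifier.** Every pair (i,j) becomes the length-2k concatenation of
   the two embedding rows; a LightGBM binary classifier is fit on all
   negative pairs plus the training positives (no negative subsampling —
   the tree ensemble absorbs the ~1:500 imbalance) and scores all m×n pairs.

The autoencoder, its gradients and Adam are implemented directly in numpy.
Training is full batch (the graphs of interest have at most a few thousand
nodes), so closed-form backpropagation is exact; correctness is verified by
finite-difference gradient checks in the test suite, and a fixed seed
reproduces a run bit-for-bit on CPU.

## Loss-form bookkeeping

The pairwise double sum `Σ_{i,r} s_{ir}‖z_i − z_r‖²` over ordered pairs
equals `2·Tr(ZᵀLZ)` with `L = D − Ŝ`. We take the double-sum form as the
definition of the loss and implement the trace form with the matching
factor 2 (`scc_trace_factor`, configurable), so both printed forms agree
numerically; the equality is asserted on random instances to 1e−8. The
Tikhonov term stays explicit in the loss rather than being folded into
optimizer weight decay, so the logged `L_encoding` is exactly
`L_reconstitution + L_spatial_consistency` at every epoch.

## Parameters

| name | default | meaning |
|---|---|---|
| `eta` | 0.8 | geometric decay of neighbour weights in WKNKN |
| `K` | 10 | known-neighbour count for densification |
| `p` | 5 | neighbour-set size of the spatial-consistency graph |
| `lambda_l` | 1e−5 | Tikhonov weight on the embeddings |
| `lambda_d`, `lambda_t` | 1e−3 | drug/target Laplacian weights |
| `epochs` | 5000 | encoder/discriminator training epochs |
| `lr_repr` | 1e−4 | Adam learning rate, representation stage |
| `lr_gbdt` | 0.02 | LightGBM learning rate |
| `hidden_dim` (l) | 500 | first GCN layer width |
| `embed_dim` (k) | 200 | embedding dimension |
| `n_folds` | 10 | cross-validation folds |

The first block are published settings. `l` and `k` are not printed for
this model; 500/200 are the values assigned to its closest relative among
the compared methods and are therefore the paper-profile defaults.
`RunConfig.desk_profile()` ships a second profile (l=64, k=32, 400 epochs,
learning rate 5e−3, 300 boosting rounds) whose learning rate is chosen so
full-batch Adam converges within the shorter budget on graphs of ~10²
nodes; it makes a complete 10-fold CV run a ~20-second affair on one CPU
core. LightGBM settings beyond the learning rate are not published;
defaults are 500 rounds / 31 leaves (300 rounds in the desk profile),
seeded and deterministic.

Open choices made once and kept: the two WKNKN side estimates are
*averaged* (configurable to max); the median of an even-sized `E` is the
lower central value, so the threshold is always an attained imputation;
neighbour ties break by ascending index everywhere, keeping runs
deterministic; the off-diagonal feature block uses the real-valued
`Y_dense` (more informative than the binarized `Y_DTI`; switchable);
the generator loss is optimized in its own unweighted step.

## Cross-validation protocol

Positive pairs are folded; all negative pairs are available to every
training fold. For each fold the held-out positives are zeroed in the
working `Y` and **everything downstream is recomputed** — WKNKN, graph,
embeddings, classifier — because a held-out edge would otherwise leak
through imputation or the adjacency. Per-fold AUC/AUPR are computed on the
held-out positives against all true negatives. A pooled m×n score matrix
(positives scored by their own test fold, each negative the mean of its
per-fold scores) yields the global AUC/AUPR, the per-drug metric lists
(drugs with at least one known target only) and the mean top-ω recall for
ω ∈ {5, 10, 15, 20, 30}%. In the novel-interaction mode the roles flip:
embeddings are trained once on the full `Y`, negatives are folded, and
each candidate is scored strictly out-of-fold before ranking.

## Synthetic benchmark

The generator plants `c` matched drug/target cluster pairs: interaction
probability `pi_in = 0.3` within a matched pair versus `pi_out = 0.01`
elsewhere; intra-type networks and association matrices draw from
per-cluster feature blocks (rate 0.4, 2% background), so the Jaccard views
recover the clusters; the precomputed similarities are noisy cluster
indicators (between-cluster level 0.2, jitter sd 0.1). 20% of drugs and
30% of targets have their `Y` rows/columns zeroed to emulate the isolated
unknown nodes that motivate densification, with the hidden positives
retained as recoverable ground truth. The default benchmark is m=60, n=80,
c=4, generator seed 7 — sized for minutes-scale end-to-end runs.

The benchmark realizes the assumption the method is built on — similar
molecules interact with the same partners — in an idealized form. Passing
it shows the pipeline recovers planted neighbourhood structure through
every stage; it does not show performance on real pharmacological data,
where similarity views are weaker, cluster structure is diffuse and the
positive rate is an order of magnitude lower (0.18% in the published
matrix collection versus ~6% here). The published headline figures
require that dataset and a 5000-epoch paper-profile run; `run_pipeline`
reproduces the protocol unchanged when such a dataset directory is
supplied in the canonical text layout.

## Numerical notes and limitations

* Binary cross-entropy clamps probabilities to [1e−7, 1 − 1e−7].
* The sigmoid is evaluated in the numerically stable two-branch form.
* Self-loops guarantee positive degrees, so the normalized adjacency is
  always defined; its spectral radius is ≤ 1.
* Degenerate inputs: an empty neighbour list leaves a WKNKN row untouched;
  an empty imputation set `E` makes densification the identity and the
  threshold undefined (reported as `None`); a single-class training fold
  raises rather than returning a vacuous model.
* Paper-profile memory: materializing all 1.07M pair features at k=200
  costs ~3.4 GB; the desk profile is far below that. A streaming
  predictor would remove the ceiling and is future work.
* The discriminator architecture and update schedule are fixed (not
  searched); the adversarial term mainly regularizes scale and is the
  first thing to switch off (`use_gan=False`) when diagnosing training.
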