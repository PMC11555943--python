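# Methods

## Problem and model

Given drugs `D` and side effects `S` with observed frequency triplets
`(d, s, y)`, `y ∈ {1..5}`, the observed data induce a matrix `A ∈ ℝ^{n×m}`
with `A(i,j) = y` for known pairs and 0 otherwise. The model learns, for
every pair, an association probability and an ordinal frequency estimate.

Each drug is represented by three vectors in a shared `dim`-space and each
side effect by two:

* **Text** `t`: a deterministic sentence embedding of the entity's
  description, linearly projected `f → dim`. The embedding provider is
  pluggable; the built-in provider is a hashed bag-of-words (tokens hashed
  into `f = 64` signed buckets, counts L2-normalized). It is not a language
  model: it carries lexical-overlap signal only, which is exactly what the
  synthetic corpus plants. Precomputed embeddings from any external model
  can be supplied as a TSV and used unchanged; they are never fine-tuned,
  only the projection is learned.
* **Structure** `v` (drugs only): a two-layer, four-head graph attention
  network over the RDKit heavy-atom graph. Atom features are one-hot
  element indicators over the corpus element vocabulary (optionally
  extended with degree, formal charge, aromaticity). Attention logits
  `e_pq = a·[W x_p ; W x_q]` pass through LeakyReLU (slope 0.2) and a
  softmax over the neighborhood; self-loops are added so every atom —
  including isolated ones — attends to itself. Head outputs are
  concatenated, ELU sits between layers, and a final linear map to `dim`
  precedes coordinate-wise max pooling over atoms (projecting per-atom and
  then pooling keeps the output permutation-invariant and
  dimension-stable).
* **Attributes** `o`: for drugs, `o^d = ReLU(W [chem_row ; disease_row] + b)`
  where `chem_row` is the drug's row of an externally supplied chemical
  similarity matrix and `disease_row` its row of the Jaccard similarity
  over binary drug–disease profiles (two all-zero profiles get Jaccard 0 —
  no evidence of similarity). For side effects, three similarity views —
  ontology hyponymy, word-vector cosine, association-profile cosine — are
  each projected to `dim` and combined by a learned softmax attention with
  one shared single-output scorer `tanh(W u + b)`; weights always sum to 1
  over the *available* views, which is what makes the cold-start
  configuration (two views) well-defined.

**Ontology similarity.** Side-effect terms map to dotted ids in a
four-level hierarchy whose 'is-a' edges connect each id to its prefix
parent. The contribution of ancestor `s` to term `A` is `D_A(A) = 1` and
`D_A(s) = μ · max over children of s inside A's ancestor closure`,
i.e. `μ^L` for the best upward path of length `L`; `μ = 0.5`. The
similarity of two terms is the sum of both contributions over shared
ancestors divided by the sum of their total semantic values. Terms with
several ids take the union closure; terms absent from the ontology are
similar only to themselves. The recursion is verified in the test suite
against a brute-force max-over-paths enumeration.

**Fusion.** The 3×2 modality pairs feed two operators. Coarse: the printed
formula is read as the *scalar* inner product per pair, the six scalars
mixed by a linear map then ReLU; the alternative reading (sum of the six
element-wise product vectors, then the linear map) is available behind
`fusion_reading="vector"`. Fine: the six outer-product maps (`dim × dim`)
are stacked as channels and passed through two convolution blocks of 2×2
kernels with stride 2 (kernel = stride, so each block is a linear map on
non-overlapping patches), channels 6→16→32, ReLU, flatten, linear, ReLU.
Two separate two-layer MLPs on `[c₁ ; c₂]` emit `FS` (linear output,
unclamped during training, clamped to [1,5] only for reporting) and `AS`
(sigmoid). The heads share no weights — the two equations are printed
separately.

**Loss.** `L = L₁·L₂ + γR(Θ)` with `L₁` the mean squared association
error over all samples in the batch and `L₂` the mean squared frequency
error over positives only; negatives carry no frequency label (frequency
is undefined for non-associated pairs). Association labels are hard
{0,1}; an optional label-smoothing ε is exposed since the source notation
leaves the open interval ambiguous. A batch with no positives contributes
`L₁ + γR` (multiplying by a placeholder `L₂` would distort the gradient
scale); the stratified batch sampler makes such batches impossible under
the usual 1:1 negative sampling. `R` is the sum of squared parameters and
is implemented explicitly in the loss; the optimizer's weight decay
(1e-3) is honored in addition, since the protocol lists both.

## Training protocol

Adam, initial learning rate 5e-4 multiplied by 0.2 after epoch 250, at
most 400 epochs, batch size 128, embedding dimension 128 at full scale.
Dropout (inverted, applied to the hidden layer of each prediction head —
the protocol fixes only the rate grid, not the site) and `γ` are tuned on
the 3×3 grid {0.4, 0.5, 0.6} × {1e-3, 1e-4, 1e-5} by inner
cross-validation on frequency RMSE, ties broken toward lower `γ`, then
lower dropout. Negative sampling draws exactly |positives| unobserved
cells uniformly without replacement, seeded. All randomness — init,
shuffling, dropout, sampling — flows from one generator per run.

Numerics: all tensors run through a package-local reverse-mode autodiff
engine on NumPy (float32 working precision by default; float64 switchable,
used by the finite-difference gradient checks). Masked attention uses a
−1e30 fill with the usual max-shift softmax; gradient of a tied max splits
equally among the argmaxes. Divergence (non-finite loss) aborts with a
diagnostic rather than continuing.

## Evaluation

AUROC (Mann–Whitney concordance, ties at 0.5) and AUPR (step-wise average
precision, not trapezoid-interpolated) measure association ranking; RMSE
and MAE on positives only measure frequency accuracy. Pairwise protocol:
positives and sampled negatives are pooled, shuffled into five outer
folds, each outer-train re-split five-fold for the inner loop. Cold-start
protocol: a held-out fraction of drugs (10%) never contributes a training
pair, the remaining drugs form drug-wise folds (fold count shrinks to the
number of available drugs when they are scarce), and the
association-profile view is disabled throughout. The association-profile
similarity matrix is always built from the training fold's matrix only;
a test verifies its serialized form is byte-identical under any change of
test-fold cells. The Wilcoxon rank-sum utility reports the rank-sum
statistic with a two-sided p-value (exact for small tie-free samples,
tie-corrected normal approximation otherwise).

## Synthetic corpus

The generator plants one low-rank structure in every modality so that
end-to-end learnability is a property of the implementation, not of data
availability. Drug factors `U (n×r)` and side-effect factors `V (m×r)`
are standard normal; the raw affinity is `UVᵀ + ε`, `ε ~ N(0, 0.3²)`
(about 10% of the affinity scale `√r ≈ 2.8`). The top 10% of cells by raw
value become observed pairs; observed values are quantized into classes
1–5 by within-observed quantiles — near-balanced classes by default, with
a `skew` parameter that tilts mass toward the middle classes the way real
pharmacovigilance data is imbalanced. Defaults: 100 drugs, 120 side
effects, rank 8, seed-driven.

Derived inputs: chemical similarity is the cosine of drug factors mapped
to [0,1]; the binary drug–disease matrix thresholds affinities to 900
disease prototypes (nine diseases per drug, the ratio of the reference
toxicogenomics database) — the panel size matters, because the Jaccard
profile is the main carrier of drug-factor *magnitude*, which the cosine
construction discards; descriptions are built from per-dimension topic
vocabularies with token repetition counts proportional to |U_td| and a
constant anchor sentence, so the normalized bag-of-words embedding retains
both direction and overall magnitude; word vectors are noisy linear images
of `V`; the ontology assigns each side effect a distinct leaf of a
4×4×4×4 tree (ontology placement is deliberately *uncorrelated* with the
latent factors — the hyponymy view contributes structure, not label
signal). Molecules are drawn from a bundled list of 56 drug-like SMILES
with seeded substituent edits, re-validated by the parser; molecular
structure is therefore also uncorrelated with the planted labels, and the
GAT branch is exercised architecturally rather than semantically.

What passing tests therefore show: the pipeline recovers planted
bilinear structure from text, attribute, and association-profile
channels under realistic noise. What they do not show: performance on
real pharmacovigilance data, usefulness of a pretrained language model,
or any benefit of molecular structure for frequency prediction — the
generator's molecules carry no label signal by design.

## Desk-scale problem sizes

The shipped experiments (test suite and `scripts/acceptance.py`) use the
default synthetic corpus with embedding dimension 32, batch 128, up to
200 epochs for the pairwise run and 100–150 for cold start. (dropout, γ)
are fixed to (0.5, 1e-3), the values selected once by validation-RMSE
grid search on this corpus; the learning-rate decay epoch is rescaled
proportionally to the shortened budget (125 of 200, mirroring 250 of
400). Because the multiplicative objective makes the frequency error
fluctuate once the association task saturates, the epoch count is treated
as a hyperparameter: training monitors a validation split every five
epochs, restores the best checkpoint, and can average the predictions of
the best three (`train_with_validation` / `predict_ensemble`). All
selection uses validation data only. The nested 5×5 cross-validation and
the full 3×3 grid are exercised end-to-end at tiny scale in the tests; a
full-scale nested run is a matter of compute, not code.

## Known limitations

* The hashed text encoder is a fixture-grade stand-in by design; with it,
  the text channel measures lexical overlap only.
* Bond types and 3-D geometry are ignored (adjacency-only molecular
  graphs, matching the bond-set reading of the molecular graph).
* The multiplicative loss couples the tasks asymmetrically: as the
  association error shrinks, the frequency gradient through the shared
  trunk is scaled down by `L₁`, so frequency accuracy converges slowly on
  corpora where association is easy. This is a property of the printed
  objective, observable in the training logs.
* Whether the two heads should share their first layer, whether
  similarity rows should be row-normalized before projection, and the
  exact CNN depth/width are under-determined by the source; the choices
  here (no sharing, no normalization, 6→16→32 channels) are documented
  defaults, each behind a parameter.
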