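# Methods

## Problem setting

Catalogues of experimentally verified miRNA–disease associations are
positive-unlabeled: the complement of the recorded positives mixes genuine
negatives with not-yet-verified positives. Any classifier trained with
"negatives" drawn from that pool learns from mislabelled examples. The
package treats this as a label-noise problem with three mitigations:
feature-space-spread negative selection, bootstrap-subsample ensembling
with soft voting, and a gradient-boosted base learner.

The noise level itself is estimable from catalogue growth: if an older
release records `n_old` positives, a newer one `n_new`, over an
`n_m × n_d` universe, a uniform draw from the older release's undetected
pool is a hidden positive with probability
`(n_new − n_old) / (n_m·n_d − n_old)`. For the reference catalogue pair
used throughout the documentation (5430 → 12 034 over 495 × 383) this is
3.59%.

## Disease semantic similarity

Diseases carry dot-separated hierarchy codes; whole-segment prefixes define
ancestry. DAG(d) contains d plus every disease owning a prefix of one of
d's codes, with edges along immediate-prefix parenthood. Two semantic-value
models are computed over each DAG:

* **Decay model.** D(d)=1 at the target; otherwise
  D(d) = max over children d′ (within the DAG) of Δ·D(d′), evaluated by a
  reverse topological sweep. Δ is a free decay parameter; the source method
  does not fix it, and the package defaults to 0.5, the convention of the
  semantic-similarity literature this construction descends from. A vertex
  reachable by several paths takes the maximum, consistently with the
  recursion.
* **Information-content model.** D(d) = −log(N_d/N), where N_d counts how
  many diseases' DAGs contain d and N is the number of diseases in the
  tree-number table. The logarithm base cancels in the similarity ratio;
  natural log is used. N is taken over the supplied table, not any larger
  vocabulary — the table is the ingestion contract.

Similarity is shared semantic mass over summed totals (the SS formula in
the README), computed under each model and averaged. Degenerate cases: an
empty vertex intersection scores 0; if both totals are 0 (possible under
the information-content model when every vertex is ubiquitous) the score is
defined as 0, which makes the self-similarity of a ubiquitous root 0.5
after averaging — a documented artefact of the model pair, left
uncorrected. Diseases absent from the table have no semantic row at all;
absence is tracked explicitly (NaN), never encoded as 0, because 0 is a
legal similarity.

Missing intermediate headings (a prefix code owned by no disease) are
skipped, and the nearest existing ancestor is connected directly to the
nearest existing descendant so every vertex keeps a path to the target.

## miRNA functional similarity and GIP kernels

FSM(mᵢ, mⱼ) is the best-match average between the two miRNAs' associated
disease sets (restricted to diseases with semantic rows); it is undefined —
not zero — for miRNAs with no usable diseases. The GIP kernel uses binary
interaction profiles (adjacency rows/columns) with bandwidth
γ = γ′ / mean‖IP‖², γ′ = 1 per the source method, exposed as configuration.
Integrated similarity averages SS (or FSM) with the GIP value where the
former exists and falls back to GIP alone otherwise. Pair features are the
concatenated integrated rows, miRNA block first (n_m + n_d dimensions).

By default the GIP kernel is computed once from the full association matrix
(`gip_mode="full"`), which lets held-out associations inform features
during cross-validation; `fold_safe` mode zeroes the held-out cells per
fold. Full mode is the convention of this method family and the default,
with a logged warning; the fold-safe comparison is available because the
leakage inflates full-mode scores (verified as a property test).

## Negative sampling

Undetected pairs are clustered with seeded k-means (k-means++
initialisation, up to 300 iterations, tolerance 1e-4; k = 23 by default,
inherited from the method family) on exactly the pair features used for
classification. Quotas are ⌊n/k⌋ per cluster, the remainder distributed
one-per-cluster by descending cluster size; clusters smaller than their
quota contribute everything and the deficit is redistributed proportionally
to the remaining spare capacity. The draw within each cluster is uniform
without replacement; the result is exactly n pairs, reproducible per seed.

Whether equal-quota sampling actually *reduces* the hidden-positive
fraction relative to uniform sampling depends on the data: its expected
noise fraction is the unweighted mean of per-cluster noise rates, versus
uniform sampling's size-weighted mean, so it helps precisely when larger
clusters are noisier. In the latent-factor generator below the correlation
between cluster size and noise rate is consistently *negative* (positive-
like pairs form small, tight clusters), so equal quotas do not reduce the
noise there; the package ships `sampling.cluster_noise_profile` to measure
this on any dataset rather than assume a direction.

## Ensemble and evaluation

`fit` draws S bootstrap subsets (default 10, subset size equal to the
training set, with replacement — the classic bootstrap) and fits one base
learner per subset; prediction is the mean positive-class probability
(soft voting). Base learners: LightGBM (library defaults: 100 trees, 31
leaves, learning rate 0.1; `min_child_samples` relaxed to 5 for
hundreds-of-pairs training sets), kNN, MLP, logistic regression. For small
synthetic studies the pipeline uses 200 trees of 15 leaves
(`pipeline.SMALL_STUDY_GBM`), a shallower/longer schedule that overfits
less at a few hundred training pairs. Thresholded metrics use 0.5 on the
averaged probability.

Evaluation is repeated stratified k-fold cross-validation (defaults: 5
folds; the protocol of record uses 100 repeats, library default here is 10
for interactive use). Per repeat, out-of-fold predictions are pooled and
AUROC/AUPR/precision/recall/F1 computed once; the report carries mean and
sample standard deviation (ddof = 1) across repeats. Ranking of undetected
pairs sorts by score, ties broken lexicographically by (miRNA, disease)
ids, with global top-N and per-disease top-N modes.

## Label-noise experiments

`inject_label_noise` builds matched arms from positive/negative pools: the
clean arm takes n per class; the noisy arm flips `n_flip` of those
positives to negative labels, drops `n_flip` original negatives and
promotes `n_flip` reserve positives, so both arms stay balanced at the same
size and differ only by the mislabelled points. The standard design uses
200 per class with 7 flips (3.5% contamination, matching the estimated
catalogue noise rate's order of magnitude).

The smoothing comparison trains the S = 10 ensemble and a single model of
the same kind on the noisy arm's stratified 70/30 split and compares test
AUROC. The MLP used here (`NOISE_EXPERIMENT_MLP_PARAMS`: one hidden layer
of 32, 60 iterations, initial learning rate 0.05) is deliberately lightly
trained and high-variance — subsample averaging is a variance-reduction
device, and a converged low-variance learner leaves it little to remove.
kNN uses its default 5 neighbours. Across 30 seeds the ensemble improves
mean test AUROC for both kinds and does not increase the across-seed
spread.

## Synthetic data

* **Associations** (`make_associations`): miRNAs and diseases receive
  latent vectors `u, v ~ N(0, scale²·I_r)` (r = 4), each scaled by a
  lognormal(0, 1) per-entity multiplier to produce the heavy-tailed degree
  distribution real catalogues show; association probability is
  `logistic(u·v/√r + bias)` with the bias solved by bisection to hit the
  target density. Defaults (50 × 40, density 0.25, scale 4.0) give each
  miRNA ~8–10 visible associations, matching the real per-miRNA average
  (~11) at the scaled-down size. A `hidden_positive_fraction` (default
  0.3) of true positives is demoted to undetected status and returned as
  ground truth.
* **Disease hierarchy** (`make_correlated_tree`): recursive k-means on the
  disease latents; each cluster's medoid owns the internal heading and the
  rest descend below it, so prefix chains are closed and hierarchy
  proximity tracks latent similarity — the coupling that makes semantic
  features informative, as real disease vocabularies exhibit (related
  diseases share both headings and miRNA programmes). `make_tree_table`
  generates structure-only random hierarchies for fixtures where no
  coupling is wanted.
* **Blobs** (`make_blobs`): two spherical Gaussian classes whose means
  differ by a vector of norm `separation` (default 3.0) in 10 dimensions
  with unit noise; the optimal linear AUROC is Φ(separation/√2) ≈ 0.983,
  placing the noise-free logistic-regression arm in the ≥ 0.97 regime the
  label-flip design assumes.

What the generator does *not* emulate: real identifier vocabularies, the
exact degree distribution or hierarchy topology of any real catalogue,
biased (non-uniform) discovery of hidden positives, or disease-specific
annotation depth. Passing tests therefore demonstrate that the machinery
recovers planted latent structure under realistic scale and noise — not
performance on any real catalogue.

## Problem sizes and numerical choices

Study sizes used by the test suite and the acceptance script: 50 random
DAGs (≤ 12 vertices) against a path-enumeration oracle at 1e-12; 50 random
association matrices against a double-loop GIP oracle at 1e-12; 30 seeds
for the label-flip and smoothing experiments (200/200 blobs, 7 flips); 10
seeds of 50 × 40 matrices for end-to-end recovery; 20 fresh label
permutations for the cross-validation null. Serialized matrices carry 17
significant digits for lossless round trips; symmetry is enforced at
1e-12. Identifiers are compared case-insensitively after trimming, with
first-appearance casing preserved. All randomness flows through explicit
integer seeds; k-means and fold shuffles derive per-repeat seeds
deterministically.

## Known limitations

* The semantic-value model pair can score a ubiquitous root's
  self-similarity below 1 (see above); no correction is applied.
* Full-mode GIP leaks held-out associations into features; it remains the
  default for comparability with the method family, and fold-safe mode
  quantifies the effect.
* Equal-quota cluster sampling is a spreading device, not a guaranteed
  noise reducer (measure with `cluster_noise_profile`).
* The 23-cluster and S = 10 defaults are inherited/conventional, not tuned
  here; both are exposed as parameters.
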