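# Methods

## Model and assumptions

`sidefx` casts side-effect prediction as a set of independent per-side-effect
binary classification problems in a positive–unlabeled (PU) setting. Two
symmetric assumptions drive it: similar drugs tend to share side-effects
(the basis of similarity-vector featurization), and dissimilar drugs tend
not to (the basis of reliable negative selection). Neither is a causal
claim; both are statistical regularities of curated pharmacovigilance data,
and the method stands or falls with them.

### Similarity channels

All four channels produce scores in [0, 1] for a drug pair:

* **chem** — Tanimoto coefficient over binary fingerprints. Any fixed-length
  bit representation is accepted; fingerprints from different toolkits are
  not bit-compatible, so one backend must be used per dataset. Precomputed
  bit tables are the reference input; an RDKit adapter
  (`fingerprints_from_smiles`) is provided for convenience.
* **tar** — proteins are compared by the Jaccard overlap of their GO term
  sets (all three ontologies pooled, terms treated as opaque strings —
  no ancestor expansion; supplying pre-expanded sets is the caller's
  prerogative and needs no special hook). Drug-level similarity is the mean
  over all cross pairs of the two drugs' target sets. A protein with zero
  GO terms contributes 0 to every pair that includes it.
* **sub**, **thera** — set Jaccard over substituents, and the mean over the
  five WHO ATC levels of the Jaccard of level-prefix sets (prefix lengths
  1, 3, 4, 5, 7 characters). Multi-code drugs are handled by taking Jaccard
  over prefix *sets*, which reduces to prefix equality for single codes.

Conventions: both-empty-set similarity and all-zero-fingerprint Tanimoto
are 0 ("no evidence" is not "identical"); diagonal self-similarity is fixed
at 1 regardless of channel arithmetic, which also keeps feature vectors
free of 0/0 artifacts.

### Consensus integration

`S_com` fuses the enabled channels by maximum, arithmetic mean or geometric
mean. Mean and geometric mean divide (or take the root) by the number of
*enabled* channels, so two-channel configurations (e.g. chem+tar) are
well-defined. Maximum is the default: it is the most permissive consensus
(a pair similar on any one channel counts as similar) and performs best for
negative selection, where missing a single strong similarity is the costly
error. For any fixed pair, max ≥ mean ≥ geometric mean (AM–GM), which is
asserted as a property.

### Negative selection

For side-effect *se* with positive set of size N, each candidate (unlabeled)
drug receives the raw accumulative score Σ_j S_com(c, d_p,j). Candidates are
ranked ascending by (score, drug id) — the id tie-break makes selection
deterministic and invariant to input order — and the n lowest become the
reliable negatives. Selection is count-driven (n is supplied by the balanced
training-set builder) rather than threshold-driven; a per-positive-count
normalized score is exposed for reporting but never used for ranking, since
dividing by the constant N cannot change a within-side-effect ordering.
The random baseline draws n candidates uniformly without replacement from
one independent substream per (side-effect, repeat).

### Featurization and classifiers

Each drug is the row of S_com over all D drugs. The similarity matrix is
computed once over the full drug set, including drugs that later fall into
test folds. This is deliberate and matches standard practice for
similarity-vector methods: the channels derive from chemistry and
annotations, never from the side-effect labels under prediction, so the
labels being predicted cannot leak through the features.

* **KNN** (native): Euclidean distance on feature vectors (the conventional
  metric for vectorized KNN; exposed via the spec of the classifier),
  effective k′ = min(k, training size), score = positive fraction among the
  k′ nearest with (distance, drug id) tie-breaking, label at score ≥ 0.5.
* **ELM** (native): hidden weights/biases uniform on [−1, 1] from the given
  seed, sigmoid activation, output weights by minimum-norm least squares
  against ±1 targets; label at raw margin ≥ 0. With hidden units ≥ training
  size and distinct inputs the least-squares fit interpolates (zero training
  error), which is checked on toy sets.
* **SVM / RBF network** (backends): pluggable registry keyed by classifier
  kind; registered defaults are scikit-learn's `SVC` (RBF kernel) and an
  exact Gaussian RBF network (one unit per training point with radial basis
  exp(−(d/spread)²), least-squares output weights). Backends must be
  deterministic given the seed and return confidence-monotone scores.

Default hyperparameters — KNN k = 50, ELM sigmoid with 150 hidden units,
SVM gamma = 0.07, RBF spread = 500 — are the tuned operating points for
this prediction task at realistic scale (~917 drugs).

### Training sets and evaluation

Balanced mode takes n_s = min(#labeled, #unlabeled) drugs per class:
positives are a seeded uniform subsample when the labeled side is larger,
negatives the first n_s of the gold-standard ranking (or random draw).
Unbalanced mode uses everything as-is. Evaluation is stratified 5-fold CV
over the gold standard (positives + selected negatives): folds are dealt
round-robin after seeded within-class shuffles, so fold sizes and per-fold
positive counts each deviate from proportionality by at most one. Fold
predictions are pooled into a single confusion table per side-effect before
computing precision/recall/F1 (pooling, not fold-averaging). Undefined
ratios (0/0) are reported as 0. Macro metrics are unweighted means across
side-effects; note Macro-F1 is the mean of per-side-effect F1 values, not
the F1 of the macro precision and recall. Stochastic situations re-randomize
both the negative draw and the CV folds per repeat and report metric means
with per-repeat values retained.

## Synthetic benchmark

The generator plants the assumed structure explicitly. Parameters, with
defaults:

| parameter | default | meaning |
| --- | --- | --- |
| n_drugs / n_clusters | 200 / 8 | cluster size 25; round-robin assignment |
| n_side_effects | 30 | round-robin over clusters |
| fingerprint_length | 1024 (256 in `benchmark_config`) | bits per drug |
| bit_flip_prob θ | 0.1 | per-bit noise against the cluster prototype |
| go_pool_size / go_terms_per_protein / targets_per_drug | 160 / 6 / 3 | disjoint per-cluster GO subpools; 12 proteins per cluster |
| substituent_pool_size / substituents_per_drug | 80 / 5 | disjoint per-cluster subpools |
| atc_branching | 3 | options per deeper ATC level; level 1 is the cluster letter |
| p_in / p_out | 0.7 / 0.05 | P(drug causes in-/out-of-cluster side-effect) |
| mask_fraction μ | 0.2 | fraction of true positives hidden from the pipeline |

These defaults put ~26 true positives on each side-effect, strong but noisy
within-cluster similarity on every channel, and near-zero between-cluster
similarity apart from the Tanimoto baseline (~1/3 for independent
half-density fingerprints) — enough signal for a clear reliable-vs-random
separation while remaining a seconds-scale computation. Masking is uniform
over positive cells (exactly round(μ·positives) cells); per-drug masking
schemes are out of scope.

What the generator does **not** emulate: real chemistry (fingerprints are
abstract bit vectors, no valid SMILES), the long-tailed empirical frequency
distribution of side-effects, correlated annotation noise, or overlap
between cluster vocabularies. Passing tests on this benchmark therefore
demonstrate that the machinery exploits similarity structure when present
at known strength — not that comparable F1 values will be reached on real
pharmacovigilance data, where the structure is weaker and channel-dependent.

### The end-to-end benchmark size

Classifier comparisons use a 400-drug variant (`e2e_benchmark_config`,
cluster size 50, all other parameters unchanged). The reason is a regime
constraint, derivable before running anything: with k′ = min(k, training
size), KNN at the default k = 50 needs 5-fold training sets larger than 50
drugs, i.e. roughly n_s > 31 and hence ≥ ~40 positives per side-effect.
At 200 drugs (~21 positives per side-effect) the vote spans the entire
training set, every prediction collapses to the training-set majority, and
any comparison between negative-selection strategies is vacuous — the
measured gap is identically zero. The realistic task sits far inside the
safe regime (~157 positive drugs per side-effect on average), so the
400-drug variant is the smallest benchmark that preserves the operating
regime of the method being compared. Selection-purity measurements involve
no classifier and use the 200-drug default unchanged.

## Numerical choices

* All-pairs channel matrices are computed by incidence-matrix algebra
  (intersections as Gram matrices); symmetry is enforced exactly by
  averaging with the transpose, values clipped to [0, 1], diagonal set to 1.
  Matrices are dense float64 (~8 MB at D ≈ 1000).
* Ties: ascending (score, drug id) in negative selection; (distance, drug
  id) in KNN; descending (score, drug id) in prediction ranking. KNN
  distances are compared after rounding squared distances at 1e−12 so that
  bitwise-equal points tie regardless of summation order.
* Every stochastic stage draws from a named substream of the master seed
  (SHA-256 of the stage name into a `SeedSequence` spawn key), so adding a
  stage never perturbs another stage's stream and all artifacts are
  byte-reproducible from one integer.
* Degenerate cases: empty similarity-score sets, zero-target drugs, and
  oversize selection requests raise informative errors; 0/0 metric ratios
  return 0 and remain visible in the per-side-effect report; ELM
  least-squares uses the pseudo-inverse path, so rank-deficient hidden
  matrices cannot crash the fit.

## Design choices on open points

* GO annotation sets are used as given; semantic (information-content or
  graph) similarity is out of scope by design.
* Negative selection and featurization share one configured integration
  method (maximum by default) rather than fixing selection to maximum
  independently; the two uses are conceptually the same quantity.
* KNN operates on similarity feature vectors; using the similarity matrix
  directly as an affinity (1 − S as distance) is a documented alternative
  the code does not implement.
* Positive subsampling (when labeled drugs outnumber unlabeled) is uniform
  and seeded; no informativeness weighting.
* `min_positives` defaults to 1: any side-effect with at least one known
  causer is kept.

## Known limitations

Per-side-effect classifiers ignore correlations between side-effects; the
feature dimension grows with the drug panel (D-vectors), so transferring a
trained model to a new panel requires recomputing similarities; evaluation
on gold standards containing *selected* negatives measures separability
from those negatives, not calibrated real-world precision; and the reliable
negative selection inherits any systematic bias of the similarity channels
(e.g. therapeutically novel drugs are dissimilar to everything and thus
overrepresented among "reliable" negatives).
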