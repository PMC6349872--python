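# Methods

## Encodings

A cDNA sequence of length N over {A,C,G,T} (IUPAC ambiguity codes allowed)
is mapped to numeric features per window size k:

**Contiguous k-mer (CkM).** `f_i` is the count of sliding windows equal to
the i-th k-mer divided by the number of *valid* windows, a valid window
containing only A/C/G/T. Windows with ambiguous bases are excluded from both
numerator and denominator, so sequences with scattered Ns remain encodable
at prediction time; a sequence with no valid window for some k fails to
encode and is reported by id. Each k-block therefore sums to exactly 1.
Feature order is fixed — lexicographic k-mers with A<C<G<T inside each
block, blocks in ascending k — so matrices and serialized models are
portable. For k = 1..4 the vector has 340 components.

**Pseudo k-mer (PkM).** The CkM block is extended with d tier-correlation
terms. The j-th tier correlation

    ρ_j = (1/(N−j−k+1)) Σ_{i} [p(w_i) − p(w_{i+j})]² ,  1 ≤ j < N−k,

where `p(w)` is the *global* normalized frequency of the k-mer occupying
window w. Position pairs where either window is invalid are skipped and the
divisor reduced accordingly. The block `(f_1..f_{4^k}, w·ρ_1..w·ρ_d)` is
divided by `D = Σ f_i + w Σ_{j≤d} ρ_j`, so each per-k block of 4^k + d
entries sums to 1; with d = 1, k = 1..4 the vector has 344 components.
Interpretation notes: the correlation sum in the denominator runs over the
d defined tiers (the standard pseudo-composition form, and the only reading
under which blocks normalize); `p(·)` is read as a data-dependent global
proportion — a positional indicator reading would make ρ_j independent of
the sequence. The weight w has no canonical value; the default 0.1 follows
common pseudo-composition practice, and the headline CkM configuration does
not use it. ρ_j of any homopolymer is 0, so PkM degenerates to pure
composition there; w = 0 reproduces CkM exactly in the composition entries.

## Classifier

Binary classification is a soft-margin SVM; the dual QP (0 ≤ α_i ≤ C,
Σ α_i y_i = 0) is solved by libsvm via scikit-learn, but the fitted state —
support vectors, α_i y_i, bias b — is held in-package and decision values
are recomputed from the kernel expansion with our own kernel functions
(linear x·y, polynomial (γx·y + r)^d, RBF exp(−γ‖x−y‖²), sigmoid
tanh(γx·y + r)). Defaults: C = 1, r = 0, degree 3, γ = 1/dimension (0.0029
for the 340-feature CkM set), recomputed per feature matrix. A decision
value of exactly 0 goes to the positive class (pinned in tests); the
positive class defaults to the lexicographically larger label and is
`resistant` in the gate.

**Standardization.** Feature columns are standardized to zero mean and unit
variance on the training set by default, with the transform stored in the
model and applied to queries. This matters: block-normalized frequency
vectors are nearly identical in Euclidean norm, so at γ = 1/dimension an
unstandardized RBF kernel is numerically constant and small training sets
collapse to majority-class prediction. Standardization is the convention of
the classical libsvm front ends under which the γ = 1/dimension default is
meaningful; it can be disabled (`standardize=False`), which the kernel-math
property tests use.

**Tuning.** `tune_rbf` grid-searches C ∈ {2⁻⁵…2¹⁵} and γ ∈ {2⁻¹⁵…2⁻⁵}
(multiplicative step 2) by stratified k-fold CV accuracy, ties broken toward
smaller C then smaller γ. Defaults are used unless tuning is explicitly
invoked.

**Multi-class.** One-vs-one: m(m−1)/2 pairwise SVMs, majority voting, ties
broken by summed decision-value magnitude then class name. Class
probabilities couple the Platt-calibrated pairwise probabilities with the
iterative least-squares scheme used in libsvm (pairwise probabilities
clipped to [1e−7, 1−1e−7] for stability); they always sum to 1.

**Calibration.** A Platt sigmoid `P(+|f) = 1/(1+exp(Af+B))` is fitted on the
training-set decision values with Platt's smoothed targets, A bounded ≤ 0 so
the map is monotone by construction. No resampling is involved, so
calibration is deterministic; on separable training sets the sigmoid is
steep and probabilities are confident, which is acceptable for ranking and
argmax use but means probabilities near 0/1 should not be over-interpreted.

## Two-stage prediction

Stage 1 (binary gate, trained on balanced resistant/non-resistant data)
decides resistant vs non-resistant; sequences predicted non-resistant are
final and never reach stage 2. Stage 2 (7-class one-vs-one model) assigns
the argmax class among ACCase, ALS, EPSPS, GS, HPPD, PDS, PPO. The reported
probability is that of the assigned class at the assigning stage — the two
stages' probabilities are never blended. Unencodable queries yield a row
flagged `failed` instead of aborting the batch. The single-stage 8-class
model (28 pairwise SVMs) is the comparison baseline.

## Validation protocols and metrics

* Sen, Spe, Acc, Pre, MCC from confusion counts; any zero-denominator
  metric is reported as undefined (None), never silently 0.
* Two accuracy notions are kept distinct: *pooled* accuracy (tp+tn)/n and
  *balanced overall* accuracy (mean of per-class recalls), the latter used
  for class-imbalanced independent sets. On the independent set the
  resistant recall pools the seven classes: a resistant sequence counts as
  recovered only if assigned its own class.
* ROC: thresholds swept over distinct scores, prediction positive iff
  score ≥ threshold, (0,0) and (1,1) anchored; trapezoidal AUC, which
  equals tie-corrected Mann–Whitney concordance (tested to 1e−12).
  PR: step-wise average precision over the recall axis (the precision/recall
  axis order in plots is presentational, not an integration order).
* Stratified 5-fold CV with class-balanced folds; each item tested exactly
  once; pooled-confusion metrics plus per-fold metrics.
* Bootstrap balanced CV: draw `per_class_n` (default 120) from each class
  pool without replacement, run k-fold CV, repeat `n_bootstrap` (default
  100) times; report mean ± SE over sets (SE over sets, not over the 5×
  folds). A pure function of (pools, config, seed).
* Jackknife: n leave-one-out fits of the full one-vs-one model; equivalent
  to a naive LOO loop (tested against an independent implementation).

## Synthetic benchmark

Each class is an order-2 Markov chain over {A,C,G,T}; class transition rows
are the convex mixture `(1−δ)·base + δ·class-specific rows`, class rows
drawn from a flat Dirichlet (symmetric across classes, seeded), the base
mildly AT-rich. δ = 0 makes classes indistinguishable (null); larger δ
separates their k-mer compositions, which is exactly the signal axis the
encodings measure. Order 2 is the default so tri- and tetra-mer features
carry information beyond mononucleotide composition. Default shapes mirror
the study datasets: 120+120 balanced binary set; 7-class set of
{36,37,29,25,18,18,20} = 183; independent set of 44 resistant
({9,9,7,6,4,4,5} per class) + 1324 non-resistant; pools of 122/1444 for
bootstrap draws. Lengths are uniform on [300, 900] (cDNA-scale, and ≥ 4·k_max
so every sequence encodes). Everything is deterministic given (parameters,
seed).

What the benchmark does *not* emulate: real GETS homology and phylogenetic
correlation between sequences, codon structure, indel/mutation processes,
and the heterogeneous length and quality of database cDNAs. Passing the
null/signal tests shows the pipeline recovers compositional class structure
when present and finds none when absent; it does not certify accuracy on
real weed-gene data.

## Problem sizes and numerical choices

The test suite and acceptance script run the bootstrap protocol at 20
bootstrap sets (the protocol's set and fold shapes unchanged); the null run
uses pools of 150/300 and the signal runs δ = 0.8 (benchmark recovery) and
δ = 0.9 (end-to-end two-stage example). Pairwise identity defaults to
global alignment with match +1, mismatch 0, zero gap penalty — under which
identical aligned columns / shorter length is exactly the
longest-common-subsequence ratio, a tie-free quantity; a negative gap
penalty is available for stricter alignments. The greedy redundancy filter
visits records longest-first (ties by id) and is deterministic and
idempotent; it is a simplified stand-in for CD-HIT clustering, not a
replica. Encoder tolerances: block sums asserted to 1e−9; KKT invariants to
1e−6; coupled probabilities to 1e−9.

## Known limitations

* Probabilities are calibrated on training decisions without held-out
  splits; with strongly separable training data they saturate.
* The per-class training subsets of the published single-stage comparison
  are not reconstructible from the printed material; `train_single_stage`
  accepts arbitrary per-class sets and does not guess a selection rule.
* No sequence-intrinsic filter for partial-CDS entries is implemented (no
  such rule is definable without annotation).
* O(n²) pairwise identity in the redundancy filter is fine for hundreds of
  sequences but not for large databases.
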