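# Methods

## Model and procedure

`enhancerkit` treats enhancer identification as two nested binary
classification problems on fixed-length DNA fragments: layer I separates
enhancers (strong ∪ weak) from non-enhancers, layer II separates strong
from weak enhancers among predicted positives. Each layer owns its
feature set, its bi-profile Bayes (BPB) model and its SVM, because the
sequence signals that identify an enhancer are not the ones that grade
its strength.

### Encoders

*BPB.* For each class (positive, negative) a 4×n matrix of per-position
base frequencies is estimated from the training sequences; the encoder
maps a sequence to 2n values — at each position, the frequency of its
observed base in the positive profile, then in the negative profile.
The frequency is used as the posterior-probability estimate directly;
an optional additive-smoothing pseudocount α (default 0) is exposed
because singleton or tiny classes otherwise produce many exact zeros,
but with realistic class sizes raw frequencies are the estimator.

*NC.* Normalised mononucleotide frequencies, fixed order (A, T, G, C).

*PseNC.* Overlapping trinucleotide frequencies: counts over the n−2
sliding windows divided by n−2, in lexicographic order AAA…TTT, so the
64-vector sums to 1. Overlapping counts with denominator n−2 are the
standard k-mer-frequency reading of 3-mer composition.

With n = 200 the three families give 400 + 4 + 64 = 468 features. (The
originating publication states a total of 472 in passing; its per-family
definitions sum to 468, and this package follows the definitions.)

*Ambiguity policy.* Non-ACGT symbols are rejected by default. An opt-in
`mask` mode replaces them with N; masked positions contribute to no
mono-/trinucleotide count or profile denominator, and BPB lookups at
masked positions return the uniform value 0.25 (uninformative rather
than zero). Case is folded on read.

### F-score and wrapper selection

The per-feature F-score is the ratio of between-class mean separation to
pooled within-class scatter (unbiased per-class variances, 1/(n±−1)).
Degenerate features are scored deterministically: zero scatter with
separated means → +inf sentinel (ranked first); zero scatter and zero
separation → 0. Ties rank by ascending original feature index.

Selection is a wrapper around jackknife accuracy of the downstream SVM,
in five stages: BPB coarse threshold scan (default step Δw₁ = 0.001),
BPB fine dimension scan (step Δw₂ = 2, over a window of ±10 dimensions
around the coarse optimum), greedy add-one over NC candidates (strict
improvement required, up to 4 trials), PseNC coarse threshold scan
(Δw₃ = 0.01) and PseNC fine dimension scan (Δw₄ = 2), with the PseNC
candidates always evaluated on top of the set selected so far. Accuracy
alone drives every decision; Sn/Sp/MCC are logged in the trajectory.
Ties resolve toward fewer features (larger threshold, smaller
dimension). A stage's outcome is kept only if it does not lose accuracy,
which makes the stage-to-stage accuracy trajectory monotone by
construction — the property the acceptance checks exercise.

Scan evaluations are memoised on the retained feature set, so adjacent
thresholds that select identical sets cost one evaluation; the
fixed-matrix jackknife evaluator precomputes the RBF Gram matrix once
per candidate set and solves each fold on a submatrix.

The selection wrapper evaluates candidate sets by jackknife over a
feature matrix whose BPB model is fitted once on the full layer
(matching the published protocol). The resulting selection-level
optimism is documented below; the unbiased alternative is to re-run the
whole selection inside an outer CV, which the evaluator interface
permits but which is not the reproduction default.

### SVM

RBF-kernel SVC (scikit-learn). Defaults are the published operating
points: C = 0.35355 (= 2^−1.5) for both layers, γ = 0.03125 (= 2^−5) for
layer I, γ = 1.4142 (= 2^0.5) for layer II. The grid search scans the
conventional powers-of-two lattice (exponents −8…8, step 0.5) with
seeded stratified cross-validation (default 15-fold); ties prefer
smaller C, then smaller γ. No feature scaling by default — all three
families are frequencies in [0, 1]; an optional per-feature min–max
rescale exists for user-supplied features. Class weighting is off
(the benchmark geometry is balanced per layer). Predictions use the
sign of the decision value; no probability calibration.

### Evaluation

Jackknife (leave-one-out) is the reference protocol: it yields a unique
result per dataset. Two modes:

* `leakage_free` (default): the BPB profiles are re-estimated in every
  fold from the n−1 training sequences (implemented as count
  subtraction, so the refit is exact and cheap). The held-out sequence
  never touches its own features.
* `paper_literal`: profiles fitted once on all sequences, reproducing
  the published protocol. Because each sequence contributes to its own
  class profile at every position, this leaks; on effect-0 synthetic
  data (exchangeable classes) the measured leakage is large (LOO
  accuracy ≈ 0.8 vs ≈ 0.5 leakage-free at 100 sequences/class — the
  per-sequence contribution is 1/n⁺ per position, aggregated over all
  200 positions).

k-fold evaluation deals shuffled within-class indices round-robin into k
folds, so k = n reduces exactly to the jackknife, prediction by
prediction, regardless of seed. Metrics always derive from integer
confusion counts; MCC is defined as 0 when any marginal is empty, while
Sn/Sp raise rather than silently report 0 when a class is absent.
Positive-class convention: layer I positive = enhancer, layer II
positive = strong enhancer.

## Synthetic data generator

The generator emulates the statistical structure of the benchmark the
method was developed on: 200-bp fragments in classes of 742/742/1484 by
default, i.i.d. uniform A/C/G/T background, and three plantable signal
types aligned with the three feature families —

* positional base-probability boosts (1-based positions, matching the
  `BPB_pos_<i>` feature names);
* per-class mononucleotide composition shifts (the canned designs use
  +0.05 on C in enhancer classes, mirroring the C-enrichment reported
  for real enhancers);
* multiplicative trinucleotide enrichment (canned designs enrich ATA,
  TAT and GGC 2-fold, three of the 3-mers reported informative for
  enhancer identification), implemented by overwriting a
  Poisson-distributed number of random windows so that the *expected*
  3-mer count is scaled by the multiplier — expectation-level control,
  exactly seedable.

A global `effect_size` ∈ [0, 1] multiplies every planted effect; at 0
all classes are exchangeable background draws, which keeps the null
calibration analytic. Emission columns are clipped and renormalised
after boosts so they remain distributions. A truth manifest lists every
directly planted feature plus indirectly affected PseNC features (3-mers
containing a composition-shifted base).

Default signal magnitudes were fixed at design time: positional boost
0.3 (a moderate motif-like signal; boosted-base emission 0.42 vs 0.19),
with 0.5 as the "strong" regime used by the signal-recovery checks
(emission 0.50 vs 0.167). Under these settings planted BPB features
carry F-scores of order 0.02–0.08 — the same order as the informative
F-score window reported for the real benchmark — so the selection
machinery is exercised in a realistic score regime, not a caricature.

What the generator does *not* emulate: chromatin-state structure,
cell-line heterogeneity, sequence-redundancy structure, non-uniform
genomic background composition, and motif positional jitter. Passing
tests therefore demonstrate correctness and calibration of the
machinery, not expected accuracy on real enhancer data.

## Numerical and design choices

* **SVM operating point for synthetic data.** The published (C, γ) values
  were tuned on the real benchmark. On the synthetic feature matrices
  they put the SVC in the all-bounded-α regime, where leave-one-out on
  balanced classes exhibits the classic anti-learning artifact (the
  held-out sample is driven toward the opposite class by the one-sample
  imbalance; LOO accuracy can reach 0 on separable data). Synthetic
  experiments therefore use C = 2, γ = 0.5 from the same powers-of-two
  lattice, with γ chosen as ≈ 1/median pairwise squared distance of the
  encoded synthetic matrix (median ≈ 1.5–1.8) and C moderate. The
  published values remain the layer defaults for real data.
* **Problem sizes.** The bundled evaluation scripts and tests run the
  selection schedule on 200+200 sequences with coarse steps 0.005 (BPB)
  and 0.01 (PseNC), null calibration on 100+100, signal recovery on
  200+200, and the jackknife/k-fold equivalence on 30 sequences — sizes
  at which every quantity is stable across seeds while the full suite
  stays fast on a single CPU.
* **Determinism.** All randomness flows through seeded NumPy generators;
  selection, grid search, fold assignment and the generator are exactly
  reproducible. Scan ties and F-score ties have fixed deterministic
  resolutions (see above).
* **Degenerate inputs.** Empty classes, single-member classes (Sn/Sp
  undefined), non-finite features, sequences shorter than 3 bp (PseNC),
  fully masked sequences and empty family sets all raise informative
  errors rather than propagating NaNs.

## Known limitations

* The wrapper selection reports the same jackknife accuracy it
  optimises; without an outer CV that number is an optimistic estimate
  of generalisation. This is faithful to the reproduced protocol and
  documented rather than silently "fixed".
* BPB profiles assume positional independence; correlated motifs are
  only captured indirectly (and by PseNC locally).
* The two-layer cascade propagates layer-I errors into layer II by
  construction; no joint calibration is attempted.
* `paper_literal` mode exists for protocol fidelity and comparison and
  should not be used to report performance of new models.
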