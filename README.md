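# enhancerkit

Sequence-based identification of enhancers and their strength.

Enhancers are *cis*-regulatory DNA elements that boost transcription of
target genes, and they come in subgroups — strong and weak — with
different regulatory impact. `enhancerkit` implements a classical
two-layer machine-learning predictor for 200-bp DNA fragments: layer I
decides *enhancer vs non-enhancer*, and layer II, consulted only for
predicted enhancers, decides *strong vs weak*. The pipeline is built
from three sequence feature families, an F-score-driven two-step wrapper
feature selection, and RBF-kernel support vector machines, evaluated by
the jackknife (leave-one-out) test with Sn/Sp/Acc/MCC reporting.

## The method

**Feature families.** A length-n fragment (n = 200 by default) is encoded
by:

* *Bi-profile Bayes (BPB)* — 2n features. Position-specific base
  frequencies are estimated separately from the positive and negative
  training classes; a sequence becomes the probability vector
  V = (p₁ … pₙ, pₙ₊₁ … p₂ₙ), where pᵢ is the positive-class frequency of
  its observed base at position i and pₙ₊ᵢ the negative-class frequency.
* *Nucleotide composition (NC)* — 4 features, the normalised single-base
  frequencies (A, T, G, C).
* *Pseudo-nucleotide composition (PseNC)* — 64 features, the overlapping
  trinucleotide frequencies Nᵢ/(n−2) for the 3-mers AAA … TTT.

**Feature selection.** Features are ranked by the F-score

    F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] /
           [ (1/(n⁺−1)) Σₖ(x⁺ₖᵢ − x̄ᵢ⁺)² + (1/(n⁻−1)) Σₖ(x⁻ₖᵢ − x̄ᵢ⁻)² ]

and selected by a wrapper schedule driven by jackknife accuracy of the
downstream SVM: a coarse F-score-threshold scan over the BPB features
(step 0.001), a fine scan over the number of top-ranked dimensions
(step 2), a greedy add-one pass over the NC features (kept only if
accuracy strictly improves), and a coarse (step 0.01) + fine (step 2)
scan pair for the PseNC features.

**Classifier.** RBF-kernel SVMs (scikit-learn) with the published
operating points C = 0.35355, γ = 0.03125 (layer I) and C = 0.35355,
γ = 1.4142 (layer II) as defaults, plus a seeded (C, γ) grid search over
the conventional powers-of-two lattice with stratified cross-validation.

**Evaluation.** Jackknife and stratified k-fold with the metric set
Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total and the Matthews
correlation coefficient. Because the BPB features depend on training
labels, the default `leakage_free` mode refits the BPB profiles inside
every fold; the `paper_literal` mode (profiles fitted once on all data)
is provided for reproducing the published protocol and is measurably
optimistic on null data.

**Synthetic data.** The original benchmark (742 strong enhancers, 742
weak enhancers, 1484 non-enhancers from nine ENCODE cell lines) is
external data and is not bundled. A seeded generator emulates its
statistical structure — class-specific positional base biases,
composition shifts (e.g. C-enrichment in enhancers) and trinucleotide
enrichment — with a global `effect_size` dial so every pipeline stage is
testable from scratch.

## Worked example

```python
import enhancerkit as ek

spec = ek.two_class_spec(n_per_class=100, n=100, effect_size=1.0, seed=3)
dataset = ek.generate(spec)
config = ek.SelectionConfig(svm=ek.SvmConfig(C=2.0, gamma=0.5),
                            bpb_coarse_step=0.01, psenc_coarse_step=0.02)
result = ek.run_full_selection(dataset, "I", config)
for name, stage in result.stages.items():
    print(f"{name:>14}: Acc {stage.best_acc:.4f} ({len(stage.selected)} features)")
```

prints

```
    bpb_coarse: Acc 0.7750 (64 features)
      bpb_fine: Acc 0.7900 (54 features)
     nc_greedy: Acc 0.7900 (54 features)
  psenc_coarse: Acc 0.8100 (58 features)
    psenc_fine: Acc 0.8100 (59 features)
```

Each row is one stage of the wrapper schedule: the coarse BPB threshold
scan finds a 64-feature set at jackknife Acc 0.775; the fine dimension
scan trims it to 54 features and 0.790; the greedy NC pass accepts
nothing (no strict improvement); and the PseNC scans add five 3-mer
features for a final 59-feature set at Acc 0.810. Later stages only
accept changes that do not lose accuracy, so the trajectory is monotone.
The `examples/` directory holds runnable scripts for encoding, feature
selection, jackknife evaluation and the two-layer cascade; the
`enhancerkit` command exposes `simulate`, `train` and `predict` for
shell use.

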