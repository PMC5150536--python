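"""Train and apply the two-layer cascade on a three-class dataset.

Layer I separates enhancers (strong + weak) from non-enhancers; layer II
is consulted only for predicted enhancers and grades them strong vs
weak.  Each layer gets its own bi-profile Bayes model and feature set.
"""

from collections import Counter

import enhancerkit as ek
from enhancerkit.encoders import NC_FEATURE_NAMES, bpb_feature_names

spec = ek.three_class_spec(strong=60, weak=60, non=120, n=100, seed=6)
dataset = ek.generate(spec)
print(f"dataset: {dataset.class_counts}")

bpb_names = bpb_feature_names(dataset.n)
model = ek.train_two_layer(
    dataset,
    layer1_features=bpb_names + NC_FEATURE_NAMES,
    layer2_features=bpb_names,
    config1=ek.SvmConfig(C=2.0, gamma=0.5),
    config2=ek.SvmConfig(C=2.0, gamma=0.5),
)

predictions = ek.predict_two_layer(model, dataset.records)
confusion = Counter((r.label, p.label) for r, p in zip(dataset.records, predictions))
print("\ntrue -> predicted counts:")
for (true, pred), count in sorted(confusion.items()):
    print(f"  {true:>16} -> {pred:<16} {count}")
called_non = sum(1 for p in predictions if p.layer2_score is None)
print(f"\n{called_non} sequences stopped at layer I (layer II never consulted)")
# Strong/weak labels can only appear for sequences layer I called
# positive - the cascade property.
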