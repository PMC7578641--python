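"""Mine reliable negatives from the unlabeled miRNA x disease universe.

With no database of confirmed non-associations, every non-positive pair
is merely unlabeled.  The centroid/AED rule treats an unlabeled pair as a
reliable negative when its Euclidean distance to the positive-class
centroid (in the 448-dim pair feature space) exceeds a multiple of the
average such distance (AED); the published threshold is 1.5 x AED.
"""

from seqsymrf import (
    FixtureConfig,
    build_pairs,
    feature_table,
    make_associations,
    make_hairpins,
    make_symptom_network,
    positive_centroid,
    select_reliable_negatives,
    vectors_to_frame,
)

config = FixtureConfig(n_mirnas=120, n_diseases=24, n_positive_pairs=250,
                       seed=7)
hairpins = make_hairpins(config)
vocab, vectors = make_symptom_network(config)
mirna_features = feature_table(hairpins)
disease_features = vectors_to_frame(vocab, vectors)

raw = make_associations(config, list(mirna_features.index),
                        list(disease_features.index))
positives, universe = build_pairs(
    list(mirna_features.index), list(disease_features.index), raw
)
print(f"{len(positives)} positives; unlabeled universe of {len(universe)} "
      f"pairs ({config.n_mirnas} x {config.n_diseases} - {len(positives)})")

centroid = positive_centroid(positives, mirna_features, disease_features)
for multiplier in (0.8, 1.0, 1.5):
    result = select_reliable_negatives(
        universe, mirna_features, disease_features, centroid,
        multiplier=multiplier,
    )
    share = 100 * len(result.candidates) / len(universe)
    print(f"  multiplier {multiplier:3.1f}: AED {result.aed:7.2f}, "
          f"threshold {result.threshold:7.2f}, "
          f"{len(result.candidates):5d} candidates ({share:4.1f}% of universe)")

# Raising the multiplier keeps only pairs ever farther from the positive
# centroid: fewer, but more confidently negative.  Every selected pair's
# distance strictly exceeds multiplier * AED.
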