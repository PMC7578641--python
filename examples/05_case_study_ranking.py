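"""Leave-disease-out candidate ranking (the case-study protocol).

Every association involving the query disease is removed, the forest is
retrained from scratch on the remaining positives with freshly mined
negatives, and all miRNAs are scored against the query.  On the synthetic
corpus the query's planted cluster partners should crowd the top of the
list.
"""

from seqsymrf import (
    FixtureConfig,
    build_pairs,
    feature_table,
    make_associations,
    make_hairpins,
    make_symptom_network,
    rank_candidates,
    vectors_to_frame,
)
from seqsymrf.synthetic import disease_cluster, mirna_cluster

config = FixtureConfig(seed=5)
hairpins = make_hairpins(config)
vocab, vectors = make_symptom_network(config)
mirna_features = feature_table(hairpins)
disease_features = vectors_to_frame(vocab, vectors)
raw = make_associations(config, list(mirna_features.index),
                        list(disease_features.index))
positives, _ = build_pairs(
    list(mirna_features.index), list(disease_features.index), raw
)

query = positives[0][1]
query_cluster = disease_cluster(list(disease_features.index).index(query),
                                config)
print(f"query disease: {query} (planted cluster {query_cluster})")

ranked = rank_candidates(
    query, "disease", positives, mirna_features, disease_features,
    multiplier=1.0, trees=100, seed=5, top=15,
)

mirna_ids = list(mirna_features.index)
print("\ntop 15 candidate miRNAs:")
hits = 0
for rank, (candidate, score) in enumerate(ranked, start=1):
    cluster = mirna_cluster(mirna_ids.index(candidate), config)
    mark = "*" if cluster == query_cluster else " "
    hits += cluster == query_cluster
    print(f"  {rank:2d}. {candidate}  score {score:.3f}  cluster {cluster} {mark}")
print(f"\n{hits}/15 top candidates come from the query's planted cluster "
      f"(* marks a true planted partner).")
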