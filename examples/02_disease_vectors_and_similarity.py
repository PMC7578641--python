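"""Score diseases by their clinical symptoms and compare them.

Disease vectors use TF-IDF with term frequency replaced by the absolute
disease-symptom co-occurrence: score(d, s) = C(d, s) * ln(N / n_s).
Disease-disease similarity is the Jaccard coefficient on symptom supports.
"""

import pandas as pd

from seqsymrf import jaccard_similarity, tfidf_scores
from seqsymrf.similarity import histogram, pair_similarity

# raw co-occurrence counts: 4 diseases x 5 symptoms
counts = pd.DataFrame(
    {
        "cough":    [8, 5, 0, 0],
        "fever":    [3, 2, 1, 0],
        "nausea":   [0, 1, 6, 4],
        "vomiting": [0, 0, 4, 7],
        "fatigue":  [1, 1, 1, 1],   # ubiquitous -> idf = ln(1) = 0
    },
    index=["flu", "cold", "gastritis", "food_poisoning"],
)

vocab, vectors = tfidf_scores(counts)
by_id = {v.disease_id: v for v in vectors}

print("TF-IDF score vectors (symptom order:", ", ".join(vocab.symptoms), ")")
for v in vectors:
    print(f"  {v.disease_id:15s}", [round(s, 2) for s in v.scores])

print("\npairwise Jaccard similarity of symptom supports:")
names = list(by_id)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        print(f"  {a:15s} vs {b:15s} {jaccard_similarity(by_id[a], by_id[b]):.2f}")

# An association-pair similarity (mDPS) averages a miRNA similarity and a
# disease similarity; 0.5 here means 'half-way related on both axes'.
print(f"\nmDPS(Sm=0.6, Sd=0.4) = {pair_similarity(0.6, 0.4):.2f}")

sims = [jaccard_similarity(by_id[a], by_id[b])
        for i, a in enumerate(names) for b in names[i + 1:]]
h = histogram(sims)
print("similarity histogram proportions (10 bins on [0,1]):",
      [round(p, 2) for p in h.proportions])
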