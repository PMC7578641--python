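"""Disease characterisation by clinical-symptom score vectors.

Each disease is a nonnegative vector over a frozen symptom vocabulary;
scores come either from a precomputed disease-symptom TSV (as published in
the human symptom-disease network) or from raw co-occurrence counts via
TF-IDF with term frequency replaced by the absolute co-occurrence:

    score(d, s) = C(d, s) * ln(N / n_s)

with N the number of diseases and n_s the number of diseases co-occurring
with symptom s.  Disease-disease similarity is the Jaccard coefficient on
symptom support sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SymptomVocabulary",
    "DiseaseVector",
    "read_symptom_scores",
    "write_symptom_scores",
    "tfidf_scores",
    "jaccard_similarity",
    "vectors_to_frame",
]


@dataclass(frozen=True)
class SymptomVocabulary:
    """Ordered, duplicate-free symptom names; order frozen at construction."""

    symptoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symptoms)) != len(self.symptoms):
            raise ValueError("duplicate symptom names in vocabulary")

    @property
    def size(self) -> int:
        return len(self.symptoms)


@dataclass(frozen=True)
class DiseaseVector:
    disease_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scores) < 0):
            raise ValueError(f"disease {self.disease_id!r}: negative score")

    def support(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(np.asarray(self.scores) > 0).tolist())


def read_symptom_scores(
    path: str | Path,
) -> tuple[SymptomVocabulary, list[DiseaseVector]]:
    """Read a disease / symptom / score TSV (no header).

    The vocabulary is the sorted set of symptoms seen; missing
    (disease, symptom) entries score 0.  Negative scores and duplicate
    (disease, symptom) rows are validation errors naming the row.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["disease", "symptom", "score"],
            dtype={"disease": str, "symptom": str},
        )
    except pd.errors.EmptyDataError:
        return SymptomVocabulary(symptoms=()), []
    if df.empty:
        return SymptomVocabulary(symptoms=()), []
    neg = df.index[df["score"] < 0]
    if len(neg):
        raise ValueError(f"negative score at row {neg[0] + 1}")
    dup = df.duplicated(subset=["disease", "symptom"])
    if dup.any():
        raise ValueError(
            f"duplicate (disease, symptom) entry at row {int(np.flatnonzero(dup)[0]) + 1}"
        )
    wide = (
        df.pivot(index="disease", columns="symptom", values="score")
        .fillna(0.0)
        .sort_index(axis=1)
    )
    vocab = SymptomVocabulary(symptoms=tuple(wide.columns))
    vectors = [
        DiseaseVector(disease_id=str(d), scores=wide.loc[d].to_numpy(dtype=float))
        for d in wide.index
    ]
    return vocab, vectors


def write_symptom_scores(
    vocab: SymptomVocabulary,
    vectors: Iterable[DiseaseVector],
    path: str | Path,
) -> None:
    """Write nonzero (disease, symptom, score) rows as TSV."""
    rows = []
    for vec in vectors:
        for idx in sorted(vec.support()):
            rows.append((vec.disease_id, vocab.symptoms[idx], vec.scores[idx]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def tfidf_scores(
    cooccurrence: pd.DataFrame,
) -> tuple[SymptomVocabulary, list[DiseaseVector]]:
    """Score a diseases x symptoms co-occurrence count matrix.

    score(d, s) = C(d, s) * ln(N / n_s); symptoms occurring in every
    disease score 0 (idf = ln 1); all-zero symptom columns are dropped
    with a warning.
    """
    counts = cooccurrence.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("co-occurrence counts must be nonnegative")
    n_s = (counts > 0).sum(axis=0)
    dead = n_s == 0
    if dead.any():
        dropped = [str(c) for c in cooccurrence.columns[dead]]
        warnings.warn(
            f"dropping {len(dropped)} all-zero symptom column(s): {dropped[:5]}",
            stacklevel=2,
        )
        cooccurrence = cooccurrence.loc[:, ~dead]
        counts = counts[:, ~dead]
        n_s = n_s[~dead]
    n_diseases = counts.shape[0]
    idf = np.log(n_diseases / n_s)
    scores = counts * idf
    vocab = SymptomVocabulary(symptoms=tuple(str(c) for c in cooccurrence.columns))
    vectors = [
        DiseaseVector(disease_id=str(d), scores=scores[i])
        for i, d in enumerate(cooccurrence.index)
    ]
    return vocab, vectors


def jaccard_similarity(a: DiseaseVector, b: DiseaseVector) -> float:
    """Jaccard coefficient on symptom supports (score > 0); 0 when both
    supports are empty."""
    if len(a.scores) != len(b.scores):
        raise ValueError(
            f"vocabulary mismatch: {len(a.scores)} vs {len(b.scores)} symptoms"
        )
    sa, sb = a.support(), b.support()
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def vectors_to_frame(
    vocab: SymptomVocabulary, vectors: Iterable[DiseaseVector]
) -> pd.DataFrame:
    """Disease x symptom score matrix with ids as the index."""
    vecs = list(vectors)
    return pd.DataFrame(
        np.vstack([v.scores for v in vecs]) if vecs else np.empty((0, vocab.size)),
        index=pd.Index([v.disease_id for v in vecs], name="disease_id"),
        columns=list(vocab.symptoms),
    )
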