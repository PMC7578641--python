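"""Pairwise similarity of miRNAs, diseases and association pairs.

miRNA similarity is global-alignment identity (match +1, mismatch 0,
linear gap -1; identity = identical aligned columns / alignment length).
Disease similarity is the Jaccard coefficient on symptom supports.  A
pair-of-pairs similarity averages the two:

    mDPS(m_i-d_p, m_j-d_q) = (Sm(i, j) + Sd(p, q)) / 2

Greedy non-redundant construction removes an entity (or association)
whenever its similarity to something already retained strictly exceeds
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from Bio import Align

from .structure_io import RnaRecord

Pair = tuple[str, str]

__all__ = [
    "SimilarityHistogram",
    "mirna_similarity",
    "pair_similarity",
    "histogram",
    "nonredundant_entities",
    "nonredundant_pairs",
]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def mirna_similarity(a: RnaRecord | str, b: RnaRecord | str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with match +1 / mismatch 0 / gap -1 (the gap penalty
    shapes the alignment only); identity is the fraction of alignment
    columns whose characters agree.
    """
    sa = a.sequence if isinstance(a, RnaRecord) else a
    sb = b.sequence if isinstance(b, RnaRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be nonempty")
    alignment = _aligner().align(sa, sb)[0]
    top, bottom = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(top, bottom) if x == y and x != "-")
    return matches / len(top)


def pair_similarity(sm: float, sd: float) -> float:
    """mDPS: the mean of a miRNA similarity and a disease similarity."""
    for name, v in (("Sm", sm), ("Sd", sd)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    return (sm + sd) / 2


@dataclass(frozen=True)
class SimilarityHistogram:
    """Ten-bin histogram over [0, 1]; bins half-open, the last closed."""

    bin_edges: tuple[float, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        assert abs(sum(self.proportions) - 1) < 1e-9


def histogram(values: Sequence[float]) -> SimilarityHistogram:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot histogram an empty value set")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("similarity values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(vals, bins=edges)  # last bin closed by numpy
    return SimilarityHistogram(
        bin_edges=tuple(edges.tolist()),
        proportions=tuple((counts / vals.size).tolist()),
    )


def nonredundant_entities(
    entities: Sequence,
    pairwise_similarity: Callable,
    threshold: float,
    seed: int | None = None,
):
    """Greedy redundancy pruning: walk the entities (optionally in seeded
    shuffled order) and drop any whose similarity to an already-retained
    entity strictly exceeds the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = list(entities)
    if seed is not None:
        rng = np.random.default_rng(seed)
        items = [items[i] for i in rng.permutation(len(items))]
    retained: list = []
    for item in items:
        if all(pairwise_similarity(item, kept) <= threshold for kept in retained):
            retained.append(item)
    return retained


def nonredundant_pairs(
    positives: Sequence[Pair],
    reliable_negatives: Sequence[Pair],
    mirna_sim: Callable[[str, str], float],
    disease_sim: Callable[[str, str], float],
    threshold: float,
    seed: int = 0,
) -> tuple[list[Pair], list[Pair]]:
    """Balanced non-redundant training set at the association-pair level.

    First the positives are pruned greedily (seeded random order) so no
    two retained positives have mDPS above the threshold.  Negatives are
    then deleted one at a time: a randomly chosen negative is removed
    whenever its mDPS to any retained positive or any other remaining
    negative exceeds the threshold, and the deletion loop stops as soon
    as the negative pool size equals the positive count.  A pool that
    ends larger (nothing redundant left) is trimmed at random to 1:1;
    one that cannot reach balance raises, naming the achievable
    negative count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rng = np.random.default_rng(seed)

    def mdps(p: Pair, q: Pair) -> float:
        return pair_similarity(mirna_sim(p[0], q[0]), disease_sim(p[1], q[1]))

    pos = [positives[i] for i in rng.permutation(len(positives))]
    kept_pos: list[Pair] = []
    for p in pos:
        if all(mdps(p, q) <= threshold for q in kept_pos):
            kept_pos.append(p)

    pool = [reliable_negatives[i]
            for i in rng.permutation(len(reliable_negatives))]
    while len(pool) > len(kept_pos):
        removed = False
        for idx in rng.permutation(len(pool)):
            q = pool[idx]
            others = kept_pos + [r for j, r in enumerate(pool) if j != idx]
            if any(mdps(q, r) > threshold for r in others):
                pool.pop(int(idx))
                removed = True
                break
        if not removed:
            break
    if len(pool) > len(kept_pos):  # non-redundant pool, just oversized
        idx = rng.choice(len(pool), size=len(kept_pos), replace=False)
        pool = [pool[i] for i in sorted(idx)]
    if len(pool) < len(kept_pos):
        raise ValueError(
            f"cannot reach 1:1 balance at threshold {threshold}: only "
            f"{len(pool)} non-redundant negatives for {len(kept_pos)} "
            f"positives"
        )
    return kept_pos, pool
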