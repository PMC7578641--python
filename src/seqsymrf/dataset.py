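"""Pair assembly, reliable-negative selection and train/test splits.

An association pair (miRNA m, disease d) is characterised by the
448-dimension concatenation of the miRNA feature vector (126, first) and
the disease symptom vector (322 on the published vocabulary).  With no
database of confirmed negatives, the problem is positive-unlabeled:
every non-positive (m, d) combination forms the unlabeled universe, and
reliable negatives are the unlabeled pairs whose Euclidean distance to
the positive-class centroid exceeds ``multiplier`` x AED, where AED is
the average distance of unlabeled pairs to the centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

__all__ = [
    "LabeledPair",
    "NegativeSelectionResult",
    "build_pairs",
    "pair_features",
    "positive_centroid",
    "select_reliable_negatives",
    "make_training_set",
    "split_independent",
    "read_pairs_tsv",
    "write_pairs_tsv",
]


@dataclass(frozen=True)
class LabeledPair:
    mirna_id: str
    disease_id: str
    label: str  # "positive" | "unlabeled" | "reliable_negative"
    features: np.ndarray | None = None

    @property
    def key(self) -> Pair:
        return (self.mirna_id, self.disease_id)


@dataclass
class NegativeSelectionResult:
    """Outcome of centroid/AED reliable-negative mining.

    ``pairs`` and ``distances`` are parallel (all unlabeled pairs);
    ``selected`` holds the sampled reliable negatives, each of whose
    distance strictly exceeds ``multiplier * aed``.
    """

    centroid: np.ndarray
    pairs: list[Pair]
    distances: np.ndarray
    aed: float
    multiplier: float
    candidates: list[Pair] = field(default_factory=list)
    selected: list[Pair] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.multiplier * self.aed


def read_pairs_tsv(path) -> list[Pair]:
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna_id", "disease_id"],
                     dtype=str)
    return list(df.itertuples(index=False, name=None))


def write_pairs_tsv(pairs: Iterable[Pair], path) -> None:
    pd.DataFrame(pairs).to_csv(path, sep="\t", header=False, index=False)


def build_pairs(
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
    positives: Iterable[Pair],
) -> tuple[list[Pair], list[Pair]]:
    """Split the full miRNA x disease grid into positives and the
    unlabeled universe.

    Positive rows referencing unknown ids are dropped with a logged count
    (mirroring benchmark filtering against the sequence and symptom
    resources); duplicates are removed with a warning.  The universe is
    every remaining combination, so |universe| = M * D - P.
    """
    mset, dset = set(mirna_ids), set(disease_ids)
    seen: set[Pair] = set()
    kept: list[Pair] = []
    dropped = dups = 0
    for m, d in positives:
        if m not in mset or d not in dset:
            dropped += 1
            continue
        if (m, d) in seen:
            dups += 1
            continue
        seen.add((m, d))
        kept.append((m, d))
    if dropped:
        logger.info("dropped %d positive pair(s) referencing unknown ids", dropped)
    if dups:
        warnings.warn(f"removed {dups} duplicate positive pair(s)", stacklevel=2)
    universe = [
        (m, d) for m in mirna_ids for d in disease_ids if (m, d) not in seen
    ]
    return kept, universe


def pair_features(
    pairs: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
) -> np.ndarray:
    """448-dim design matrix rows: miRNA block (126) then disease block."""
    mf = mirna_features.loc[[m for m, _ in pairs]].to_numpy(dtype=float)
    df_ = disease_features.loc[[d for _, d in pairs]].to_numpy(dtype=float)
    return np.hstack([mf, df_])


def positive_centroid(
    positives: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
) -> np.ndarray:
    """Per-dimension mean of the positive pair vectors (the cluster centre)."""
    if len(positives) == 0:
        raise ValueError("cannot compute a centroid from an empty positive set")
    return pair_features(positives, mirna_features, disease_features).mean(axis=0)


def _distances_to_centroid(
    pairs: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
    centroid: np.ndarray,
) -> np.ndarray:
    # dist^2([m;d], [cm;cd]) = ||m-cm||^2 + ||d-cd||^2, so per-entity squared
    # distances are precomputed once instead of materialising the universe.
    n_m = mirna_features.shape[1]
    cm, cd = centroid[:n_m], centroid[n_m:]
    dm2 = ((mirna_features.to_numpy(dtype=float) - cm) ** 2).sum(axis=1)
    dd2 = ((disease_features.to_numpy(dtype=float) - cd) ** 2).sum(axis=1)
    m_idx = {m: i for i, m in enumerate(mirna_features.index)}
    d_idx = {d: i for i, d in enumerate(disease_features.index)}
    sq = np.array([dm2[m_idx[m]] + dd2[d_idx[d]] for m, d in pairs])
    return np.sqrt(sq)


def select_reliable_negatives(
    universe: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
    centroid: np.ndarray,
    multiplier: float = 1.5,
    n_select: int | None = None,
    seed: int = 0,
) -> NegativeSelectionResult:
    """Mine reliable negatives from the unlabeled universe.

    Steps: Euclidean distance of every unlabeled pair to the positive
    centroid; AED = mean of those distances; candidates are pairs with
    distance strictly greater than ``multiplier * AED``; ``n_select``
    reliable negatives (all candidates if None) are drawn uniformly
    without replacement with the given seed.
    """
    if len(universe) == 0:
        raise ValueError("unlabeled universe is empty")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    distances = _distances_to_centroid(
        universe, mirna_features, disease_features, centroid
    )
    aed = float(distances.mean())
    mask = distances > multiplier * aed
    candidates = [p for p, keep in zip(universe, mask) if keep]
    if n_select is None:
        selected = list(candidates)
    else:
        if len(candidates) < n_select:
            raise ValueError(
                f"only {len(candidates)} reliable-negative candidates at "
                f"multiplier {multiplier} but {n_select} requested; lower the "
                f"multiplier (e.g. 1.0) or the ratio"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=n_select, replace=False)
        selected = [candidates[i] for i in sorted(idx)]
    return NegativeSelectionResult(
        centroid=np.asarray(centroid, dtype=float),
        pairs=list(universe),
        distances=distances,
        aed=aed,
        multiplier=multiplier,
        candidates=candidates,
        selected=selected,
    )


def make_training_set(
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
    ratio: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
    """Row-shuffled design matrix with binary labels at a positives:negatives
    ratio of 1:``ratio`` (the published default is 1:1)."""
    n_neg = ratio * len(positives)
    if len(negatives) < n_neg:
        raise ValueError(
            f"need {n_neg} negatives for ratio 1:{ratio} but only "
            f"{len(negatives)} available"
        )
    neg = list(negatives[:n_neg])
    pairs = list(positives) + neg
    X = pair_features(pairs, mirna_features, disease_features)
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(neg))]).astype(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return X[order], y[order], [pairs[i] for i in order]


def split_independent(
    positives: Sequence[Pair], fraction_train: float = 0.8, seed: int = 0
) -> tuple[list[Pair], list[Pair]]:
    """Disjoint, exhaustive random split of the positives.

    The held-out size is floor(n * (1 - fraction_train)) and the remainder
    trains, which reproduces the published 5965/1491 split of 7456 pairs
    at 80/20.
    """
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must be in (0, 1)")
    positives = list(positives)
    n = len(positives)
    # round before flooring: 10 * (1 - 0.8) is 1.9999... in floats
    n_test = int(np.floor(round(n * (1 - fraction_train), 9)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [positives[i] for i in range(n) if i not in test_idx]
    test = [positives[i] for i in sorted(test_idx)]
    return train, test
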