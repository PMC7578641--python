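"""The 126-dimension miRNA feature vector: 10 global + 32 triplet + 84 k-mer.

Global descriptors summarise the hairpin geometry (base pairs, GC content,
central loop, bulges, tails, arm asymmetry, free energy per nucleotide).
Triplet features count the 8 paired/unpaired patterns of three adjacent
positions combined with the middle base (8 x 4 = 32); ")" is mapped to "("
so that structure is binarised to paired/unpaired.  The k-mer block holds
overlapping 1-, 2- and 3-mer counts (4 + 16 + 64 = 84) in lexicographic
order over A < C < G < U.

The feature order is frozen; :data:`FEATURE_NAMES` is the contract.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .structure_io import RnaRecord, SecondaryStructure

__all__ = [
    "GLOBAL_NAMES",
    "TRIPLET_PATTERNS",
    "TRIPLET_NAMES",
    "KMER_NAMES",
    "FEATURE_NAMES",
    "global_features",
    "triplet_features",
    "kmer_features",
    "mirna_vector",
    "feature_table",
]

BASES = "ACGU"

GLOBAL_NAMES: tuple[str, ...] = (
    "symmetric_difference",
    "n_base_pairs",
    "gc_content",
    "length_bp_ratio",
    "seq_length",
    "central_loop_length",
    "free_energy_per_nt",
    "bulge_number",
    "tail_length",
    "n_tails",
)

TRIPLET_PATTERNS: tuple[str, ...] = (
    "(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...",
)

TRIPLET_NAMES: tuple[str, ...] = tuple(
    f"triplet_{p}_{b}" for p in TRIPLET_PATTERNS for b in BASES
)

KMER_NAMES: tuple[str, ...] = tuple(
    "kmer_" + "".join(km)
    for k in (1, 2, 3)
    for km in itertools.product(BASES, repeat=k)
)

FEATURE_NAMES: tuple[str, ...] = GLOBAL_NAMES + TRIPLET_NAMES + KMER_NAMES
assert len(FEATURE_NAMES) == 126

_PATTERN_INDEX = {p: i for i, p in enumerate(TRIPLET_PATTERNS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_KMER_INDEX = {name[5:]: i for i, name in enumerate(KMER_NAMES)}


def _check_matched(record: RnaRecord, structure: SecondaryStructure) -> None:
    if record.length != structure.length:
        raise ValueError(
            f"record {record.id!r}: sequence length {record.length} != "
            f"structure length {structure.length}"
        )


def _dot_runs(dotbracket: str) -> list[tuple[int, int]]:
    """Maximal runs of '.' as half-open [start, end) intervals."""
    runs = []
    i, n = 0, len(dotbracket)
    while i < n:
        if dotbracket[i] == ".":
            j = i
            while j < n and dotbracket[j] == ".":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _central_loop(dotbracket: str) -> tuple[int, int] | None:
    """The hairpin loop: the longest '.' run with '(' on its left and ')'
    on its right.  Returns a half-open interval, or None if no such run
    exists (first occurrence wins on ties)."""
    best: tuple[int, int] | None = None
    for start, end in _dot_runs(dotbracket):
        if start == 0 or end == len(dotbracket):
            continue
        if dotbracket[start - 1] == "(" and dotbracket[end] == ")":
            if best is None or end - start > best[1] - best[0]:
                best = (start, end)
    return best


def global_features(
    record: RnaRecord, structure: SecondaryStructure
) -> np.ndarray:
    """The 10 global hairpin descriptors in the frozen order.

    ``symmetric_difference`` is |U5 - U3| where U5 / U3 count unpaired
    nucleotides 5' / 3' of the central loop, excluding the terminal tails
    (0 when there is no central loop).  ``length_bp_ratio`` is L / #pairs,
    defined as L for a fully unpaired structure (with a warning).
    """
    _check_matched(record, structure)
    db = structure.dotbracket
    seq = record.sequence
    L = len(seq)

    n_bp = db.count("(")
    gc = (seq.count("G") + seq.count("C")) / L
    if n_bp == 0:
        warnings.warn(
            f"record {record.id!r}: no base pairs; length_bp_ratio set to L",
            stacklevel=2,
        )
        lbp_ratio = float(L)
    else:
        lbp_ratio = L / n_bp

    lead = len(db) - len(db.lstrip("."))
    trail = len(db) - len(db.rstrip("."))
    if lead == L:  # fully unpaired: a single run is the 5' tail only
        trail = 0
    tail_length = lead + trail
    n_tails = (1 if lead > 0 else 0) + (1 if trail > 0 else 0)

    loop = _central_loop(db)
    loop_len = (loop[1] - loop[0]) if loop else 0

    bulges = 0
    for start, end in _dot_runs(db):
        if start == 0 or end == L:
            continue  # tails
        if loop is not None and (start, end) == loop:
            continue
        bulges += 1

    if loop is None:
        sym_diff = 0
    else:
        u5 = sum(1 for i in range(lead, loop[0]) if db[i] == ".")
        u3 = sum(1 for i in range(loop[1], L - trail) if db[i] == ".")
        sym_diff = abs(u5 - u3)

    return np.array(
        [
            float(sym_diff),
            float(n_bp),
            gc,
            lbp_ratio,
            float(L),
            float(loop_len),
            structure.mfe / L,
            float(bulges),
            float(tail_length),
            float(n_tails),
        ]
    )


def triplet_features(
    record: RnaRecord, structure: SecondaryStructure
) -> np.ndarray:
    """32 triplet counts: structure pattern of 3 adjacent positions (with
    ")" binarised to "(") crossed with the middle base."""
    _check_matched(record, structure)
    if record.length < 3:
        raise ValueError("sequence too short for triplet features (need L >= 3)")
    db = structure.dotbracket.replace(")", "(")
    seq = record.sequence
    counts = np.zeros(32, dtype=np.int64)
    for i in range(1, record.length - 1):
        pattern = db[i - 1 : i + 2]
        counts[_PATTERN_INDEX[pattern] * 4 + _BASE_INDEX[seq[i]]] += 1
    return counts


def kmer_features(record: RnaRecord) -> np.ndarray:
    """84 overlapping k-mer counts (4 mono, 16 di, 64 tri; lexicographic)."""
    if record.length < 3:
        raise ValueError("sequence too short for k-mer features (need L >= 3)")
    seq = record.sequence
    counts = np.zeros(84, dtype=np.int64)
    for k in (1, 2, 3):
        for i in range(record.length - k + 1):
            counts[_KMER_INDEX[seq[i : i + k]]] += 1
    return counts


def mirna_vector(
    record: RnaRecord, structure: SecondaryStructure, normalize: bool = False
) -> np.ndarray:
    """The full 126-dimension feature vector (global ++ triplet ++ k-mer).

    With ``normalize=True`` the triplet and k-mer blocks are divided by
    their window counts (L-2 and L, L-1, L-2), yielding frequencies; the
    default keeps raw counts, which is what a random forest consumes.
    """
    g = global_features(record, structure)
    t = triplet_features(record, structure).astype(float)
    k = kmer_features(record).astype(float)
    if normalize:
        L = record.length
        t /= L - 2
        k[:4] /= L
        k[4:20] /= L - 1
        k[20:] /= L - 2
    vec = np.concatenate([g, t, k])
    assert vec.shape == (126,)
    return vec


def feature_table(
    pairs: Iterable[tuple[RnaRecord, SecondaryStructure]],
    normalize: bool = False,
) -> pd.DataFrame:
    """Feature matrix for a batch: one row per miRNA, 126 named columns."""
    ids, rows = [], []
    for rec, structure in pairs:
        ids.append(rec.id)
        rows.append(mirna_vector(rec, structure, normalize=normalize))
    return pd.DataFrame(rows, index=pd.Index(ids, name="mirna_id"),
                        columns=list(FEATURE_NAMES))
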