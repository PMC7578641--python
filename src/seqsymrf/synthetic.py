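"""Self-contained synthetic inputs with the statistical structure the
pipeline assumes.

The generator emulates the three real resources: hairpin pre-miRNA
sequences with valid dot-bracket structures (miRBase + RNAfold), a sparse
disease-symptom score matrix (the symptom-disease network), and positive
miRNA-disease associations (HMDD).  A learnable signal is planted by
assigning miRNAs and diseases to latent clusters: each miRNA cluster has
a biased nucleotide composition (so the 84 k-mer features identify it)
and each disease cluster a dedicated symptom block (so the symptom
support identifies it); positive pairs preferentially connect matching
clusters with probability ``signal_strength``.  At signal 0 positives are
uniform random pairs and downstream classification collapses to chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .disease_features import (
    DiseaseVector,
    SymptomVocabulary,
    tfidf_scores,
    write_symptom_scores,
)
from .structure_io import RnaRecord, SecondaryStructure, write_fasta, write_vienna

Pair = tuple[str, str]

__all__ = [
    "FixtureConfig",
    "mirna_cluster",
    "disease_cluster",
    "make_hairpins",
    "make_symptom_network",
    "make_associations",
    "write_fixture",
]

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

# one strongly skewed composition per latent cluster (A-, C-, G-, U-rich)
_CLUSTER_PROBS = (
    (0.55, 0.15, 0.15, 0.15),
    (0.15, 0.55, 0.15, 0.15),
    (0.15, 0.15, 0.55, 0.15),
    (0.15, 0.15, 0.15, 0.55),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic corpus.

    Defaults: 300 miRNAs x 50 diseases over a 322-symptom vocabulary with
    1000 positive associations — large enough for stable cross-validation,
    small enough that a full pipeline run stays in the minutes range on
    one CPU.  ``signal_strength`` is the probability that a positive pair
    connects matching latent clusters (1.0 = fully planted signal,
    0.0 = uniform random positives).
    """

    n_mirnas: int = 300
    n_diseases: int = 50
    n_symptoms: int = 322
    n_clusters: int = 4
    stem_length_range: tuple[int, int] = (18, 55)
    loop_length_range: tuple[int, int] = (4, 15)
    max_tail: int = 8
    bulge_probability: float = 0.3
    mutation_rate: float = 0.05
    symptoms_per_disease: tuple[int, int] = (5, 15)
    n_positive_pairs: int = 1000
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_positive_pairs > self.n_mirnas * self.n_diseases:
            raise ValueError("more positives requested than pairs exist")
        for lo, hi in (self.stem_length_range, self.loop_length_range,
                       self.symptoms_per_disease):
            if lo > hi:
                raise ValueError("empty range in config")


def mirna_cluster(index: int, config: FixtureConfig) -> int:
    """Latent cluster of the index-th miRNA (deterministic: index mod K)."""
    return index % config.n_clusters


def disease_cluster(index: int, config: FixtureConfig) -> int:
    return index % config.n_clusters


def _draw(rng: np.random.Generator, n: int, probs: Sequence[float]) -> str:
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(probs)))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def make_hairpins(
    config: FixtureConfig,
) -> list[tuple[RnaRecord, SecondaryStructure]]:
    """Generate hairpin records with consistent dot-bracket annotations.

    Each hairpin is 5' tail + stem arm (optionally interrupted by a short
    bulge) + loop + reverse-complement arm + 3' tail; the 3' arm carries
    seeded point mutations at ``mutation_rate`` while the structure
    annotation keeps the constructed pairing.  Arm and loop nucleotides
    follow the miRNA's cluster composition, planting the k-mer signal.
    The annotated mfe is a stem-length proxy (-1.2 kcal/mol per pair).
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_mirnas):
        probs = _CLUSTER_PROBS[mirna_cluster(i, config) % len(_CLUSTER_PROBS)]
        stem = int(rng.integers(config.stem_length_range[0],
                                config.stem_length_range[1] + 1))
        loop = int(rng.integers(config.loop_length_range[0],
                                config.loop_length_range[1] + 1))
        t5 = int(rng.integers(0, config.max_tail + 1))
        t3 = int(rng.integers(0, config.max_tail + 1))
        arm5 = _draw(rng, stem, probs)
        loop_nt = _draw(rng, loop, probs)
        arm3 = list(_revcomp(arm5))
        for j in range(len(arm3)):
            if rng.random() < config.mutation_rate:
                arm3[j] = str(rng.choice(_BASES))
        bulge = ""
        if rng.random() < config.bulge_probability:
            bulge = _draw(rng, int(rng.integers(1, 4)), probs)
        cut = stem // 2
        sequence = (
            _draw(rng, t5, probs) + arm5[:cut] + bulge + arm5[cut:]
            + loop_nt + "".join(arm3) + _draw(rng, t3, probs)
        )
        dotbracket = (
            "." * t5 + "(" * cut + "." * len(bulge) + "(" * (stem - cut)
            + "." * loop + ")" * stem + "." * t3
        )
        record = RnaRecord(id=f"mir-{i:04d}", sequence=sequence)
        structure = SecondaryStructure(dotbracket=dotbracket, mfe=-1.2 * stem)
        assert structure.length == record.length
        out.append((record, structure))
    return out


def make_symptom_network(
    config: FixtureConfig,
) -> tuple[SymptomVocabulary, list[DiseaseVector]]:
    """Sparse disease-symptom scores with latent cluster blocks.

    The vocabulary is partitioned into one symptom block per cluster plus
    a shared background pool; each disease draws 5-15 symptoms, 70% from
    its cluster block, with small integer co-occurrence counts scored via
    TF-IDF (absolute co-occurrence x ln(N / n_s)).  Every symptom is
    guaranteed at least one occurrence so the published vocabulary size
    is preserved.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_sym, n_dis, K = config.n_symptoms, config.n_diseases, config.n_clusters
    block = n_sym // (K + 1)
    background = np.arange(K * block, n_sym)
    counts = np.zeros((n_dis, n_sym), dtype=int)
    lo, hi = config.symptoms_per_disease
    # diseases of a cluster draw mostly from a small shared symptom core,
    # like the recurring cardinal symptoms of a disease family
    core = max(8, block // 4)
    for j in range(n_dis):
        c = disease_cluster(j, config)
        block_ids = np.arange(c * block, c * block + core)
        k = int(rng.integers(lo, hi + 1))
        k_block = max(1, int(round(0.7 * k)))
        chosen = np.concatenate([
            rng.choice(block_ids, size=min(k_block, len(block_ids)),
                       replace=False),
            rng.choice(background, size=min(k - k_block, len(background)),
                       replace=False),
        ])
        # heavy-tailed (but bounded) co-occurrence counts, like literature
        # co-mention data; every fifth disease is "severe" (heavily
        # documented), giving the pair-distance distribution a stable long
        # right tail instead of one driven by unbounded outliers
        draws = np.clip(np.ceil(rng.lognormal(1.0, 1.0, size=len(chosen))),
                        1, 12)
        if j % 5 == 4:
            draws = draws * 4
        counts[j, chosen] = draws
    # guarantee full vocabulary coverage
    for s in np.flatnonzero(counts.sum(axis=0) == 0):
        counts[int(rng.integers(0, n_dis)), s] = 1
    frame = pd.DataFrame(
        counts,
        index=[f"disease-{j:03d}" for j in range(n_dis)],
        columns=[f"symptom-{s:03d}" for s in range(n_sym)],
    )
    return tfidf_scores(frame)


def make_associations(
    config: FixtureConfig,
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> list[Pair]:
    """Positive associations with a planted cluster-match signal.

    With probability ``signal_strength`` a positive connects a miRNA and
    a disease of the same latent cluster (clusters read off the index
    positions, matching the generators); otherwise the pair is uniform
    random.  Pairs are unique.
    """
    rng = np.random.default_rng(config.seed + 2)
    K = config.n_clusters
    matched = [
        (mirna_ids[i], disease_ids[j])
        for i in range(len(mirna_ids))
        for j in range(len(disease_ids))
        if mirna_cluster(i, config) == disease_cluster(j, config)
    ]
    matched = [matched[i] for i in rng.permutation(len(matched))]
    chosen: set[Pair] = set()
    out: list[Pair] = []
    while len(out) < config.n_positive_pairs:
        if rng.random() < config.signal_strength:
            while matched and matched[-1] in chosen:
                matched.pop()
            if not matched:
                raise ValueError(
                    f"matched-cluster pair pool exhausted after {len(out)} "
                    f"positives; lower n_positive_pairs or signal_strength "
                    f"(about M*D/{K} matched pairs exist)"
                )
            pair = matched.pop()
        else:
            pair = (
                mirna_ids[int(rng.integers(0, len(mirna_ids)))],
                disease_ids[int(rng.integers(0, len(disease_ids)))],
            )
            if pair in chosen:
                continue
        chosen.add(pair)
        out.append(pair)
    return out


def write_fixture(config: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture corpus (FASTA, Vienna, symptom TSV, positive
    pair TSV) and return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hairpins = make_hairpins(config)
    vocab, vectors = make_symptom_network(config)
    positives = make_associations(
        config,
        [rec.id for rec, _ in hairpins],
        [v.disease_id for v in vectors],
    )
    paths = {
        "fasta": out_dir / "hairpins.fa",
        "vienna": out_dir / "hairpins.vienna",
        "symptoms": out_dir / "symptoms.tsv",
        "positives": out_dir / "positives.tsv",
    }
    write_fasta([rec for rec, _ in hairpins], paths["fasta"])
    write_vienna(hairpins, paths["vienna"])
    write_symptom_scores(vocab, vectors, paths["symptoms"])
    pd.DataFrame(positives).to_csv(
        paths["positives"], sep="\t", header=False, index=False
    )
    return paths
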