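import numpy as np
import pytest

from seqsymrf import disease_features as dz
from seqsymrf import synthetic
from seqsymrf.dataset import build_pairs
from seqsymrf.mirna_features import feature_table


SMALL_CONFIG = synthetic.FixtureConfig(
    n_mirnas=80, n_diseases=20, n_positive_pairs=200, seed=11
)


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus shared across tests: feature tables,
    positives and the unlabeled universe."""
    cfg = SMALL_CONFIG
    hairpins = synthetic.make_hairpins(cfg)
    vocab, vectors = synthetic.make_symptom_network(cfg)
    mirna_features = feature_table(hairpins)
    disease_features = dz.vectors_to_frame(vocab, vectors)
    raw_pos = synthetic.make_associations(
        cfg, list(mirna_features.index), list(disease_features.index)
    )
    positives, universe = build_pairs(
        list(mirna_features.index), list(disease_features.index), raw_pos
    )
    return {
        "config": cfg,
        "hairpins": hairpins,
        "mirna_features": mirna_features,
        "disease_features": disease_features,
        "positives": positives,
        "universe": universe,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
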