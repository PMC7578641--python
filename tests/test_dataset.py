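"""Pair universe arithmetic, centroid/AED negative selection, splits."""

import numpy as np
import pandas as pd
import pytest

from seqsymrf.dataset import (
    build_pairs,
    make_training_set,
    pair_features,
    positive_centroid,
    select_reliable_negatives,
    split_independent,
)


def _toy_tables(mirna_values, disease_values):
    """1-dim miRNA and disease feature tables from plain value lists."""
    mt = pd.DataFrame({"f": mirna_values},
                      index=[f"m{i}" for i in range(len(mirna_values))])
    dt = pd.DataFrame({"g": disease_values},
                      index=[f"d{i}" for i in range(len(disease_values))])
    return mt, dt


class TestBuildPairs:
    def test_benchmark_universe_arithmetic(self, rng):
        mirnas = [f"m{i}" for i in range(917)]
        diseases = [f"d{i}" for i in range(339)]
        pairs = set()
        while len(pairs) < 7456:
            pairs.add((mirnas[rng.integers(917)], diseases[rng.integers(339)]))
        pos, universe = build_pairs(mirnas, diseases, sorted(pairs))
        assert len(pos) == 7456
        assert len(universe) == 303_407
        assert len(universe) + len(pos) == 917 * 339

    def test_small_grid(self):
        pos, universe = build_pairs(["m0", "m1"], ["d0", "d1"], [("m0", "d0")])
        assert len(universe) == 3
        pos, universe = build_pairs(
            ["m0"], ["d0"], [("m0", "d0")]
        )
        assert universe == []

    def test_unknown_ids_dropped_and_duplicates_warned(self):
        with pytest.warns(UserWarning, match="duplicate"):
            pos, universe = build_pairs(
                ["m0"], ["d0", "d1"],
                [("m0", "d0"), ("m0", "d0"), ("mX", "d0")],
            )
        assert pos == [("m0", "d0")]
        assert universe == [("m0", "d1")]


class TestCentroid:
    def test_mean_and_single_point(self):
        mt, dt = _toy_tables([0.0, 2.0], [0.0, 2.0])
        c = positive_centroid([("m0", "d0"), ("m1", "d1")], mt, dt)
        np.testing.assert_allclose(c, [1.0, 1.0])
        c = positive_centroid([("m1", "d0")], mt, dt)
        np.testing.assert_allclose(c, [2.0, 0.0])

    def test_empty_positive_set_rejected(self):
        mt, dt = _toy_tables([0.0], [0.0])
        with pytest.raises(ValueError, match="empty"):
            positive_centroid([], mt, dt)


class TestNegativeSelection:
    def _toy_universe(self):
        # distances to the origin-centroid are exactly 1, 2, 3, 4
        mt, dt = _toy_tables([1.0, 2.0, 3.0, 4.0], [0.0])
        universe = [(m, "d0") for m in mt.index]
        return universe, mt, dt, np.zeros(2)

    def test_aed_thresholding_hand_computed(self):
        universe, mt, dt, c = self._toy_universe()
        res = select_reliable_negatives(universe, mt, dt, c, multiplier=1.0)
        assert res.aed == pytest.approx(2.5)
        assert {p[0] for p in res.candidates} == {"m2", "m3"}
        res = select_reliable_negatives(universe, mt, dt, c, multiplier=1.5)
        assert res.threshold == pytest.approx(3.75)
        assert {p[0] for p in res.candidates} == {"m3"}

    def test_zero_distance_never_selected(self):
        mt, dt = _toy_tables([0.0, 5.0], [0.0])
        universe = [("m0", "d0"), ("m1", "d0")]
        res = select_reliable_negatives(universe, mt, dt, np.zeros(2),
                                        multiplier=0.5)
        assert ("m0", "d0") not in res.candidates

    def test_candidate_count_monotone_in_multiplier(self, rng):
        mt = pd.DataFrame(rng.normal(size=(30, 5)),
                          index=[f"m{i}" for i in range(30)])
        dt = pd.DataFrame(rng.normal(size=(10, 3)),
                          index=[f"d{i}" for i in range(10)])
        universe = [(m, d) for m in mt.index for d in dt.index]
        c = np.zeros(8)
        counts = [
            len(select_reliable_negatives(universe, mt, dt, c, m).candidates)
            for m in (0.5, 0.6, 0.8, 1.0, 1.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_distance_matches_naive_loop_oracle(self, rng):
        mt = pd.DataFrame(rng.normal(size=(6, 126)),
                          index=[f"m{i}" for i in range(6)])
        dt = pd.DataFrame(rng.normal(size=(4, 322)),
                          index=[f"d{i}" for i in range(4)])
        universe = [(m, d) for m in mt.index for d in dt.index]
        centroid = rng.normal(size=448)
        res = select_reliable_negatives(universe, mt, dt, centroid,
                                        multiplier=1.0)
        X = pair_features(universe, mt, dt)
        for row, dist in zip(X, res.distances):
            naive = 0.0
            for a, b in zip(row, centroid):
                naive += (a - b) ** 2
            assert dist == pytest.approx(np.sqrt(naive), abs=1e-9)

    def test_seeded_selection_reproducible(self, rng):
        mt = pd.DataFrame(rng.normal(size=(40, 3)),
                          index=[f"m{i}" for i in range(40)])
        dt = pd.DataFrame(rng.normal(size=(5, 2)),
                          index=[f"d{i}" for i in range(5)])
        universe = [(m, d) for m in mt.index for d in dt.index]
        kw = dict(multiplier=0.8, n_select=10, seed=123)
        r1 = select_reliable_negatives(universe, mt, dt, np.zeros(5), **kw)
        r2 = select_reliable_negatives(universe, mt, dt, np.zeros(5), **kw)
        assert r1.selected == r2.selected
        assert all(
            d > r1.threshold
            for p, d in zip(r1.pairs, r1.distances) if p in set(r1.selected)
        )

    def test_insufficient_candidates_is_explicit(self):
        universe, mt, dt, c = self._toy_universe()
        with pytest.raises(ValueError, match="lower the multiplier"):
            select_reliable_negatives(universe, mt, dt, c,
                                      multiplier=1.5, n_select=3)


class TestTrainingSet:
    def test_ratio_row_counts(self):
        mt, dt = _toy_tables(list(range(10)), list(range(10)))
        pos = [(f"m{i}", f"d{i}") for i in range(5)]
        neg = [(f"m{i}", f"d{9 - i}") for i in range(10)]
        for ratio, rows in ((1, 10), (2, 15)):
            X, y, pairs = make_training_set(pos, neg, mt, dt, ratio=ratio)
            assert X.shape == (rows, 2)
            assert int(y.sum()) == 5 and len(y) - y.sum() == 5 * ratio
        with pytest.raises(ValueError, match="ratio"):
            make_training_set(pos, neg, mt, dt, ratio=3)


class TestIndependentSplit:
    def test_published_split_sizes(self):
        pos = [(f"m{i}", "d") for i in range(7456)]
        train, test = split_independent(pos, 0.8, seed=0)
        assert (len(train), len(test)) == (5965, 1491)

    def test_small_split_and_partition(self):
        pos = [(f"m{i}", "d") for i in range(10)]
        train, test = split_independent(pos, 0.8, seed=1)
        assert (len(train), len(test)) == (8, 2)
        assert set(train) | set(test) == set(pos)
        assert set(train) & set(test) == set()
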