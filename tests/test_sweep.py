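"""Combination enumeration, pruning, forest training and model selection."""

import itertools

import numpy as np
import pytest

from kirc.errors import ParameterError
from kirc.features import FeatureCache, FeatureRegistry, FeatureSpec, PairScoreStore
from kirc.pairs import PairKey
from kirc.refsets import RefSet
from kirc.sweep import (
    DatasetCombo,
    ForestConfig,
    SweepResult,
    build_screening_set,
    enumerate_combos,
    prune_combos,
    select_final,
    subsample_refset,
    train_classifier,
)


class TestEnumeration:
    def test_full_grid_count(self):
        combos = enumerate_combos()
        assert len(combos) == 3825  # (4^2 - 1) * (4^4 - 1)

    def test_single_set_single_level(self):
        combos = enumerate_combos(pos_sets=["P"], neg_sets=["N"], fractions=(0.0, 1.0))
        assert len(combos) == 1
        assert combos[0].as_dict() == {"P": 1.0, "N": 1.0}

    def test_two_by_two_matches_brute_force(self):
        combos = enumerate_combos(pos_sets=["P1", "P2"], neg_sets=["N1", "N2"])
        # independent oracle: direct product enumeration with exclusions
        fr = (0.0, 0.33, 0.66, 1.0)
        brute = [
            (p, n)
            for p in itertools.product(fr, repeat=2)
            for n in itertools.product(fr, repeat=2)
            if any(f > 0 for f in p) and any(f > 0 for f in n)
        ]
        assert len(combos) == len(brute) == 225

    @pytest.mark.parametrize("n_pos,n_neg,n_fr", [(1, 2, 3), (3, 2, 2), (2, 4, 4)])
    def test_closed_form(self, n_pos, n_neg, n_fr):
        fr = tuple(i / (n_fr - 1) for i in range(n_fr))
        combos = enumerate_combos(
            pos_sets=[f"P{i}" for i in range(n_pos)],
            neg_sets=[f"N{i}" for i in range(n_neg)],
            fractions=fr,
        )
        assert len(combos) == (n_fr**n_pos - 1) * (n_fr**n_neg - 1)

    def test_empty_fraction_set_rejected(self):
        with pytest.raises(ParameterError):
            enumerate_combos(fractions=())


class TestPruning:
    def test_survivor_count_on_full_sweep(self):
        survivors = prune_combos(enumerate_combos())
        assert len(survivors) == 1920

    def test_no_decoy_combo_excluded(self):
        combo = DatasetCombo.of({"PDB": 0.33, "XLMS": 0.33, "PDB_Decoy": 0.0,
                                 "XLMS_Decoy": 0.0, "Random": 1.0, "XLMS_Random": 0.0})
        assert prune_combos([combo]) == []

    def test_missing_positive_source_excluded(self):
        combo = DatasetCombo.of({"PDB": 0.33, "XLMS": 0.0, "PDB_Decoy": 1.0,
                                 "XLMS_Decoy": 0.0, "Random": 1.0, "XLMS_Random": 0.0})
        assert prune_combos([combo]) == []

    def test_both_positives_full_excluded(self):
        combo = DatasetCombo.of({"PDB": 1.0, "XLMS": 1.0, "PDB_Decoy": 1.0,
                                 "XLMS_Decoy": 0.0, "Random": 0.0, "XLMS_Random": 0.0})
        assert prune_combos([combo]) == []

    def test_idempotent_and_order_independent(self):
        combos = enumerate_combos()
        once = prune_combos(combos)
        assert prune_combos(once) == once
        assert set(prune_combos(list(reversed(combos)))) == set(once)


class TestSubsampling:
    def make_refset(self, n=100):
        refset = RefSet("PDB", "positive")
        for i in range(n):
            refset.add(PairKey.of(f"A{i:03d}", f"B{i:03d}"))
        return refset

    @pytest.mark.parametrize("fraction,expected", [(0.33, 33), (1.0, 100), (0.0, 0), (0.66, 66)])
    def test_round_half_up_sizes(self, fraction, expected):
        assert len(subsample_refset(self.make_refset(), fraction, seed=1)) == expected

    def test_smaller_fraction_nested_in_larger(self):
        refset = self.make_refset()
        small = set(subsample_refset(refset, 0.33, seed=5))
        large = set(subsample_refset(refset, 0.66, seed=5))
        assert small <= large

    def test_deterministic_per_seed_and_name(self):
        refset = self.make_refset()
        assert subsample_refset(refset, 0.5, seed=2) == subsample_refset(refset, 0.5, seed=2)
        assert subsample_refset(refset, 0.5, seed=2) != subsample_refset(refset, 0.5, seed=3)


def planted_training_setup(n=200, sigma=0.1, seed=0):
    """One informative feature equal to the label plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    pos = RefSet("PDB", "positive")
    neg = RefSet("Random", "negative")
    signal = PairScoreStore("signal")
    noise = PairScoreStore("noise")
    for i in range(n):
        p = PairKey.of(f"P{i:04d}", f"Q{i:04d}")
        (pos if i % 2 == 0 else neg).add(p)
        label = 1.0 if i % 2 == 0 else 0.0
        signal.put(p, label + rng.normal(0, sigma))
        noise.put(p, rng.normal())
    registry = FeatureRegistry((
        FeatureSpec("signal", "pair_score", "signal"),
        FeatureSpec("noise", "pair_score", "noise"),
    ))
    cache = FeatureCache(registry, {"signal": signal, "noise": noise})
    return pos, neg, cache, rng


class TestTraining:
    def combo(self):
        return DatasetCombo.of({"PDB": 1.0, "Random": 1.0})

    def test_recovers_planted_signal(self):
        pos, neg, cache, rng = planted_training_setup()
        clf = train_classifier(self.combo(), {"PDB": pos, "Random": neg}, cache,
                               ForestConfig(n_trees=50))
        # held-out pairs with the same generative law
        from kirc.evaluate import roc_auc

        held, labels = [], []
        for i in range(100):
            p = PairKey.of(f"X{i:04d}", f"Y{i:04d}")
            label = i % 2
            cache.stores["signal"].put(p, label + rng.normal(0, 0.1))
            cache.stores["noise"].put(p, rng.normal())
            held.append(p)
            labels.append(label)
        auc = roc_auc(clf.score_matrix(cache.matrix(held)), labels)
        assert auc > 0.95
        imp = clf.feature_importances
        assert imp["signal"] > imp["noise"]

    def test_two_runs_bitwise_identical(self):
        pos, neg, cache, _ = planted_training_setup()
        refsets = {"PDB": pos, "Random": neg}
        s1 = train_classifier(self.combo(), refsets, cache).score_matrix(
            cache.matrix(sorted(pos.members)))
        s2 = train_classifier(self.combo(), refsets, cache).score_matrix(
            cache.matrix(sorted(pos.members)))
        assert np.array_equal(s1, s2)

    def test_single_class_combo_skipped(self):
        pos, neg, cache, _ = planted_training_setup()
        combo = DatasetCombo.of({"PDB": 1.0, "Random": 0.0})
        assert train_classifier(combo, {"PDB": pos, "Random": neg}, cache) is None


class TestSelection:
    def result(self, median, below, pdb_decoy=0.0):
        combo = DatasetCombo.of({"PDB": 0.66, "XLMS": 0.33, "PDB_Decoy": pdb_decoy,
                                 "Random": 1.0})
        return SweepResult(combo, median, below)

    def test_median_rank_dominates(self):
        a, b = self.result(10, 35), self.result(9, 20)
        assert select_final([a, b]) is b

    def test_tie_prefers_structure_decoy_training(self):
        tied = [self.result(8, 31, 0.0), self.result(8, 31, 0.33), self.result(9, 30)]
        assert select_final(tied) is tied[1]

    def test_single_classifier_returned(self):
        only = self.result(5, 1)
        assert select_final([only]) is only

    def test_empty_sweep_rejected(self):
        with pytest.raises(ParameterError):
            select_final([])


class TestScreeningSet:
    def setup_method(self):
        self.lengths = {"A": 1800, "B": 1801, "C": 100, "D": 200, "E": 150}

    def test_combined_length_cap(self):
        kept, excluded = build_screening_set(
            self.lengths, {PairKey.of("A", "B"): 0.9, PairKey.of("C", "D"): 0.9})
        assert [p for p, _ in kept] == [PairKey.of("C", "D")]
        assert (PairKey.of("A", "B"), "combined_length") in excluded

    def test_homodimer_excluded_regardless_of_score(self):
        kept, excluded = build_screening_set(self.lengths, {PairKey.of("C", "C"): 0.99})
        assert kept == [] and excluded[0][1] == "homodimer"

    def test_score_floor_boundary_inclusive(self):
        scores = {PairKey.of("C", "D"): 0.088, PairKey.of("C", "E"): 0.0879}
        kept, excluded = build_screening_set(self.lengths, scores)
        assert [p for p, _ in kept] == [PairKey.of("C", "D")]
        assert (PairKey.of("C", "E"), "below_score_floor") in excluded

    def test_one_representative_per_redundant_cluster_pair(self):
        scores = {PairKey.of("C", "D"): 0.9, PairKey.of("C", "E"): 0.8}
        clusters = {"D": "clu1", "E": "clu1", "C": "clu2"}
        kept, excluded = build_screening_set(self.lengths, scores,
                                             redundancy_clusters=clusters)
        assert [p for p, _ in kept] == [PairKey.of("C", "D")]  # higher score wins
        assert (PairKey.of("C", "E"), "redundant") in excluded

    def test_descending_score_order(self):
        scores = {PairKey.of("C", "D"): 0.3, PairKey.of("C", "E"): 0.7,
                  PairKey.of("D", "E"): 0.5}
        kept, _ = build_screening_set(self.lengths, scores)
        assert [s for _, s in kept] == [0.7, 0.5, 0.3]
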