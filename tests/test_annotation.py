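"""Homolog-pair mapping, novelty calls, GO clustering and Jaccard."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirc.annotation import (
    GOClusterAssignment,
    GOTerm,
    InteractionCluster,
    SequenceCluster,
    classify_novelty,
    cluster_go_terms,
    expand_by_clusters,
    find_homolog_pairs,
    go_pair_jaccard,
    levenshtein_norm_similarity,
    post_training_recall,
    read_gaf_annotations,
    read_obo_terms,
    select_best_alignment,
)
from kirc.errors import ParameterError
from kirc.pairs import PairKey
from kirc.refsets import AlignmentHit, Evidence, EvidenceTable
from kirc.simulate import generate_contact_structure


def hit(target="T", pident=90.0, evalue=1e-10, alnlen=100):
    return AlignmentHit("Q", target, pident, evalue, alnlen)


class TestBestAlignment:
    def test_identity_dominates(self):
        assert select_best_alignment([hit(pident=80), hit("W", pident=90)]).target == "W"

    def test_evalue_breaks_identity_tie(self):
        best = select_best_alignment([hit("X", evalue=1e-5), hit("Y", evalue=1e-10)])
        assert best.target == "Y"

    def test_length_breaks_remaining_tie(self):
        best = select_best_alignment([hit("X", alnlen=50), hit("Y", alnlen=100)])
        assert best.target == "Y"

    def test_gates_drop_short_or_divergent_hits(self):
        assert select_best_alignment([hit(alnlen=5)]) is None
        assert select_best_alignment([hit(pident=29.9)]) is None
        assert select_best_alignment([]) is None


class TestHomologPairs:
    def make(self, pid_a, pid_b, seed):
        st = generate_contact_structure(pid_a, pid_b, 12, seed=seed)
        return st

    def test_both_chains_mapped_yields_pair(self):
        st = self.make("X1", "X2", 1)
        hits = {(st.structure_id, "A"): "H1", (st.structure_id, "B"): "H2"}
        assert find_homolog_pairs([st], hits) == {PairKey.of("H1", "H2")}

    def test_unmapped_chain_yields_nothing(self):
        st = self.make("X1", "X2", 2)
        assert find_homolog_pairs([st], {(st.structure_id, "A"): "H1"}) == set()

    def test_set_union_over_structures(self):
        structures, hits = [], {}
        targets = [("H1", "H2"), ("H1", "H2"), ("H3", "H4"), ("H5", "H6"), ("H3", "H4")]
        for i, (ta, tb) in enumerate(targets):
            st = generate_contact_structure(f"A{i}", f"B{i}", 12, seed=10 + i)
            # distinct structure ids per fixture
            object.__setattr__(st, "structure_id", f"st{i}")
            structures.append(st)
            hits[("st" + str(i), "A")] = ta
            hits[("st" + str(i), "B")] = tb
        assert len(find_homolog_pairs(structures, hits)) == 3


class TestClusterExpansion:
    def clusters(self):
        return [
            SequenceCluster("A1", frozenset({"A1", "A2"})),
            SequenceCluster("B1", frozenset({"B1", "B2"})),
        ]

    def test_cartesian_product_of_two_clusters(self):
        out = expand_by_clusters({PairKey.of("A1", "B1")}, self.clusters())
        assert out == {PairKey.of(a, b) for a in ("A1", "A2") for b in ("B1", "B2")}

    def test_singleton_clusters_identity(self):
        pairs = {PairKey.of("X", "Y")}
        assert expand_by_clusters(pairs, []) == pairs

    def test_intra_cluster_seed_expands_to_all_within_pairs(self):
        cl = [SequenceCluster("A1", frozenset({"A1", "A2", "A3"}))]
        out = expand_by_clusters({PairKey.of("A1", "A2")}, cl)
        assert out == {PairKey.of("A1", "A2"), PairKey.of("A1", "A3"), PairKey.of("A2", "A3")}

    def test_superset_and_idempotent(self):
        seed = {PairKey.of("A1", "B2")}
        once = expand_by_clusters(seed, self.clusters())
        assert seed <= once
        assert expand_by_clusters(once, self.clusters()) == once

    def test_conflicting_membership_rejected(self):
        bad = [SequenceCluster("A1", frozenset({"A1", "A2"})),
               SequenceCluster("A2", frozenset({"A2", "A3"}))]
        with pytest.raises(ParameterError):
            expand_by_clusters({PairKey.of("A1", "A3")}, bad)


class TestNovelty:
    def ev(self, **kwargs):
        pair = PairKey.of("A", "B")
        return pair, EvidenceTable({pair: Evidence(**kwargs)})

    def test_experimental_via_intact_count(self):
        pair, ev = self.ev(intact_count=2)
        assert classify_novelty(pair, ev, set()) == "experimental"

    def test_string_physical_boundary_strict(self):
        pair, ev = self.ev(string_physical=700)
        assert classify_novelty(pair, ev, set()) == "novel"
        pair, ev = self.ev(string_physical=701)
        assert classify_novelty(pair, ev, set()) == "experimental"

    def test_functional_only_category(self):
        pair, ev = self.ev(string_combined=800)
        assert classify_novelty(pair, ev, set()) == "string_functional"

    def test_structure_homology_takes_priority(self):
        pair, ev = self.ev(intact_count=5)
        assert classify_novelty(pair, ev, {pair}) == "pdb_homolog"

    def test_all_zeros_is_novel(self):
        pair, ev = self.ev()
        assert classify_novelty(pair, ev, set()) == "novel"


class TestPostTrainingRecall:
    def cluster(self, score, day):
        return InteractionCluster(
            frozenset({PairKey.of("A", "B")}),
            datetime.date(2024, 11, day),
            score,
        )

    def test_fraction_above_cutoff(self):
        clusters = [self.cluster(0.9, d) for d in (1, 2)] + [
            self.cluster(0.3, d) for d in range(3, 11)
        ]
        recall = post_training_recall(
            clusters, datetime.date(2024, 10, 1), datetime.date(2025, 4, 16))
        assert recall == pytest.approx(0.20)

    def test_best_member_score_counts(self):
        cl = InteractionCluster(
            frozenset({PairKey.of("A", "B"), PairKey.of("C", "D")}),
            datetime.date(2024, 12, 1),
            max(0.3, 0.9),
        )
        recall = post_training_recall(
            [cl], datetime.date(2024, 10, 1), datetime.date(2025, 4, 16))
        assert recall == 1.0

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            post_training_recall(
                [self.cluster(0.9, 1)], datetime.date(2030, 1, 1), datetime.date(2030, 2, 1))


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook dynamic-programming oracle, independent of the edlib path."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestLevenshteinSimilarity:
    def test_identical_strings(self):
        assert levenshtein_norm_similarity("kinase", "kinase") == 1.0

    def test_single_insertion(self):
        assert levenshtein_norm_similarity("kinase", "kinases") == pytest.approx(1 - 1 / 7)

    def test_empty_versus_nonempty(self):
        assert levenshtein_norm_similarity("", "abc") == 0.0
        assert levenshtein_norm_similarity("", "") == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.text(alphabet="abcde ", max_size=12), b=st.text(alphabet="abcde ", max_size=12))
    def test_matches_dp_oracle_and_symmetric(self, a, b):
        sim = levenshtein_norm_similarity(a, b)
        assert sim == levenshtein_norm_similarity(b, a)
        if a or b:
            assert sim == pytest.approx(1 - dp_edit_distance(a, b) / max(len(a), len(b)))
        assert (sim == 1.0) == (a == b)


class TestGoClustering:
    def test_similar_descriptions_cluster_together(self):
        terms = [GOTerm("GO:1", "protein kinase activity"),
                 GOTerm("GO:2", "protein kinase activitys")]
        out = cluster_go_terms(terms)
        assert out.term_to_cluster["GO:1"] == out.term_to_cluster["GO:2"]

    def test_dissimilar_descriptions_stay_singletons(self):
        terms = [GOTerm("GO:1", "dna replication"), GOTerm("GO:2", "membrane transport"),
                 GOTerm("GO:3", "ribosome biogenesis")]
        out = cluster_go_terms(terms)
        assert len(set(out.term_to_cluster.values())) == 3

    def test_greedy_founder_rule_hand_trace(self):
        # sim(a,b) = 7/8 > 0.75; sim(b,c) = 7/8; sim(a,c) = 6/8 = 0.75 (not >)
        a, b, c = "abcdefgh", "abcdefgX", "abcdefYX"
        assert levenshtein_norm_similarity(a, b) > 0.75
        assert levenshtein_norm_similarity(b, c) > 0.75
        assert levenshtein_norm_similarity(a, c) <= 0.75
        out = cluster_go_terms([GOTerm("GO:1", a), GOTerm("GO:2", b), GOTerm("GO:3", c)])
        assert out.term_to_cluster["GO:1"] == out.term_to_cluster["GO:2"]
        assert out.term_to_cluster["GO:3"] != out.term_to_cluster["GO:1"]


class TestGoJaccard:
    def assignment(self):
        return GOClusterAssignment(
            {"GO:1": 0, "GO:2": 1, "GO:3": 2, "GO:4": 3}, {0: "GO:1", 1: "GO:2", 2: "GO:3", 3: "GO:4"}
        )

    def test_identical_sets(self):
        ann = {"A": {"GO:1", "GO:2"}, "B": {"GO:1", "GO:2"}}
        assert go_pair_jaccard(PairKey.of("A", "B"), ann, self.assignment()) == 1.0

    def test_disjoint_sets(self):
        ann = {"A": {"GO:1"}, "B": {"GO:2"}}
        assert go_pair_jaccard(PairKey.of("A", "B"), ann, self.assignment()) == 0.0

    def test_hand_counted_overlap(self):
        ann = {"A": {"GO:1", "GO:2", "GO:3"}, "B": {"GO:2", "GO:3", "GO:4"}}
        assert go_pair_jaccard(PairKey.of("A", "B"), ann, self.assignment()) == 0.5

    def test_both_empty_is_missing_not_zero(self):
        assert go_pair_jaccard(PairKey.of("A", "B"), {}, self.assignment()) is None

    def test_monotone_under_shared_cluster(self):
        ann = {"A": {"GO:1"}, "B": {"GO:2"}}
        before = go_pair_jaccard(PairKey.of("A", "B"), ann, self.assignment())
        ann["A"].add("GO:2")
        after = go_pair_jaccard(PairKey.of("A", "B"), ann, self.assignment())
        assert after > before


class TestGoFileReaders:
    def test_gaf_and_obo_round_trip(self, tmp_path, small_interactome):
        from kirc.simulate import write_fixture_tree

        out = tmp_path / "fixture"
        write_fixture_tree(small_interactome, out)
        annotations = read_gaf_annotations(out / "go" / "annotations.gaf")
        terms = read_obo_terms(out / "go" / "terms.obo")
        assert len(annotations) == len(small_interactome.proteome)
        assert all(t.term_id.startswith("GO:") and t.description for t in terms)
        # template families (base vs pluralized) land in the same cluster
        assignment = cluster_go_terms(terms)
        by_desc = {t.description: t.term_id for t in terms}
        base = by_desc["protein kinase activity"]
        variant = by_desc["protein kinase activitys"]
        assert assignment.term_to_cluster[base] == assignment.term_to_cluster[variant]
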