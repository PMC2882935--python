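"""PFP raw scoring: co-occurrence statistics, direct scores, propagation."""

import io
import math

import pytest

from funsimnet import pfp_core
from funsimnet.ontology import AnnotationCorpus
from funsimnet.pfp_core import (
    Hit,
    PFPScoreSet,
    TermAssociationStats,
    association_stats,
    conditional_probability,
    direct_scores,
    propagate_and_finalize,
    read_hits,
    score_query,
)


class TestReadHits:
    def test_three_column(self):
        hits = read_hits(io.StringIO("q1\ts1\t1e-5\nq1\ts2\t2.0\n"))
        assert hits[0] == Hit("q1", "s1", 1e-5)
        assert hits[1].e_value == 2.0

    def test_outfmt6_row(self):
        row = ("q1\ts9\t98.5\t120\t2\t0\t1\t120\t5\t124\t3e-50\t230\n")
        hits = read_hits(io.StringIO(row))
        assert hits[0].subject == "s9"
        assert hits[0].e_value == 3e-50

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValueError, match="E-value"):
            Hit("q", "s", 0.0)


class TestAssociationStats:
    def test_single_protein_pair_counts_direct(self, chain_dag):
        corpus = AnnotationCorpus(
            dag=chain_dag, direct={"p": {"GO:0000002", "GO:0000003"}})
        stats = association_stats(corpus)
        assert stats.c_pair("GO:0000002", "GO:0000003") == 1
        assert stats.single_count == {"GO:0000002": 1, "GO:0000003": 1}
        assert stats.mu == 2

    def test_closed_counting_includes_ancestors(self, chain_dag):
        corpus = AnnotationCorpus(dag=chain_dag,
                                  direct={"p": {"GO:0000003"}})
        stats = association_stats(corpus, closed=True)
        assert stats.mu == 3
        assert stats.c_pair("GO:0000003", "GO:0000001") == 1

    def test_never_cooccurring_pair_is_zero(self, chain_dag):
        corpus = AnnotationCorpus(dag=chain_dag, direct={
            "p": {"GO:0000002"}, "q": {"GO:0000003"}})
        stats = association_stats(corpus)
        assert stats.c_pair("GO:0000002", "GO:0000003") == 0

    def test_symmetric_counts_bounded_by_singles(self, smoke_loaded):
        _, corpus, _ = smoke_loaded
        stats = association_stats(corpus)
        for (a, b), count in stats.pair_count.items():
            assert count == stats.c_pair(b, a)
            assert count <= min(stats.single_count[a],
                                stats.single_count[b])


class TestConditionalProbability:
    def stats(self):
        return TermAssociationStats(
            single_count={"f": 10, "g": 10}, pair_count={},
            mu=5, epsilon=0.05, partners={"f": {"f"}, "g": {"g"}})

    def test_self_probability(self):
        assert conditional_probability(self.stats(), "f", "f") == \
            pytest.approx(10.05 / 10.25)

    def test_never_cooccurring(self):
        assert conditional_probability(self.stats(), "f", "g") == \
            pytest.approx(0.05 / 10.25)

    def test_asymmetry(self):
        stats = TermAssociationStats(
            single_count={"a": 1, "b": 100},
            pair_count={("a", "b"): 1}, mu=2, epsilon=0.05,
            partners={"a": {"a", "b"}, "b": {"a", "b"}})
        assert conditional_probability(stats, "a", "b") != \
            conditional_probability(stats, "b", "a")

    def test_probabilities_bounded_and_sum_matches_mass(self, smoke_loaded):
        """Every P(f_a|f_j) is in (0, 1]; summed over all mu terms the
        probabilities equal (T_j + mu*eps) / (c_j + mu*eps), where T_j
        is the total co-assignment mass of f_j counted protein by
        protein (oracle recount)."""
        _, corpus, _ = smoke_loaded
        stats = association_stats(corpus)
        terms = sorted(stats.single_count)
        for f_j in terms[:5]:
            values = [conditional_probability(stats, f_a, f_j)
                      for f_a in terms]
            assert all(0.0 < v <= 1.0 for v in values)
            mass = sum(len(ts) for ts in corpus.direct.values()
                       if f_j in ts)
            c_j = stats.single_count[f_j]
            mu_eps = stats.mu * stats.epsilon
            assert sum(values) == pytest.approx(
                (mass + mu_eps) / (c_j + mu_eps))


class TestDirectScores:
    def test_no_hits_gives_empty_scores(self):
        stats = TermAssociationStats(single_count={}, pair_count={}, mu=1)
        result = direct_scores([], {}, stats)
        assert result.direct == {}

    def test_single_hit_hand_computation(self):
        # weight = -ln(1e-5) + ln(125); P(f|f) = 10.05/10.25
        stats = TermAssociationStats(
            single_count={"f": 10}, pair_count={}, mu=5, epsilon=0.05,
            partners={"f": {"f"}})
        result = direct_scores([Hit("q", "s", 1e-5)], {"s": {"f"}}, stats)
        expected = (-math.log(1e-5) + math.log(125)) * (10.05 / 10.25)
        assert result.direct["f"] == pytest.approx(expected)
        assert result.direct["f"] == pytest.approx(16.02, abs=0.01)

    def test_hit_at_shift_boundary_contributes_zero(self):
        stats = TermAssociationStats(
            single_count={"f": 10}, pair_count={}, mu=5, epsilon=0.05,
            partners={"f": {"f"}})
        result = direct_scores([Hit("q", "s", 125.0)], {"s": {"f"}}, stats)
        assert result.direct == {}

    def test_appending_hits_never_lowers_scores(self, smoke_loaded):
        _, corpus, _ = smoke_loaded
        stats = association_stats(corpus)
        proteins = sorted(corpus.direct)
        associations = {p: corpus.terms_of(p) for p in proteins}
        hits = [Hit("q", proteins[0], 1e-8)]
        previous = direct_scores(hits, associations, stats).direct
        for extra in proteins[1:4]:
            hits.append(Hit("q", extra, 1e-4))
            current = direct_scores(hits, associations, stats).direct
            for term, score in previous.items():
                assert current.get(term, 0.0) >= score - 1e-12
            previous = current


class _CountStub:
    def __init__(self, counts):
        self.term_count = counts


class TestPropagation:
    def test_single_child_ratio(self, chain_dag):
        # chain: leaf GO:0000003 -> GO:0000002 -> root
        scores = PFPScoreSet(query="q", direct={"GO:0000003": 10.0})
        corpus = _CountStub({"GO:0000003": 5, "GO:0000002": 10,
                             "GO:0000001": 20})
        result = propagate_and_finalize(scores, chain_dag, corpus)
        assert result.propagated["GO:0000002"] == pytest.approx(5.0)
        assert result.final["GO:0000003"] == pytest.approx(10.0)

    def test_equal_counts_pass_full_score(self, chain_dag):
        scores = PFPScoreSet(query="q", direct={"GO:0000003": 10.0})
        corpus = _CountStub({"GO:0000003": 7, "GO:0000002": 7,
                             "GO:0000001": 7})
        result = propagate_and_finalize(scores, chain_dag, corpus)
        assert result.propagated["GO:0000002"] == pytest.approx(10.0)

    def test_two_children_sum(self, diamond_dag):
        # both diamond parents propagate into the shared root
        scores = PFPScoreSet(query="q", direct={"GO:0000002": 4.0,
                                                "GO:0000003": 6.0})
        corpus = _CountStub({"GO:0000002": 5, "GO:0000003": 5,
                             "GO:0000001": 10, "GO:0000004": 1})
        result = propagate_and_finalize(scores, diamond_dag, corpus)
        assert result.propagated["GO:0000001"] == pytest.approx(5.0)

    def test_cascade_compounds_toward_root(self, chain_dag):
        scores = PFPScoreSet(query="q", direct={"GO:0000003": 8.0})
        corpus = _CountStub({"GO:0000003": 5, "GO:0000002": 10,
                             "GO:0000001": 20})
        flat = propagate_and_finalize(scores, chain_dag, corpus)
        cascaded = propagate_and_finalize(scores, chain_dag, corpus,
                                          cascade=True)
        # single-level: root gets nothing (its child has no direct score)
        assert "GO:0000001" not in flat.propagated
        assert cascaded.propagated["GO:0000001"] == pytest.approx(
            4.0 * 10 / 20)

    def test_parent_never_exceeds_children_sum(self, smoke_loaded):
        dag, corpus, _ = smoke_loaded
        stats = association_stats(corpus)
        proteins = sorted(corpus.direct)
        hits = [Hit("q", p, 1e-6) for p in proteins[:5]]
        result = score_query(hits, corpus, dag, stats=stats)
        for parent, received in result.propagated.items():
            child_sum = sum(result.direct.get(c, 0.0)
                            for c in dag.children(parent))
            assert received <= child_sum + 1e-9

    def test_zero_count_parent_skipped(self, chain_dag):
        scores = PFPScoreSet(query="q", direct={"GO:0000003": 10.0})
        corpus = _CountStub({"GO:0000003": 5})
        result = propagate_and_finalize(scores, chain_dag, corpus)
        assert result.propagated == {}


def test_true_term_recovered_from_planted_hits(paper_shaped_data):
    """The designated true term should top the final ranking for most
    queries of one planted scenario."""
    import funsimnet as fsn

    data = paper_shaped_data
    dag = fsn.parse_obo(io.StringIO(data.files["go.obo"]))
    corpus = AnnotationCorpus.from_pairs(
        dag, fsn.read_gaf(io.StringIO(data.files["annot.gaf"])))
    hits = read_hits(io.StringIO(data.files["hits.tsv"]))
    by_query: dict[str, list[Hit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query, []).append(hit)
    stats = association_stats(corpus)
    top_hits = sum(
        score_query(query_hits, corpus, dag, stats=stats).ranked()[0][0]
        == data.truth["queries"][query]
        for query, query_hits in by_query.items())
    assert top_hits >= 8
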