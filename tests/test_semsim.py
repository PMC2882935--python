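"""Term and protein semantic similarity, and the funSim combination."""

import io
import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from funsimnet.ontology import (
    AnnotationCorpus,
    OntologyError,
    ancestor_closure,
    compute_ic,
    parse_obo,
)
from funsimnet import semsim
from funsimnet.semsim import (
    all_pairs_scores,
    fun_sim,
    go_score,
    score_pair,
    term_similarity,
)

SIBLING_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: m
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: a
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: b
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000005
name: x
namespace: biological_process
is_a: GO:0000001
"""


@pytest.fixture(scope="module")
def sibling_setup():
    """p(a) = p(b) = 0.25, p(m) = 0.5, p(root) = 1."""
    dag = parse_obo(io.StringIO(SIBLING_OBO))
    direct = {
        "p1": {"GO:0000003"},
        "p2": {"GO:0000004"},
        "p3": {"GO:0000005"},
        "p4": {"GO:0000005"},
    }
    corpus = AnnotationCorpus(dag=dag, direct=direct)
    ic = compute_ic(dag, corpus, require_all_namespaces=False)
    return dag, corpus, ic


def brute_force_similarity(c1, c2, dag, ic, mode):
    """Independent oracle: evaluate every common ancestor explicitly."""
    common = ancestor_closure(dag, [c1]) & ancestor_closure(dag, [c2])
    denominator = math.log(ic[c1]) + math.log(ic[c2])
    best = 0.0
    for c in common:
        if c not in ic or denominator == 0:
            continue
        relevance = (1 - ic[c]) if mode == "schlicker" else 1.0
        best = max(best, relevance * 2 * math.log(ic[c]) / denominator)
    return min(1.0, max(0.0, best))


class TestTermSimilarity:
    def test_against_root_is_zero(self, sibling_setup):
        dag, _, ic = sibling_setup
        assert term_similarity("GO:0000003", "GO:0000001", dag, ic) == 0.0

    def test_self_similarity_is_one_in_lin_mode(self, sibling_setup):
        dag, _, ic = sibling_setup
        assert term_similarity("GO:0000003", "GO:0000003", dag, ic,
                               mode="lin") == 1.0

    def test_siblings_lin_and_schlicker(self, sibling_setup):
        dag, _, ic = sibling_setup
        lin = term_similarity("GO:0000003", "GO:0000004", dag, ic,
                              mode="lin")
        # 2 ln 0.5 / (ln 0.25 + ln 0.25) = 0.5; relevance (1 - 0.5) halves it
        assert lin == pytest.approx(0.5)
        schlicker = term_similarity("GO:0000003", "GO:0000004", dag, ic)
        assert schlicker == pytest.approx(0.25)

    def test_cross_namespace_is_an_error(self, smoke_loaded):
        dag, _, ic = smoke_loaded
        bp, mf = dag.roots["BP"], dag.roots["MF"]
        with pytest.raises(OntologyError, match="namespace"):
            term_similarity(bp, mf, dag, ic)

    @pytest.mark.parametrize("mode", ["schlicker", "lin"])
    def test_symmetry_and_bounds_on_random_pairs(self, smoke_loaded, mode):
        dag, _, ic = smoke_loaded
        terms = sorted(t for t in ic.p if t in dag)[:12]
        for c1, c2 in itertools.combinations(terms, 2):
            if dag.namespace_of[c1] != dag.namespace_of[c2]:
                continue
            s12 = term_similarity(c1, c2, dag, ic, mode=mode)
            s21 = term_similarity(c2, c1, dag, ic, mode=mode)
            assert s12 == s21
            assert 0.0 <= s12 <= 1.0

    @pytest.mark.parametrize("mode", ["schlicker", "lin"])
    def test_equals_exhaustive_common_ancestor_search(self, smoke_loaded,
                                                      mode):
        dag, _, ic = smoke_loaded
        terms = sorted(t for t in ic.p if t in dag)
        for c1, c2 in itertools.combinations(terms, 2):
            if dag.namespace_of[c1] != dag.namespace_of[c2]:
                continue
            assert term_similarity(c1, c2, dag, ic, mode=mode) == \
                pytest.approx(brute_force_similarity(c1, c2, dag, ic, mode))


class TestGoScore:
    def test_identical_singletons_lin(self, sibling_setup):
        dag, _, ic = sibling_setup
        score = go_score({"GO:0000003"}, {"GO:0000003"}, dag, ic,
                         mode="lin")
        assert score.value == 1.0

    def test_root_only_overlap_scores_zero(self, sibling_setup):
        dag, _, ic = sibling_setup
        # a/b subtree vs x: the only common ancestor is the root
        score = go_score({"GO:0000003"}, {"GO:0000005"}, dag, ic)
        assert score.value == 0.0

    def test_row_and_column_scores_with_stub_matrix(self, sibling_setup):
        dag, _, ic = sibling_setup

        def stub(c1, c2):
            return 1.0 if c1 == c2 else 0.2

        for combiner, expected in [("max", 1.0), ("mean", 0.8)]:
            score = go_score({"a"}, {"a", "z"}, dag, ic, combiner=combiner,
                             similarity=stub)
            assert score.row_score == pytest.approx(1.0)
            assert score.col_score == pytest.approx(0.6)
            assert score.value == pytest.approx(expected)

    def test_empty_set_is_an_error(self, sibling_setup):
        dag, _, ic = sibling_setup
        with pytest.raises(OntologyError, match="non-empty"):
            go_score(set(), {"GO:0000003"}, dag, ic)

    @pytest.mark.parametrize("combiner", ["max", "mean"])
    def test_symmetric_under_set_exchange(self, smoke_loaded, combiner):
        dag, corpus, ic = smoke_loaded
        proteins = sorted(corpus.proteins)[:8]
        for pa, pb in itertools.combinations(proteins, 2):
            a = {t for t in corpus.terms_of(pa, "BP") if t in ic}
            b = {t for t in corpus.terms_of(pb, "BP") if t in ic}
            if not a or not b:
                continue
            fwd = go_score(a, b, dag, ic, combiner=combiner)
            rev = go_score(b, a, dag, ic, combiner=combiner)
            assert fwd.value == pytest.approx(rev.value)

    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_shared_term_never_decreases_max_combiner(self, smoke_loaded,
                                                      data):
        """In Lin mode a shared non-root term has self-similarity 1, so
        adding it to both sets can only raise the row/column maxima
        means.  (Under the relevance weight self-similarity is 1 - p,
        and a frequent shared term can legitimately dilute the score.)
        """
        dag, _, ic = smoke_loaded
        bp_terms = sorted(t for t in ic.p
                          if dag.namespace_of[t] == "BP"
                          and t != dag.roots["BP"])
        a = data.draw(st.sets(st.sampled_from(bp_terms), min_size=1,
                              max_size=4))
        b = data.draw(st.sets(st.sampled_from(bp_terms), min_size=1,
                              max_size=4))
        shared = data.draw(st.sampled_from(bp_terms))
        before = go_score(a, b, dag, ic, mode="lin", combiner="max").value
        after = go_score(a | {shared}, b | {shared}, dag, ic, mode="lin",
                         combiner="max").value
        assert after >= before - 1e-12


class TestFunSim:
    @pytest.mark.parametrize("scores,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 0.0), 1.0 / 3.0),
        ((0.5, 0.5, 0.5), 0.25),
    ])
    def test_mean_of_squares(self, scores, expected):
        assert fun_sim(*scores) == pytest.approx(expected)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            fun_sim(1.2, 0.0, 0.0)


class TestAllPairs:
    def test_pair_count_is_n_choose_2(self, smoke_loaded):
        dag, corpus, ic = smoke_loaded
        proteins = sorted(corpus.proteins)[:5]
        table = all_pairs_scores(corpus.restricted_to(proteins), dag, ic)
        assert len(table) == 10

    def test_missing_category_yields_absent_funsim(self, sibling_setup):
        dag, _, _ = sibling_setup
        corpus = AnnotationCorpus(dag=dag, direct={
            "p1": {"GO:0000003"}, "p2": {"GO:0000004"}})
        ic = compute_ic(dag, corpus, require_all_namespaces=False)
        table = all_pairs_scores(corpus, dag, ic)
        row = table.iloc[0]
        assert not math.isnan(row.bp)
        assert math.isnan(row.cc) and math.isnan(row.mf)
        assert math.isnan(row.funsim)

    def test_equals_double_loop_oracle(self, smoke_loaded):
        dag, corpus, ic = smoke_loaded
        proteins = sorted(corpus.proteins)[:5]
        restricted = corpus.restricted_to(proteins)
        table = all_pairs_scores(restricted, dag, ic)
        lookup = {(r.protein_a, r.protein_b): r
                  for r in table.itertuples(index=False)}
        for pa, pb in itertools.combinations(sorted(restricted.proteins), 2):
            expected = score_pair(pa, pb, restricted, dag, ic)
            row = lookup[(pa, pb)]
            for name, want in [("bp", expected.bp), ("cc", expected.cc),
                               ("mf", expected.mf),
                               ("funsim", expected.funsim)]:
                got = getattr(row, name)
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want)

    def test_roundtrip_tsv(self, smoke_loaded, tmp_path):
        dag, corpus, ic = smoke_loaded
        proteins = sorted(corpus.proteins)[:4]
        table = all_pairs_scores(corpus.restricted_to(proteins), dag, ic)
        path = tmp_path / "pairs.tsv"
        semsim.write_pairs(table, path)
        back = semsim.read_pairs(path)
        assert list(back.columns) == list(table.columns)
        assert len(back) == len(table)
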