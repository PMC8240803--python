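"""Corpus tagging: presence coding, period binning, DF matrices, top-K."""

import datetime as dt

import numpy as np
import pytest

from ontosig.tagging import (BinningError, KeywordPeriodMatrix, PeriodBinning,
                             build_df_matrix, read_corpus_jsonl,
                             select_top_keywords, tag_documents,
                             write_corpus_jsonl)
from ontosig.ontology import UnknownConceptError
from ontosig.utils import normalize_surface

from conftest import make_doc

KW = ["financial_support_for_childbirth", "violence_and_abuse", "population_aging"]


class TestTagDocuments:
    def test_two_synonyms_of_one_concept_code_one(self, ontology):
        doc = make_doc("d1", ["the", "baby", "bonus", "and", "childbirth", "grant", "news"])
        presence = tag_documents(ontology, [doc], KW)
        assert presence[0].tolist() == [1, 0, 0]

    def test_no_fertility_terms_gives_all_zero(self, ontology):
        doc = make_doc("d2", ["weather", "report", "today"])
        assert tag_documents(ontology, [doc], KW).sum() == 0

    def test_label_counts_as_surface_form(self, ontology):
        doc = make_doc("d3", ["population", "aging", "debate"])
        assert tag_documents(ontology, [doc], KW)[0].tolist() == [0, 0, 1]

    def test_unknown_concept_raises(self, ontology):
        with pytest.raises(UnknownConceptError):
            tag_documents(ontology, [make_doc("d", ["x"])], ["no_such_concept"])

    def test_matches_set_intersection_oracle_on_random_docs(self, ontology):
        """Presence equals brute-force intersection between the document's
        n-gram set and each concept's synonym set, on 100 random synthetic
        documents."""
        rng = np.random.default_rng(11)
        synsets = {c: ontology.class_synonyms(c) for c in KW}
        vocab = ["alpha", "beta", "gamma", "baby", "bonus", "child", "abuse",
                 "aging", "society", "population", "subsidy", "grant"]
        docs = []
        for d in range(100):
            tokens = [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(3, 15))]
            docs.append(make_doc(f"r{d}", tokens))
        presence = tag_documents(ontology, docs, KW)
        for d, doc in enumerate(docs):
            toks = [normalize_surface(t) for t in doc.tokens]
            grams = {" ".join(toks[i:i + L])
                     for L in range(1, 4) for i in range(len(toks) - L + 1)}
            for k, concept in enumerate(KW):
                assert presence[d, k] == int(bool(grams & synsets[concept]))


class TestPeriodBinning:
    def test_yearly_study_window_has_half_length_final_period(self):
        binning = PeriodBinning.yearly(dt.date(2011, 1, 1), dt.date(2015, 6, 30))
        assert binning.n == 5
        assert binning.labels == ["2011", "2012", "2013", "2014", "2015"]
        last = binning.periods[-1]
        assert (last.end - last.start).days + 1 == 181  # Jan-Jun 2015
        assert binning.assign(dt.date(2013, 12, 31)) == 2

    def test_document_outside_window_is_a_binning_error(self, study_binning):
        with pytest.raises(BinningError):
            study_binning.assign(dt.date(2015, 7, 1))

    def test_overlapping_periods_rejected(self):
        from ontosig.tagging import Period
        with pytest.raises(ValueError):
            PeriodBinning([
                Period("a", dt.date(2011, 1, 1), dt.date(2011, 12, 31)),
                Period("b", dt.date(2011, 6, 1), dt.date(2012, 12, 31)),
            ])


class TestBuildDfMatrix:
    def test_direct_count(self, ontology, study_binning):
        docs = [
            make_doc("a", ["baby", "bonus"], dt.date(2011, 2, 1)),
            make_doc("b", ["subsidy", "talk"], dt.date(2011, 3, 1)),
            make_doc("c", ["nothing", "here"], dt.date(2011, 4, 1)),
        ]
        m = build_df_matrix(ontology, docs, study_binning, KW)
        assert m.df[0].tolist() == [2, 0, 0, 0, 0]
        assert m.nn.tolist() == [3, 0, 0, 0, 0]

    def test_nn_counts_every_document_and_sums_to_corpus_size(self, ontology, study_binning):
        rng = np.random.default_rng(3)
        days = [dt.date(2011, 1, 1) + dt.timedelta(days=int(x))
                for x in rng.integers(0, 1640, size=200)]
        docs = [make_doc(f"d{i}", ["noise"], day) for i, day in enumerate(days)]
        m = build_df_matrix(ontology, docs, study_binning, KW)
        assert int(m.nn.sum()) == 200
        assert m.df.sum() == 0

    def test_permuting_documents_leaves_matrix_unchanged(self, ontology, study_binning):
        rng = np.random.default_rng(5)
        docs = [make_doc(f"d{i}", ["baby", "bonus"] if i % 3 == 0 else ["x"],
                         dt.date(2011 + i % 4, 5, 1)) for i in range(60)]
        m1 = build_df_matrix(ontology, docs, study_binning, KW)
        shuffled = list(docs)
        rng.shuffle(shuffled)
        m2 = build_df_matrix(ontology, shuffled, study_binning, KW)
        assert np.array_equal(m1.df, m2.df) and np.array_equal(m1.nn, m2.nn)

    def test_streaming_equals_batch_recount_on_synthetic_corpus(self, ontology, study_binning):
        """DF from the single-pass pipeline equals an independent per-period
        batch recount on a 500-document synthetic corpus."""
        rng = np.random.default_rng(17)
        phrases = ["baby bonus", "child abuse", "population aging", "weather"]
        docs = []
        for i in range(500):
            day = dt.date(2011, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1640)))
            tokens = []
            for p in phrases:
                if rng.random() < 0.3:
                    tokens += p.split()
            docs.append(make_doc(f"d{i}", tokens or ["empty"], day))
        m = build_df_matrix(ontology, docs, study_binning, KW)
        for j, period in enumerate(study_binning.periods):
            batch = [d for d in docs if d.timestamp in period]
            assert m.nn[j] == len(batch)
            presence = tag_documents(ontology, batch, KW)
            assert m.df[:, j].tolist() == presence.sum(axis=0).tolist()

    def test_invalid_df_bounds_rejected(self):
        with pytest.raises(ValueError):
            KeywordPeriodMatrix(["k"], ["p"], np.array([[5]]), np.array([3]))


class TestSelectTopKeywords:
    def test_planted_highest_concepts_selected(self):
        keywords = [f"k{i:02d}" for i in range(25)]
        df = np.arange(25)[:, None] * np.ones((1, 4), dtype=int)
        m = KeywordPeriodMatrix(keywords, list("abcd"), df, np.full(4, 100))
        top = select_top_keywords(m, 17)
        assert top == [f"k{i:02d}" for i in range(24, 7, -1)]

    def test_k_equal_to_candidates_is_identity_ordering(self):
        m = KeywordPeriodMatrix(["a", "b"], ["p"], np.array([[3], [9]]), np.array([10]))
        assert select_top_keywords(m, 2) == ["b", "a"]

    def test_ties_break_lexicographically_matching_sort_oracle(self):
        rng = np.random.default_rng(23)
        keywords = [f"k{i:02d}" for i in range(12)]
        df = rng.integers(0, 3, size=(12, 3))  # many ties
        m = KeywordPeriodMatrix(keywords, list("xyz"), df, np.full(3, 10))
        totals = df.sum(axis=1)
        oracle = [k for _, k in sorted(zip(-totals, keywords))]
        for k in (1, 5, 12):
            assert select_top_keywords(m, k) == oracle[:k]

    def test_nonpositive_or_oversized_k_rejected(self):
        m = KeywordPeriodMatrix(["a", "b"], ["p"], np.array([[1], [2]]), np.array([5]))
        with pytest.raises(ValueError):
            select_top_keywords(m, 0)
        with pytest.raises(ValueError):
            select_top_keywords(m, 3)


class TestCorpusSerialization:
    def test_jsonl_roundtrip(self, tmp_path):
        docs = [make_doc("a", ["x", "y"], dt.date(2012, 1, 5), channel="sns", group="g1"),
                make_doc("b", ["z"], dt.date(2013, 2, 6))]
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(docs, path)
        assert read_corpus_jsonl(path) == docs

    def test_matrix_csv_roundtrip_with_nn_row(self, tmp_path):
        m = KeywordPeriodMatrix(["a", "b"], ["2011", "2012"],
                                np.array([[1, 2], [3, 4]]), np.array([10, 20]))
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = KeywordPeriodMatrix.from_csv(path)
        assert back.keywords == m.keywords
        assert np.array_equal(back.df, m.df) and np.array_equal(back.nn, m.nn)
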