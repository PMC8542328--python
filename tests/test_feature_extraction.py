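import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriseq.feature_extraction import (BASE_CONTENT_COLUMNS, FeatureMatrix,
                                       FeaturePipeline, PsekncConfig,
                                       base_content, build_vocabulary,
                                       count_kmers, extract_features,
                                       fit_tfidf, load_property_table,
                                       pseknc2, pseknc_columns,
                                       standardize_properties, transform_tfidf)

from conftest import make_set, random_set

dna = st.text(alphabet="ACGT", min_size=1, max_size=50)


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


class TestVocabulary:
    def test_k1_entries(self):
        v = build_vocabulary(1, 1)
        assert v.entries == ("A", "C", "G", "T")

    def test_k1_to_3_size_by_enumeration(self):
        # independent enumeration oracle
        expected = len({"".join(t) for k in (1, 2, 3)
                        for t in itertools.product("ACGT", repeat=k)})
        assert expected == 84
        assert len(build_vocabulary(1, 3)) == 84

    def test_ordering(self):
        v = build_vocabulary(1, 2)
        assert v.entries[:4] == ("A", "C", "G", "T")
        assert v.entries[4] == "AA"
        assert v.entries[-1] == "TT"
        assert all(v.index[e] == i for i, e in enumerate(v.entries))

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            build_vocabulary(3, 2)
        with pytest.raises(ValueError):
            build_vocabulary(0, 2)

    def test_memory_guard(self):
        with pytest.raises(ValueError, match="entries"):
            build_vocabulary(1, 20)


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------


def naive_count(sequence, kmer):
    """O(L) substring-scan oracle, overlapping occurrences."""
    k = len(kmer)
    return sum(1 for i in range(len(sequence) - k + 1)
               if sequence[i:i + k] == kmer)


class TestCountKmers:
    def test_distinct_windows(self):
        v = build_vocabulary(2, 2)
        c = count_kmers("ACGT", v).counts
        nonzero = {v.entries[i]: int(c[i]) for i in np.flatnonzero(c)}
        assert nonzero == {"AC": 1, "CG": 1, "GT": 1}

    def test_overlapping_windows(self):
        v = build_vocabulary(2, 2)
        c = count_kmers("AAAA", v).counts
        assert c[v.index["AA"]] == 3
        assert c.sum() == 3

    def test_n_windows_skipped(self):
        v = build_vocabulary(2, 2)
        c = count_kmers("ANAT", v).counts
        nonzero = {v.entries[i]: int(c[i]) for i in np.flatnonzero(c)}
        assert nonzero == {"AT": 1}

    def test_short_sequence_all_zero(self):
        v = build_vocabulary(3, 3)
        assert count_kmers("AC", v).counts.sum() == 0

    def test_bad_alphabet(self):
        v = build_vocabulary(1, 1)
        with pytest.raises(ValueError, match="non-ACGTN"):
            count_kmers("ACGU", v)

    def test_against_substring_oracle(self, rng):
        v = build_vocabulary(1, 3)
        for _ in range(100):
            L = int(rng.integers(1, 51))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            counts = count_kmers(seq, v).counts
            for i, kmer in enumerate(v.entries):
                assert counts[i] == naive_count(seq, kmer)

    def test_oracle_with_n(self, rng):
        v = build_vocabulary(2, 2)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=30))
            counts = count_kmers(seq, v).counts
            for i, kmer in enumerate(v.entries):
                assert counts[i] == naive_count(seq, kmer)

    @given(seq=dna)
    @settings(max_examples=50, deadline=None)
    def test_total_per_k_is_window_count(self, seq):
        v = build_vocabulary(1, 2)
        counts = count_kmers(seq, v).counts
        assert counts[:4].sum() == len(seq)
        assert counts[4:].sum() == max(len(seq) - 1, 0)


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


class TestTfIdf:
    def test_hand_oracle(self, tiny_set):
        # fit on {pos "AC", neg "AA"}: positive counts A=1, C=1, AC=1, sum 3
        v = build_vocabulary(1, 2)
        m = fit_tfidf(tiny_set, v)
        i = v.index["A"]
        assert m.tf[i] == pytest.approx(1 / 3, abs=1e-15)
        assert m.idf[i] == pytest.approx(math.log(2 / 3), abs=1e-15)
        assert m.tfidf[i] == pytest.approx(math.log(2 / 3) / 3, abs=1e-15)

    def test_hand_oracle_transform(self, tiny_set):
        v = build_vocabulary(1, 2)
        m = fit_tfidf(tiny_set, v)
        other = make_set(["AA"], ["AC"])
        fm = transform_tfidf(m, other, v)
        expected = 2 * math.log(2 / 3) / 3
        assert fm.values[0, v.index["A"]] == pytest.approx(expected, abs=1e-15)

    def test_tf_sums_to_one(self, rng):
        s = random_set(rng, 5, 5, 40)
        v = build_vocabulary(1, 3)
        m = fit_tfidf(s, v)
        assert m.tf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_absent_tuple(self, tiny_set):
        v = build_vocabulary(1, 2)
        m = fit_tfidf(tiny_set, v)
        i = v.index["GG"]
        assert m.tf[i] == 0
        assert m.idf[i] == pytest.approx(math.log(2 / 1), abs=1e-15)
        assert m.tfidf[i] == 0

    def test_doc_frequency_bounds(self, rng):
        s = random_set(rng, 4, 4, 30)
        v = build_vocabulary(1, 2)
        m = fit_tfidf(s, v)
        assert m.n_documents == 8
        assert np.all(m.doc_frequency >= 0)
        assert np.all(m.doc_frequency <= 8)

    def test_requires_both_classes(self):
        s = make_set(["ACGT", "GGTT"], [])
        v = build_vocabulary(1, 1)
        with pytest.raises(ValueError, match="both classes"):
            fit_tfidf(s, v)

    def test_all_n_positive_corpus_errors(self):
        s = make_set(["NNNN"], ["ACGT"])
        v = build_vocabulary(2, 2)
        with pytest.raises(ValueError, match="countable"):
            fit_tfidf(s, v)

    def test_all_n_sequence_transforms_to_zero_row(self, tiny_set):
        v = build_vocabulary(1, 2)
        m = fit_tfidf(tiny_set, v)
        fm = transform_tfidf(m, make_set(["NNNN"], ["ACGT"]), v)
        assert np.all(fm.values[0] == 0)

    def test_vocab_mismatch_errors(self, tiny_set):
        m = fit_tfidf(tiny_set, build_vocabulary(1, 2))
        with pytest.raises(ValueError, match="mismatch"):
            transform_tfidf(m, tiny_set, build_vocabulary(1, 3))

    def test_transform_deterministic(self, rng):
        s = random_set(rng, 4, 4, 30)
        v = build_vocabulary(1, 2)
        m = fit_tfidf(s, v)
        a = transform_tfidf(m, s, v)
        b = transform_tfidf(m, s, v)
        assert np.array_equal(a.values, b.values)

    def test_log_base_rescales(self, tiny_set):
        v = build_vocabulary(1, 2)
        nat = fit_tfidf(tiny_set, v)
        b10 = fit_tfidf(tiny_set, v, log_base=10)
        np.testing.assert_allclose(b10.idf * math.log(10), nat.idf, atol=1e-12)

    def test_frozen_after_transform(self, tiny_set, rng):
        # transforming unseen data must not mutate the model
        v = build_vocabulary(1, 2)
        m = fit_tfidf(tiny_set, v)
        before = (m.tf.copy(), m.idf.copy(), m.tfidf.copy())
        transform_tfidf(m, random_set(rng, 3, 3, 25), v)
        assert np.array_equal(m.tf, before[0])
        assert np.array_equal(m.idf, before[1])
        assert np.array_equal(m.tfidf, before[2])


# ---------------------------------------------------------------------------
# Base content
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class TestBaseContent:
    def test_symmetric_composition(self):
        b = base_content("ATGC")
        assert b.at_profile == 0.5
        assert b.gc_profile == 0.5
        assert b.gc_skew == 0
        assert b.at_skew == 0

    def test_direct_count_oracle(self):
        b = base_content("GGC")
        assert b.gc_skew == pytest.approx((2 - 1) / 3)
        assert b.gc_profile == 1.0

    def test_degenerate_at(self):
        b = base_content("GGGG")
        assert b.gc_skew == 1.0
        assert b.at_skew == 0.0
        assert b.at_degenerate
        assert not b.gc_degenerate

    def test_all_n_errors(self):
        with pytest.raises(ValueError, match="countable"):
            base_content("NNN")

    def test_n_excluded_from_counts(self):
        assert base_content("ANT").at_profile == 1.0

    @given(seq=dna)
    @settings(max_examples=100, deadline=None)
    def test_profiles_sum_to_one(self, seq):
        b = base_content(seq)
        assert b.at_profile + b.gc_profile == pytest.approx(1.0, abs=1e-12)
        assert -1 <= b.gc_skew <= 1
        assert -1 <= b.at_skew <= 1

    @given(seq=dna)
    @settings(max_examples=100, deadline=None)
    def test_complement_negates_skews(self, seq):
        b = base_content(seq)
        c = base_content(seq.translate(_COMPLEMENT))
        assert c.gc_skew == pytest.approx(-b.gc_skew, abs=1e-12)
        assert c.at_skew == pytest.approx(-b.at_skew, abs=1e-12)
        assert c.at_profile == pytest.approx(b.at_profile, abs=1e-12)
        assert c.gc_profile == pytest.approx(b.gc_profile, abs=1e-12)

    @given(seq=dna)
    @settings(max_examples=50, deadline=None)
    def test_reversal_invariance(self, seq):
        assert base_content(seq) == base_content(seq[::-1])


# ---------------------------------------------------------------------------
# PseKNC type II
# ---------------------------------------------------------------------------


def brute_force_pseknc(sequence, k, lam, w, props):
    """Independent loop implementation. props: dict dinuc -> list of values."""
    L = len(sequence)
    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    counts = [naive_count(sequence, km) for km in kmers]
    total = sum(counts)
    freqs = [c / total for c in counts]
    if lam == 0:
        return freqs
    n_props = len(next(iter(props.values())))
    thetas = []
    for j in range(1, lam + 1):
        for q in range(n_props):
            acc = 0.0
            for m in range(1, L - j):  # 1-based m up to L-j-1
                d1 = sequence[m - 1:m + 1]
                d2 = sequence[m + j - 1:m + j + 1]
                acc += props[d1][q] * props[d2][q]
            thetas.append(acc / (L - j - 1))
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


class TestPseknc:
    def test_lambda_zero_is_composition(self):
        cfg = PsekncConfig(k=2, lam=0)
        seq = "ACGTACGTAC"
        out = pseknc2(seq, cfg)
        v = build_vocabulary(2, 2)
        counts = count_kmers(seq, v).counts
        np.testing.assert_allclose(out, counts / counts.sum(), atol=1e-15)

    def test_sums_to_one(self, rng):
        cfg = PsekncConfig(k=3, lam=2)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            assert pseknc2(seq, cfg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension(self):
        cfg = PsekncConfig(k=3, lam=2)
        assert cfg.dimension == 64 + 2 * 6
        assert len(pseknc2("ACGT" * 10, cfg)) == cfg.dimension
        assert len(pseknc_columns(cfg)) == cfg.dimension

    def test_homopolymer_theta_is_h_squared(self):
        # single property: on "A"*10 every correlation term is H(AA)^2
        h = 1.7
        table = pd.DataFrame({"prop": [h] + [0.0] * 15},
                             index=["".join(t) for t in
                                    itertools.product("ACGT", repeat=2)])
        cfg = PsekncConfig(k=1, lam=3, w=0.5, properties=table)
        out = pseknc2("A" * 10, cfg)
        denom = 1 + 0.5 * 3 * h ** 2
        np.testing.assert_allclose(out[:4], np.array([1, 0, 0, 0]) / denom,
                                   atol=1e-12)
        np.testing.assert_allclose(out[4:], 0.5 * h ** 2 / denom, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        cfg = PsekncConfig(k=2, lam=3, w=0.7)
        props = {d: list(cfg.properties.loc[d]) for d in cfg.properties.index}
        for _ in range(20):
            L = int(rng.integers(10, 30))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            expected = brute_force_pseknc(seq, 2, 3, 0.7, props)
            np.testing.assert_allclose(pseknc2(seq, cfg), expected, atol=1e-10)

    def test_lambda_too_large_errors(self):
        cfg = PsekncConfig(k=2, lam=10)
        with pytest.raises(ValueError, match="lam"):
            pseknc2("ACGTACGT", cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PsekncConfig(k=0)
        with pytest.raises(ValueError):
            PsekncConfig(lam=-1)
        with pytest.raises(ValueError):
            PsekncConfig(w=0)
        with pytest.raises(ValueError):
            PsekncConfig(w=1.5)

    def test_default_properties_standardized(self):
        cfg = PsekncConfig()
        table = cfg.properties
        assert table.shape == (16, 6)
        np.testing.assert_allclose(table.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(table.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_property_table_missing_dinuc_rejected(self, tmp_path):
        p = tmp_path / "props.tsv"
        p.write_text("dinucleotide\tx\nAA\t1.0\n")
        with pytest.raises(ValueError, match="missing"):
            load_property_table(p)

    def test_constant_property_rejected(self):
        raw = load_property_table()
        raw["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            standardize_properties(raw)


# ---------------------------------------------------------------------------
# extract_features / FeatureMatrix / FeaturePipeline
# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_base_content_shape(self, rng):
        s = random_set(rng, 3, 3, 20)
        fm = extract_features(s, "base_content")
        assert fm.values.shape == (6, 4)
        assert fm.columns == list(BASE_CONTENT_COLUMNS)
        assert np.array_equal(fm.labels, s.labels)

    def test_pseknc_combined_dimension(self, rng):
        s = random_set(rng, 2, 2, 40)
        lam = 2
        configs = [PsekncConfig(k=k, lam=lam) for k in (1, 2, 3)]
        fm = extract_features(s, "pseknc", pseknc_configs=configs)
        assert fm.n_features == sum(4 ** k for k in (1, 2, 3)) + 3 * lam * 6

    def test_tfidf_plus_base_dimension(self, rng):
        s = random_set(rng, 3, 3, 30)
        fm = extract_features(s, ["tfidf", "base_content"])
        assert fm.n_features == 5460 + 4

    def test_empty_method_list_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_features(random_set(rng, 2, 2, 10), [])

    def test_unknown_method_errors(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            extract_features(random_set(rng, 2, 2, 10), "onehot")


class TestFeatureMatrix:
    def test_tsv_round_trip_exact(self, tmp_path, rng):
        fm = FeatureMatrix(values=rng.normal(size=(5, 3)),
                           columns=["a", "b", "c"],
                           labels=np.array([1, 1, 0, 0, 0], dtype=np.int8),
                           ids=[f"s{i}" for i in range(5)])
        path = tmp_path / "m.tsv"
        fm.to_tsv(path)
        again = FeatureMatrix.from_tsv(path)
        assert np.array_equal(again.values, fm.values)  # bit-identical
        assert again.columns == fm.columns
        assert np.array_equal(again.labels, fm.labels)
        assert again.ids == fm.ids

    def test_select_columns(self, rng):
        fm = FeatureMatrix(values=np.arange(6.0).reshape(2, 3),
                           columns=["a", "b", "c"],
                           labels=np.array([1, 0]), ids=["x", "y"])
        sub = fm.select_columns(["c", "a"])
        assert sub.columns == ["c", "a"]
        assert np.array_equal(sub.values, [[2.0, 0.0], [5.0, 3.0]])

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(values=np.zeros((1, 2)), columns=["a", "a"],
                          labels=np.array([1]), ids=["x"])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureMatrix(values=np.array([[np.nan]]), columns=["a"],
                          labels=np.array([1]), ids=["x"])

    def test_hstack_alignment_enforced(self, rng):
        a = FeatureMatrix(values=np.zeros((2, 1)), columns=["a"],
                          labels=np.array([1, 0]), ids=["x", "y"])
        b = FeatureMatrix(values=np.zeros((2, 1)), columns=["b"],
                          labels=np.array([1, 0]), ids=["x", "z"])
        with pytest.raises(ValueError, match="aligned"):
            FeatureMatrix.hstack([a, b])


class TestFeaturePipeline:
    def test_unfitted_tfidf_transform_errors(self, rng):
        pipe = FeaturePipeline(methods=["tfidf"], k_max=2)
        with pytest.raises(ValueError, match="not fitted"):
            pipe.transform(random_set(rng, 2, 2, 10))

    def test_fit_freezes_tfidf(self, rng):
        train = random_set(rng, 4, 4, 30)
        test = random_set(rng, 3, 3, 30)
        pipe = FeaturePipeline(methods=["tfidf"], k_max=2)
        pipe.fit(train)
        tf_before = pipe.tfidf_model.tf.copy()
        a = pipe.transform(test)
        b = pipe.transform(test)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(pipe.tfidf_model.tf, tf_before)

    def test_selected_columns_subset(self, rng):
        s = random_set(rng, 3, 3, 20)
        pipe = FeaturePipeline(methods=["base_content"],
                               selected_columns=["base:gc_skew"])
        fm = pipe.fit_transform(s)
        assert fm.columns == ["base:gc_skew"]
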