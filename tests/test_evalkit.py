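import numpy as np
import pytest
from hypothesis import given, strategies as st

import medterm as mt
from medterm.evalkit import (
    ConfusionCounts,
    cosine_similarity,
    evaluate_pairs,
    precision_recall_f1,
    read_term_pairs,
    spearman_correlation,
    token_coverage,
)

from conftest import brute_force_spearman

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=8
).filter(lambda v: np.linalg.norm(v) > 1e-100)


class TestCosine:
    def test_identical_direction(self):
        assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form_45_degrees(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 0], [1, 0, 0])

    @given(finite_vectors)
    def test_self_similarity_is_one(self, v):
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    @given(finite_vectors, st.integers(0, 10_000))
    def test_symmetry(self, v, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(len(v))
        assert cosine_similarity(v, w) == pytest.approx(cosine_similarity(w, v))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert spearman_correlation([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        assert spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(
            0.6, abs=1e-9
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_unequal_or_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [1, 2])

    def test_matches_brute_force_with_ties(self):
        """1000 random instances (n <= 30, integer values to force ties)
        agree with an explicit rank-then-Pearson implementation to 1e-9."""
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(3, 31))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 8, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman_correlation(list(x), list(y)) == pytest.approx(
                brute_force_spearman(x, y), abs=1e-9
            )
            checked += 1

    def test_invariant_to_increasing_transform(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert spearman_correlation(list(np.exp(x)), list(y)) == pytest.approx(
            spearman_correlation(list(x), list(y)), abs=1e-12
        )


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (1, 0, 0, (1.0, 1.0, 1.0)),
            (0, 5, 5, (0.0, 0.0, None)),
            (3, 1, 2, (0.75, 0.6, 2 * 0.75 * 0.6 / 1.35)),
        ],
    )
    def test_closed_forms(self, tp, fp, fn, expected):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert p == pytest.approx(expected[0])
        assert r == pytest.approx(expected[1])
        if expected[2] is None:
            assert f1 is None
        else:
            assert f1 == pytest.approx(expected[2], abs=1e-4)

    def test_none_propagation_when_undefined(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(0, 0, 3))
        assert p is None and f1 is None

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f1_between_harmonic_bounds(self, tp, fp, fn):
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert f1 <= min(2 * p, 2 * r) + 1e-12
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestEvaluatePairs:
    def test_constructed_perfect_case(self, lexicon, seg_model):
        pairs, emb = mt.generate_pair_dataset(
            mt.SynthConfig(n_terms=30, seed=17, noise_sd=0.0), lexicon
        )
        report = evaluate_pairs(pairs, emb, lexicon, seg_model)
        assert report.coverage_pct == pytest.approx(100.0)
        assert report.spearman == pytest.approx(1.0)

    def test_uncovered_pair_excluded(self, lexicon, seg_model):
        emb = mt.EmbeddingSource({"heart": np.array([1.0, 0.0]), "lung": np.array([0.0, 1.0]), "hip": np.array([1.0, 1.0])})
        pairs = [
            mt.TermPair("heart", "lung", 3.0),
            mt.TermPair("heart", "hip", 2.0),
            mt.TermPair("heart", "qqqqzz", 1.0),
        ]
        report = evaluate_pairs(pairs, emb, stages={"direct"})
        assert report.n_total == 3 and report.n_covered == 2
        assert report.coverage_pct == pytest.approx(100 * 2 / 3)

    def test_coverage_monotone_in_stages(self, lexicon, seg_model):
        pairs, emb = mt.generate_pair_dataset(
            mt.SynthConfig(n_terms=25, seed=31, noise_sd=0.1), lexicon
        )
        direct = evaluate_pairs(pairs, emb, lexicon, seg_model, stages={"direct"})
        full = evaluate_pairs(pairs, emb, lexicon, seg_model)
        assert direct.coverage_pct <= full.coverage_pct

    def test_pair_order_invariance(self, lexicon, seg_model):
        pairs, emb = mt.generate_pair_dataset(
            mt.SynthConfig(n_terms=12, seed=8, noise_sd=0.05), lexicon
        )
        a = evaluate_pairs(pairs, emb, lexicon, seg_model)
        b = evaluate_pairs(list(reversed(pairs)), emb, lexicon, seg_model)
        assert a.coverage_pct == b.coverage_pct
        assert a.spearman == pytest.approx(b.spearman, abs=1e-12)

    def test_empty_pairs_rejected(self, meaning_embedding):
        with pytest.raises(ValueError):
            evaluate_pairs([], meaning_embedding)


class TestTokenCoverage:
    def test_histogram(self, lexicon, seg_model, meaning_embedding):
        tokens = ["breathing", "dyspnea", "qqqq"]
        hist = token_coverage(tokens, meaning_embedding, lexicon, seg_model)
        assert hist["direct"] == 1
        assert hist["parser"] == 1
        assert hist["unresolved"] == 1


class TestReadTermPairs:
    def test_csv_parse(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text("heart,cardiac,3.5\nlung,renal,1.0\n")
        pairs = read_term_pairs(p)
        assert pairs[0] == mt.TermPair("heart", "cardiac", 3.5)
        assert len(pairs) == 2

    def test_tab_dialect_sniffed(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("heart\tcardiac\t3.5\n")
        assert read_term_pairs(p)[0].term2 == "cardiac"

    def test_header_auto_skipped(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text("term1,term2,score\nheart,cardiac,3.5\n")
        pairs = read_term_pairs(p)
        assert len(pairs) == 1

    def test_malformed_rows_skipped_with_log(self, tmp_path, caplog):
        p = tmp_path / "pairs.csv"
        p.write_text("heart,cardiac,3.5\nbroken-row\nlung,renal,1.0\n")
        with caplog.at_level("WARNING"):
            pairs = read_term_pairs(p)
        assert len(pairs) == 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_term_pairs(p)

    def test_column_positions_configurable(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text("3.5,heart,cardiac\n")
        pairs = read_term_pairs(p, columns=(1, 2, 0))
        assert pairs[0] == mt.TermPair("heart", "cardiac", 3.5)
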