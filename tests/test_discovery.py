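"""Reversal-pair identification, ranking, k selection, fold-change summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from reosig import (
    ExpressionMatrix,
    Orientation,
    PhenotypeLabels,
    ReversalPair,
    ValidationError,
    classify_sample,
    cross_platform_filter,
    discover,
    find_reversal_pairs,
    fold_change_summary,
    pair_frequency_table,
    rank_and_select_k,
    reversal_coverage_rate,
    stable_pairs,
)
from reosig.classify import metrics_from_counts
from reosig.discovery import smallest_odd_argmax
from reosig.pairs import StablePairSet


def _stable_set(entries, group="g", threshold=0.9):
    """Build a StablePairSet from (gene_i, gene_j, orientation, freq) tuples."""
    df = pd.DataFrame(
        {
            "gene_i": [e[0] for e in entries],
            "gene_j": [e[1] for e in entries],
            "orientation": [e[2] for e in entries],
            f"freq_{group}": [e[3] for e in entries],
        }
    )
    return StablePairSet(pairs=df, threshold=threshold, groups=(group,))


class TestFindReversalPairs:
    def test_opposite_orientations_become_reversal(self):
        ref = _stable_set([("A", "B", Orientation.I_GREATER, 0.95)])
        alt = _stable_set([("A", "B", Orientation.J_GREATER, 0.92)])
        (pair,) = find_reversal_pairs(ref, alt)
        assert pair.reference_orientation is Orientation.I_GREATER
        assert pair.freq_reference == 0.95
        assert pair.freq_alternative == 0.92

    def test_same_orientation_excluded(self):
        ref = _stable_set([("A", "B", Orientation.I_GREATER, 0.95)])
        alt = _stable_set([("A", "B", Orientation.I_GREATER, 0.99)])
        assert find_reversal_pairs(ref, alt) == []

    def test_disjoint_sets_give_empty_list(self):
        ref = _stable_set([("A", "B", Orientation.I_GREATER, 0.95)])
        alt = _stable_set([("C", "D", Orientation.J_GREATER, 0.95)])
        assert find_reversal_pairs(ref, alt) == []


class TestCoverageRate:
    def test_geometric_mean_value(self):
        pair = ReversalPair("A", "B", Orientation.I_GREATER, 0.96, 0.94)
        assert pair.coverage_rate == pytest.approx(math.sqrt(0.96 * 0.94), abs=1e-12)
        assert pair.coverage_rate == pytest.approx(0.9499473, abs=1e-6)

    def test_perfect_reversal(self):
        assert ReversalPair("A", "B", Orientation.I_GREATER, 1.0, 1.0).coverage_rate == 1.0

    def test_zero_annihilates(self):
        assert ReversalPair("A", "B", Orientation.I_GREATER, 1.0, 0.0).coverage_rate == 0.0

    def test_recomputed_on_training_data(self):
        # A > B in all 4 normal samples; B > A in 3 of 4 cancer samples
        values = pd.DataFrame(
            [[5, 5, 5, 5, 1, 1, 1, 5.5], [2, 2, 2, 2, 3, 3, 3, 3]],
            index=["A", "B"],
            columns=[f"s{i}" for i in range(8)],
            dtype=float,
        )
        m = ExpressionMatrix(values)
        labels = PhenotypeLabels(
            classes=pd.Series(
                ["normal"] * 4 + ["cancer"] * 4, index=[f"s{i}" for i in range(8)]
            )
        )
        pair = ReversalPair("A", "B", Orientation.I_GREATER, 0.9, 0.9)
        rate = reversal_coverage_rate(pair, m, labels, ["normal"], "cancer")
        assert rate == pytest.approx(math.sqrt(1.0 * 0.75), abs=1e-12)

    def test_monotone_transform_leaves_rate_unchanged(self, small_cohort):
        from reosig import apply_sample_monotone_batch

        matrix, labels, truth = small_cohort
        pair = ReversalPair(
            truth.pairs[0].gene_i,
            truth.pairs[0].gene_j,
            truth.pairs[0].reference_orientation,
            0.9,
            0.9,
        )
        r1 = reversal_coverage_rate(pair, matrix, labels, ["normal"], "cancer")
        r2 = reversal_coverage_rate(
            pair,
            apply_sample_monotone_batch(matrix, seed=99),
            labels,
            ["normal"],
            "cancer",
        )
        assert r1 == r2


class TestCrossPlatformFilter:
    @pytest.fixture
    def platform2(self):
        """20 reference + 20 alternative samples; pair (A,B) reverses at
        19/20 and 19/20; pair (C,D) holds in only 17/20 reference samples;
        gene F is unmeasured."""
        n = 20
        cols = [f"r{i}" for i in range(n)] + [f"a{i}" for i in range(n)]
        A = [5.0] * n + [1.0] * n
        A[3] = 1.0  # one reference sample breaks A > B
        A[n + 5] = 9.0  # one alternative sample breaks B > A
        B = [3.0] * 2 * n
        C = [5.0] * n + [1.0] * n
        for i in (0, 1, 2):
            C[i] = 1.0  # 17/20 reference samples keep C > D
        D = [3.0] * 2 * n
        m = ExpressionMatrix(
            pd.DataFrame([A, B, C, D], index=["A", "B", "C", "D"], columns=cols)
        )
        labels = PhenotypeLabels(
            classes=pd.Series(["normal"] * n + ["cancer"] * n, index=cols)
        )
        return m, labels

    def _pairs(self):
        return [
            ReversalPair("A", "B", Orientation.I_GREATER, 0.95, 0.95),
            ReversalPair("C", "D", Orientation.I_GREATER, 0.95, 0.95),
            ReversalPair("E", "F", Orientation.I_GREATER, 0.95, 0.95),
        ]

    def test_threshold_rule_and_missing_gene(self, platform2):
        m, labels = platform2
        out = cross_platform_filter(self._pairs(), m, labels, ["normal"], "cancer", 0.9)
        kept = {(p.gene_i, p.gene_j) for p in out.kept}
        assert kept == {("A", "B")}  # 0.95/0.95 on platform 2
        reasons = {(p.gene_i, p.gene_j): r for p, r in out.dropped}
        assert "below threshold" in reasons[("C", "D")]  # 17/20 = 0.85 < 0.9
        assert "not measured" in reasons[("E", "F")]

    def test_raising_threshold_never_enlarges(self, platform2):
        m, labels = platform2
        kept_090 = cross_platform_filter(
            self._pairs(), m, labels, ["normal"], "cancer", 0.90
        ).kept
        kept_099 = cross_platform_filter(
            self._pairs(), m, labels, ["normal"], "cancer", 0.99
        ).kept
        assert {(p.gene_i, p.gene_j) for p in kept_099} <= {
            (p.gene_i, p.gene_j) for p in kept_090
        }

    def test_missing_class_is_error(self, platform2):
        m, _ = platform2
        labels = PhenotypeLabels(
            classes=pd.Series(["normal"] * m.n_samples, index=m.sample_ids)
        )
        with pytest.raises(ValidationError):
            cross_platform_filter(self._pairs(), m, labels, ["normal"], "cancer", 0.9)


class TestKSelection:
    def test_smallest_odd_argmax_rule(self):
        assert smallest_odd_argmax({1: 0.90, 3: 0.95, 5: 0.95}) == 3
        assert smallest_odd_argmax({1: 0.99}) == 1
        assert smallest_odd_argmax({1: 0.5, 3: 0.5, 5: 0.5}) == 1

    def test_single_pair_selects_k1(self, small_cohort):
        matrix, labels, truth = small_cohort
        p = truth.pairs[0]
        pair = ReversalPair(p.gene_i, p.gene_j, p.reference_orientation, 0.9, 0.9)
        ranked = rank_and_select_k([pair], matrix, labels, ["normal"], "cancer")
        assert ranked.selected_k == 1

    def test_matches_independent_exhaustive_scan(self, small_cohort):
        """Vectorized per-k scoring equals a literal classify-and-count scan."""
        matrix, labels, truth = small_cohort
        result = discover(matrix, labels, ["normal"], "cancer", 0.9)
        ranked = result.ranked

        scores = {}
        for k in range(1, len(ranked.pairs) + 1, 2):
            sig = ranked.signature(k)
            tp = fn = tn = fp = ind_pos = ind_neg = 0
            for s in matrix.sample_ids:
                call = classify_sample(sig, matrix.values[s], sample_id=s).call
                positive = labels.class_of(s) == "cancer"
                if call == "indeterminate":
                    ind_pos, ind_neg = ind_pos + positive, ind_neg + (not positive)
                elif call == sig.alternative_class:
                    tp, fp = tp + positive, fp + (not positive)
                else:
                    fn, tn = fn + positive, tn + (not positive)
            m = metrics_from_counts(tp, tn, fp, fn, ind_pos, ind_neg)
            scores[k] = m.geometric_mean
        assert smallest_odd_argmax(scores) == ranked.selected_k
        for row in ranked.scores.itertuples(index=False):
            assert row.geometric_mean == pytest.approx(scores[row.k], abs=1e-12)

    def test_coverage_rates_non_increasing(self, small_cohort):
        matrix, labels, _ = small_cohort
        ranked = discover(matrix, labels, ["normal"], "cancer", 0.9).ranked
        rates = [p.coverage_rate for p in ranked.pairs]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_planted_pairs_recovered(self, small_cohort):
        matrix, labels, truth = small_cohort
        found = {
            (p.gene_i, p.gene_j)
            for p in discover(matrix, labels, ["normal"], "cancer", 0.9).ranked.pairs
        }
        assert truth.pair_keys() <= found


class TestFoldChangeSummary:
    @pytest.fixture
    def ratio_matrix(self):
        values = pd.DataFrame(
            {
                "n1": [1.0, 1.0],
                "n2": [2.0, 1.0],
                "n3": [3.0, 1.0],
                "c1": [0.5, 1.0],
                "c2": [np.nan, 1.0],
            },
            index=["A", "B"],
        )
        labels = PhenotypeLabels(
            classes=pd.Series(
                {"n1": "normal", "n2": "normal", "n3": "normal", "c1": "cancer", "c2": "cancer"}
            )
        )
        return ExpressionMatrix(values), labels

    def test_order_statistics(self, ratio_matrix):
        m, labels = ratio_matrix
        out = fold_change_summary(m, labels, "A", "B")
        assert out.loc["normal", ["min", "median", "max"]].tolist() == [1.0, 2.0, 3.0]

    def test_masked_sample_excluded_and_single_sample_class(self, ratio_matrix):
        m, labels = ratio_matrix
        out = fold_change_summary(m, labels, "A", "B")
        assert out.loc["cancer", "n"] == 1  # c2 masked out
        assert (
            out.loc["cancer", "min"]
            == out.loc["cancer", "median"]
            == out.loc["cancer", "max"]
            == 0.5
        )

    def test_nonpositive_denominator_names_sample(self, ratio_matrix):
        m, labels = ratio_matrix
        bad = m.values.copy()
        bad.loc["B", "n2"] = 0.0
        with pytest.raises(ValidationError, match="n2"):
            fold_change_summary(ExpressionMatrix(bad), labels, "A", "B")
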