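"""Concordance, ±k-rank agreement, 2×2 diagnostics, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uristrip.errors import EvaluationError
from uristrip.evaluation import (
    ConcordanceRecord,
    CrossTable2x2,
    concordance_rate,
    crosstable_from_ranks,
    mean_over_analytes,
    read_records_csv,
    roc_curve_auc,
    sensitivity_specificity,
    summarize_by_analyte,
    within_rank_rate,
    write_summary_csv,
)
from uristrip.synth import demo_layout


def _records(pairs, analyte="albumin"):
    return [ConcordanceRecord(analyte, p, r) for p, r in pairs]


def _auc_pair_count(scores, labels):
    """O(n²) oracle: P(score_pos > score_neg) with ties counting 0.5."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConcordance:
    def test_all_equal_is_100(self):
        assert concordance_rate(_records([(0, 0), (2, 2)])) == 100.0

    def test_three_of_four(self):
        assert concordance_rate(_records([(0, 0), (1, 1), (2, 2), (0, 1)])) == 75.0

    def test_matches_brute_force_recount(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            pairs = [(int(rng.integers(5)), int(rng.integers(5))) for _ in range(n)]
            expected = 100.0 * sum(p == r for p, r in pairs) / n
            assert concordance_rate(_records(pairs)) == pytest.approx(
                expected, abs=0.05 + 1e-9
            )

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            concordance_rate([])

    def test_accepts_dataframe(self):
        df = pd.DataFrame({"program_rank": [0, 1], "reference_rank": [0, 2]})
        assert concordance_rate(df) == 50.0


class TestWithinRank:
    def test_k0_reduces_to_exact(self, rng):
        pairs = [(int(rng.integers(4)), int(rng.integers(4))) for _ in range(30)]
        recs = _records(pairs)
        assert within_rank_rate(recs, k=0) == concordance_rate(recs)

    def test_worked_example(self):
        assert within_rank_rate(_records([(0, 1), (2, 1), (0, 3)]), k=1) == 66.7

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=40
        )
    )
    def test_monotone_in_k(self, pairs):
        recs = _records(pairs)
        rates = [within_rank_rate(recs, k=k) for k in range(7)]
        assert all(a <= b for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 100.0

    def test_negative_k_rejected(self):
        with pytest.raises(EvaluationError):
            within_rank_rate(_records([(0, 0)]), k=-1)


class TestSummaries:
    def test_exact_never_exceeds_within1(self, rng):
        rows = []
        for analyte in ("protein", "glucose", "pH"):
            for _ in range(40):
                rows.append(
                    {
                        "analyte": analyte,
                        "program_rank": int(rng.integers(5)),
                        "reference_rank": int(rng.integers(5)),
                    }
                )
        summary = summarize_by_analyte(pd.DataFrame(rows))
        assert (summary["exact_pct"] <= summary["within1_pct"]).all()
        me, mw = mean_over_analytes(summary["exact_pct"], summary["within1_pct"])
        assert me <= mw

    def test_single_analyte_mean_is_itself(self):
        assert mean_over_analytes([83.1], [100.0]) == (83.1, 100.0)

    def test_summary_round_trip_via_csv(self, tmp_path, rng):
        rows = []
        for analyte in ("protein", "albumin"):
            for i in range(25):
                rows.append(
                    {
                        "specimen_id": f"s{i:04d}",
                        "analyte": analyte,
                        "program_rank": int(rng.integers(4)),
                        "reference_rank": int(rng.integers(4)),
                    }
                )
        df = pd.DataFrame(rows)
        p = tmp_path / "records.csv"
        df.to_csv(p, index=False)
        again = read_records_csv(p)
        assert summarize_by_analyte(again).equals(summarize_by_analyte(df))
        write_summary_csv(summarize_by_analyte(df), tmp_path / "summary.csv")
        out = pd.read_csv(tmp_path / "summary.csv")
        assert list(out["analyte"])[-1] == "mean"


class TestSensitivitySpecificity:
    def test_worked_2x2(self):
        sens, spec = sensitivity_specificity(CrossTable2x2(tp=13, fp=12, fn=0, tn=17))
        assert (sens, spec) == (100.0, 58.6)

    def test_perfect_table(self):
        assert sensitivity_specificity(CrossTable2x2(1, 0, 0, 1)) == (100.0, 100.0)

    def test_all_missed_positives(self):
        sens, _ = sensitivity_specificity(CrossTable2x2(tp=0, fp=1, fn=5, tn=4))
        assert sens == 0.0

    def test_scaling_invariance(self):
        a = sensitivity_specificity(CrossTable2x2(13, 12, 0, 17))
        b = sensitivity_specificity(CrossTable2x2(39, 36, 0, 51))
        assert a == b

    @pytest.mark.parametrize("ct", [CrossTable2x2(0, 1, 0, 1), CrossTable2x2(1, 0, 1, 0)])
    def test_empty_margin_rejected(self, ct):
        with pytest.raises(EvaluationError):
            sensitivity_specificity(ct)

    def test_crosstable_from_ranks(self):
        prog = [1, 1, 0, 0, 2]
        disease = [True, False, True, False, True]
        ct = crosstable_from_ranks(prog, disease, threshold_rank=1)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (2, 1, 1, 1)


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_curve_auc([0, 1, 2, 3], [0, 0, 1, 1])
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        _, auc = roc_curve_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 30))
            scores = rng.integers(0, 4, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_curve_auc(scores, labels)
            assert auc == pytest.approx(_auc_pair_count(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve_auc([1.0, 2.0], [1, 1])

    def test_binary_reduction_bounds_balanced_accuracy(self):
        # AUC of a thresholded score equals (sens+spec)/2; ordinal scores
        # can only do better, which is why a reader's AUC may exceed it
        prog = np.array([2, 1, 1, 0, 0, 0, 3, 1])
        disease = np.array([1, 1, 0, 0, 0, 0, 1, 0], dtype=bool)
        ct = crosstable_from_ranks(prog, disease, threshold_rank=1)
        sens, spec = sensitivity_specificity(ct)
        _, auc_binary = roc_curve_auc((prog >= 1).astype(float), disease)
        assert auc_binary == pytest.approx((sens + spec) / 200.0, abs=1e-9)
        _, auc_ordinal = roc_curve_auc(prog.astype(float), disease)
        assert auc_ordinal >= auc_binary - 1e-12


class TestReadRecords:
    def test_label_mapping_through_layout(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "specimen_id,analyte,program_label,reference_label\n"
            's1,albumin,"30","30"\n'
            's2,albumin,"10","30"\n'
            's3,albumin,"150","999"\n'  # unmappable reference → dropped
        )
        df = read_records_csv(p, layout=demo_layout())
        assert len(df) == 2
        assert list(df["program_rank"]) == [1, 0]

    def test_missing_column_reported(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("specimen_id,analyte,program_label\ns1,albumin,30\n")
        with pytest.raises(EvaluationError, match="reference_label"):
            read_records_csv(p, layout=demo_layout())

    def test_empty_csv_rejected(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("")
        with pytest.raises(EvaluationError):
            read_records_csv(p, layout=demo_layout())
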