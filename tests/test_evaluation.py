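import math

import numpy as np
import pytest

from memtop.decoder import labels_to_segments
from memtop.evaluation import (
    confidence_interval,
    evaluate_folds,
    evaluate_split,
    match_segments,
    protein_class,
    protein_metrics,
    segment_metrics,
    significant_difference,
)
from memtop.io_formats import Segment


def H(start, end, d="in_out"):
    return Segment("TMH", start, end, d)


class TestProteinClass:
    def test_basic_classes(self):
        assert protein_class("i" * 30) == ("globular", False)
        assert protein_class("iii" + "H" * 21 + "ooo") == ("alpha", False)
        assert protein_class("S" * 10 + "o" * 20)[1] is True

    def test_mixed_b_and_h_is_beta(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cls, _ = protein_class("iii" + "B" * 9 + "ooo" + "h" * 21 + "iii")
        assert cls == "beta"


class TestMatching:
    def test_overlap_within_tolerance(self):
        m = match_segments([H(10, 31)], [H(12, 34)])[0]
        # intersection 19, union 24 -> IoU rule holds; deviations 2 and 3
        assert m.correct and m.orientation_correct

    def test_start_deviation_binds_despite_iou(self):
        m = match_segments([H(10, 31)], [H(16, 37)])[0]
        assert not m.correct

    def test_exact_match(self):
        m = match_segments([H(10, 31)], [H(10, 31)])[0]
        assert m.correct and m.orientation_correct
        m2 = match_segments([H(10, 31)], [H(10, 31, "out_in")])[0]
        assert m2.correct and not m2.orientation_correct

    def test_gap_punished(self):
        """A segment split in two matches at most once and fails IoU."""
        matches = match_segments([H(10, 31)], [H(10, 20), H(22, 31)])
        assert sum(m.correct for m in matches) == 0

    def test_correct_at_most_min_counts(self):
        obs = [H(10, 31), H(40, 61)]
        pred = [H(10, 31)]
        matches = match_segments(obs, pred)
        assert sum(m.correct for m in matches) <= 1

    def test_kinds_never_cross_matched(self):
        obs = [Segment("TMB", 10, 19, "in_out")]
        pred = [H(10, 19)]
        m = match_segments(obs, pred)[0]
        assert m.predicted is None


class TestSegmentMetrics:
    def test_all_correct(self):
        segs = [H(5, 26), H(30, 51, "out_in"), H(55, 76)]
        rep = segment_metrics([(segs, segs)], "TMH")
        assert rep == {"recall": 100.0, "precision": 100.0, "q_num": 100.0,
                       "q_ok": 100.0, "q_top": 100.0}

    def test_half_correct_arithmetic(self):
        obs = [H(10, 31), H(40, 61, "out_in")]
        pred = [H(10, 31), H(50, 71, "out_in")]  # second deviates by 10
        rep = segment_metrics([(obs, pred)], "TMH")
        assert rep["recall"] == 50.0 and rep["precision"] == 50.0
        assert rep["q_num"] == 100.0 and rep["q_ok"] == 0.0

    def test_no_predictions_recall_zero_precision_nan(self):
        rep = segment_metrics([([H(10, 31), H(40, 61)], [])], "TMH")
        assert rep["recall"] == 0.0
        assert math.isnan(rep["precision"])

    def test_absent_kind_is_nan(self):
        rep = segment_metrics([([H(10, 31)], [H(10, 31)])], "TMB")
        assert all(math.isnan(v) for v in rep.values())

    def test_qok_bounded_by_qnum(self, rng):
        from memtop.synthetic_data import GeneratorConfig, generate_dataset

        prots, _ = generate_dataset(30, GeneratorConfig(seed=9))
        pairs = []
        for p in prots:
            segs = labels_to_segments(p.labels)
            # corrupt: drop every third segment
            pred = [s for j, s in enumerate(segs) if j % 3]
            pairs.append((segs, pred))
        rep = segment_metrics(pairs, "TMH")
        assert rep["q_ok"] <= rep["q_num"] + 1e-12
        # note: q_ok is a per-protein rate while recall pools segments, so
        # q_ok <= recall holds per protein but not for the pooled quantity

    def test_shift_by_six_kills_recall(self):
        obs = [H(20, 41)]
        pred = [H(26, 47)]
        rep = segment_metrics([(obs, pred)], "TMH")
        assert rep["recall"] == 0.0


class TestProteinMetrics:
    def test_perfect(self):
        pairs = [((c, sp), (c, sp)) for c in ("beta", "alpha", "globular")
                 for sp in (True, False)]
        rep = protein_metrics(pairs)
        for cls in ("beta", "alpha", "globular"):
            assert rep[f"{cls}_recall"] == 100.0
            assert rep[f"{cls}_fpr"] == 0.0
        assert rep["sp_recall"] == 100.0 and rep["sp_fpr"] == 0.0

    def test_fpr_arithmetic(self):
        pairs = [(("globular", False), ("globular", False))] * 9
        pairs += [(("globular", False), ("alpha", False))]
        rep = protein_metrics(pairs)
        assert rep["alpha_fpr"] == pytest.approx(10.0)

    def test_tp_sum_equals_correct_classifications(self):
        pairs = [(("beta", False), ("beta", False)),
                 (("alpha", False), ("globular", False)),
                 (("globular", False), ("globular", False))]
        rep = protein_metrics(pairs)
        tp_total = sum(rep[f"{c}_recall"] / 100 *
                       sum(1 for o, _ in pairs if o[0] == c)
                       for c in ("beta", "alpha", "globular"))
        assert tp_total == pytest.approx(2)


class TestConfidence:
    def test_worked_example(self):
        mean, ci = confidence_interval([1, 2, 3, 4, 5])
        assert mean == 3.0
        assert ci == pytest.approx(1.96 * 1.5811388 / np.sqrt(5), abs=1e-4)
        assert ci == pytest.approx(1.386, abs=1e-3)

    def test_constant_values(self):
        assert confidence_interval([7.0] * 5)[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([1.0])


class TestSignificance:
    def test_boundary_not_significant(self):
        assert significant_difference(10, 3, 5, 4) is False  # |5| > 5 is false

    def test_clear_difference(self):
        assert significant_difference(10, 1.5, 5, 2) is True

    def test_equal_never_significant(self):
        assert significant_difference(4.2, 0.0, 4.2, 0.0) is False


class TestDatasetReports:
    def test_identity_prediction_all_perfect(self):
        from memtop.synthetic_data import GeneratorConfig, generate_dataset

        prots, _ = generate_dataset(24, GeneratorConfig(seed=13))
        refs = {p.record.id: p.labels for p in prots}
        rep = evaluate_split(refs, refs)
        assert rep["residue_accuracy"] == 100.0
        for cls in ("beta", "alpha", "globular"):
            assert rep[f"{cls}_recall"] == 100.0 and rep[f"{cls}_fpr"] == 0.0
        for kind in ("TMB", "TMH", "SP"):
            for metric in ("recall", "precision", "q_num", "q_ok"):
                assert rep[f"{kind}_{metric}"] == 100.0

    def test_folds_summary_has_ci(self):
        from memtop.synthetic_data import GeneratorConfig, generate_dataset

        prots, _ = generate_dataset(40, GeneratorConfig(seed=14))
        refs = {p.record.id: p.labels for p in prots}
        fold_of = {pid: j % 4 for j, pid in enumerate(sorted(refs))}
        rep = evaluate_folds(refs, refs, fold_of)
        assert set(rep["splits"]) == {"0", "1", "2", "3"}
        assert rep["summary"]["residue_accuracy"]["mean"] == 100.0
        assert rep["summary"]["residue_accuracy"]["ci95"] == 0.0

    def test_report_files(self, tmp_path):
        from memtop.evaluation import report_to_json, report_to_tsv
        import json

        rep = {"summary": {"x": {"mean": 1.0, "ci95": 0.1, "per_split": [0.9, 1.1]}}}
        report_to_json(rep, tmp_path / "r.json")
        report_to_tsv(rep, tmp_path / "r.tsv")
        assert json.loads((tmp_path / "r.json").read_text())["summary"]["x"]["mean"] == 1.0
        assert "metric\tmean" in (tmp_path / "r.tsv").read_text()
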