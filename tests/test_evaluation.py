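"""Correct/false/miss matching and the accuracy metric."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlhub import (
    GroundTruthLog,
    PredictedEvent,
    accuracy,
    match_events,
    report_tables,
)

# Published evaluation-table counts for the reference deployment:
# (activity, correct, false, miss, printed accuracy %)
KITCHEN_TABLE = [
    ("breakfast", 16, 1, 3, 80.0),
    ("lunch", 24, 7, 3, 70.6),
    ("dinner", 35, 12, 2, 71.4),
    ("ventilation", 21, 1, 0, 95.4),
    ("washing_dishes", 19, 4, 3, 73.0),
]
BATHROOM_TABLE = [
    ("bowel_movement", 52, 8, 5, 80.0),
    ("urination", 61, 17, 11, 68.5),
    ("shower", 58, 9, 0, 86.5),
    ("ventilation", 17, 3, 2, 77.3),
]


def P(adl, start, end):
    return PredictedEvent(adl, start, end)


class TestMatchEvents:
    def test_exact_match_same_label_is_correct(self):
        truth = GroundTruthLog([P("shower", 100, 200)])
        rep = match_events([P("shower", 100, 200)], truth, ["shower"])
        c = rep.counts("shower")
        assert (c.correct, c.false, c.miss) == (1, 0, 0)

    def test_covering_prediction_with_wrong_label_is_false_for_truth_adl(self):
        truth = GroundTruthLog([P("shower", 100, 200)])
        rep = match_events([P("urination", 80, 220)], truth, ["shower", "urination"])
        c = rep.counts("shower")
        assert (c.correct, c.false, c.miss) == (0, 1, 0)
        assert rep.counts("urination").total == 0

    def test_unmatched_truth_is_a_miss(self):
        truth = GroundTruthLog([P("shower", 100, 200)])
        rep = match_events([], truth, ["shower"])
        assert rep.counts("shower").miss == 1

    def test_insufficient_overlap_is_a_miss(self):
        truth = GroundTruthLog([P("shower", 100, 200)])
        rep = match_events([P("shower", 190, 280)], truth, ["shower"], overlap_frac=0.5)
        c = rep.counts("shower")
        assert (c.correct, c.miss) == (0, 1)

    def test_untargeted_prediction_lands_in_activity_tally(self):
        truth = GroundTruthLog([P("shower", 100, 200)])
        rep = match_events([P("shower", 100, 200), P("reading", 400, 500)],
                           truth, ["shower"])
        assert rep.activity == 1

    def test_one_to_one_matching_never_reuses_a_prediction(self):
        truth = GroundTruthLog([P("shower", 100, 200), P("shower", 300, 400)])
        rep = match_events([P("shower", 100, 200)], truth, ["shower"])
        c = rep.counts("shower")
        assert (c.correct, c.miss) == (1, 1)

    def test_overlapping_truth_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GroundTruthLog([P("a", 0, 100), P("b", 50, 150)])

    def test_result_independent_of_prediction_order(self):
        truth = GroundTruthLog([P("a", 0, 100), P("b", 200, 300)])
        preds = [P("b", 200, 300), P("a", 0, 100), P("c", 400, 500)]
        fwd = match_events(preds, truth, ["a", "b"])
        rev = match_events(list(reversed(preds)), truth, ["a", "b"])
        for adl in ("a", "b"):
            assert vars(fwd.counts(adl)) == vars(rev.counts(adl))
        assert fwd.activity == rev.activity

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_every_truth_entry_is_exactly_one_of_three(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        labels = ["a", "b", "c"]
        truth_entries, t = [], 0.0
        for _ in range(int(rng.integers(1, 8))):
            t += float(rng.uniform(1, 50))
            d = float(rng.uniform(5, 40))
            truth_entries.append(P(str(rng.choice(labels)), t, t + d))
            t += d
        preds = []
        for _ in range(int(rng.integers(0, 10))):
            s = float(rng.uniform(0, t))
            preds.append(P(str(rng.choice(labels + ["x"])), s, s + float(rng.uniform(1, 60))))
        rep = match_events(preds, GroundTruthLog(truth_entries), labels)
        per_label_truth = {lab: sum(1 for e in truth_entries if e.adl == lab) for lab in labels}
        for lab in labels:
            assert rep.counts(lab).total == per_label_truth[lab]


class TestAccuracy:
    @pytest.mark.parametrize("row", KITCHEN_TABLE + BATHROOM_TABLE,
                             ids=lambda r: r[0])
    def test_reproduces_published_table_cells(self, row):
        _, c, f, m, printed = row
        assert accuracy(c, f, m) == pytest.approx(printed, abs=0.15)

    def test_perfect_detection(self):
        assert accuracy(5, 0, 0) == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        assert accuracy(0, 0, 0) is None


class TestReportTables:
    def _report(self, table, space):
        from adlhub import DetectionReport

        rep = DetectionReport(space=space)
        for adl, c, f, m, _ in table:
            counts = rep.counts(adl)
            counts.correct, counts.false, counts.miss = c, f, m
        rep.activity = 55 if space == "kitchen" else 94
        return rep

    def test_kitchen_accuracy_row_computed_to_one_decimal(self):
        rep = self._report(KITCHEN_TABLE, "kitchen")
        order = {"kitchen": [r[0] for r in KITCHEN_TABLE]}
        text = report_tables({"kitchen": rep}, order)["kitchen.csv"]
        acc_line = [l for l in text.splitlines() if l.startswith("Accuracy")][0]
        assert acc_line == "Accuracy,80.0%,70.6%,71.4%,95.5%,73.1%,*"

    def test_bathroom_accuracy_row_computed_to_one_decimal(self):
        rep = self._report(BATHROOM_TABLE, "bathroom")
        order = {"bathroom": [r[0] for r in BATHROOM_TABLE]}
        text = report_tables({"bathroom": rep}, order)["bathroom.csv"]
        acc_line = [l for l in text.splitlines() if l.startswith("Accuracy")][0]
        assert acc_line == "Accuracy,80.0%,68.5%,86.6%,77.3%,*"

    def test_empty_report_renders_header_only(self):
        from adlhub import DetectionReport

        out = report_tables({"empty": DetectionReport(space="empty")})
        lines = out["empty.csv"].strip().splitlines()
        assert lines[0] == "metric,activity"
        assert len(lines) == 5  # header + 4 metric rows with no ADL columns
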