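import random

import pytest

from radformal.evaluation import (
    ConfusionMatrix,
    Prediction,
    classify_cohort,
    combine_predictions,
    compute_metrics,
    confusion_matrix,
    reference_cohort_predictions,
    round_half_up,
)
from radformal.feature_io import HEALTHY, MAP, CohortLabels
from radformal.formal_model import Action, PatientLTS
from radformal.logic import And, presence


def chain(pid, labels):
    acts = [Action.from_name(a) for a in labels]
    return PatientLTS(pid, [(i, a, i + 1) for i, a in enumerate(acts)])


class FakeRule:
    def __init__(self, formula):
        self.formula = formula


class TestClassifyCohort:
    RULE = FakeRule(And(presence("mean__high"), presence("surfacearea__very_high")))

    def test_all_atoms_present_is_map(self):
        m = chain("a", ["mean__high", "surfacearea__very_high"])
        pred = classify_cohort([m], self.RULE)
        assert pred.calls == {"a": MAP}

    def test_missing_atom_is_healthy(self):
        m = chain("a", ["mean__high", "surfacearea__low"])
        pred = classify_cohort([m], self.RULE)
        assert pred.calls == {"a": HEALTHY}

    def test_permutation_invariance(self):
        models = [
            chain("a", ["mean__high", "surfacearea__very_high"]),
            chain("b", ["mean__low"]),
            chain("c", ["surfacearea__very_high", "mean__high"]),
        ]
        p1 = classify_cohort(models, self.RULE)
        p2 = classify_cohort(models[::-1], self.RULE)
        assert p1.calls == p2.calls

    def test_duplicate_ids_error(self):
        models = [chain("a", ["mean__high"]), chain("a", ["mean__low"])]
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort(models, self.RULE)

    def test_witness_recorded_for_positives(self):
        m = chain("a", ["mean__low", "mean__high", "surfacearea__very_high"])
        pred = classify_cohort([m], self.RULE)
        assert pred.witnesses["a"] == ["mean__low", "mean__high"]


def _labels(n_map, n_healthy):
    status = {f"m{i}": MAP for i in range(n_map)}
    status.update({f"h{i}": HEALTHY for i in range(n_healthy)})
    return CohortLabels(status=status)


class TestConfusionMatrix:
    def test_all_correct(self):
        labels = _labels(3, 2)
        pred = Prediction(calls=dict(labels.status))
        assert confusion_matrix(pred, labels).as_tuple() == (3, 0, 0, 2)

    def test_all_called_map(self):
        labels = _labels(2, 2)
        pred = Prediction(calls={p: MAP for p in labels.status})
        assert confusion_matrix(pred, labels).as_tuple() == (2, 2, 0, 0)

    def test_exclusion(self):
        labels = _labels(3, 2)
        pred = Prediction(calls=dict(labels.status))
        cm = confusion_matrix(pred, labels, exclude={"m0", "h0"})
        assert cm.as_tuple() == (2, 0, 0, 1)

    def test_unlabeled_patient_errors(self):
        labels = _labels(1, 1)
        pred = Prediction(calls={"stranger": MAP})
        with pytest.raises(KeyError):
            confusion_matrix(pred, labels)

    def test_random_against_tally_oracle(self):
        rng = random.Random(31)
        labels = _labels(25, 25)
        calls = {p: rng.choice([MAP, HEALTHY]) for p in labels.status}
        pred = Prediction(calls=calls)
        cm = confusion_matrix(pred, labels)
        # independent pairwise count
        tp = sum(1 for p in calls if labels.status[p] == MAP and calls[p] == MAP)
        fp = sum(1 for p in calls if labels.status[p] == HEALTHY and calls[p] == MAP)
        fn = sum(1 for p in calls if labels.status[p] == MAP and calls[p] == HEALTHY)
        tn = sum(1 for p in calls if labels.status[p] == HEALTHY and calls[p] == HEALTHY)
        assert cm.as_tuple() == (tp, fp, fn, tn)
        assert cm.n == 50


class TestComputeMetrics:
    def test_model_alone_matrix(self):
        """(25,7,6,32): accuracy .8143, precision .7813, sensitivity .8065."""
        m = compute_metrics(ConfusionMatrix(25, 7, 6, 32))
        assert round_half_up(m.accuracy, 4) == 0.8143
        assert round_half_up(m.precision, 4) == 0.7813
        assert round_half_up(m.sensitivity, 4) == 0.8065
        assert m.rounded(2)["accuracy"] == 0.81
        assert m.rounded(2)["precision"] == 0.78
        assert m.rounded(2)["sensitivity"] == 0.81

    def test_combined_matrix(self):
        """(29,0,2,39): precision 1.00, accuracy .9714, sensitivity .9355."""
        m = compute_metrics(ConfusionMatrix(29, 0, 2, 39))
        assert m.precision == 1.0
        assert round_half_up(m.accuracy, 4) == 0.9714
        assert round_half_up(m.sensitivity, 4) == 0.9355
        assert m.rounded(2)["sensitivity"] == 0.94

    def test_degenerate_denominator(self):
        m = compute_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert m.precision is None
        assert m.sensitivity is None
        assert m.specificity == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_counts_conserved(self):
        cm = ConfusionMatrix(25, 7, 6, 32)
        assert cm.n == 70

    def test_percent_presentation(self):
        m = compute_metrics(ConfusionMatrix(25, 7, 6, 32))
        pct = m.as_percent()
        assert pct["accuracy"] == 81
        assert pct["precision"] == 78
        assert pct["sensitivity"] == 81


def test_round_half_up():
    assert round_half_up(0.975, 2) == 0.98
    assert round_half_up(0.8143, 2) == 0.81
    assert round_half_up(80.5, 0) == 81
    assert round_half_up(0.5, 0) == 1


class TestCombine:
    def _pair(self):
        labels = CohortLabels(status={"m": MAP, "h": HEALTHY})
        return labels

    def test_or_positive(self):
        labels = self._pair()
        model = Prediction(calls={"m": HEALTHY, "h": HEALTHY})
        reader = Prediction(calls={"m": MAP, "h": MAP}, source="radiologist")
        combined = combine_predictions(model, reader, labels, policy="or_positive")
        assert combined.calls == {"m": MAP, "h": MAP}

    def test_and_positive(self):
        labels = self._pair()
        model = Prediction(calls={"m": MAP, "h": MAP})
        reader = Prediction(calls={"m": MAP, "h": HEALTHY}, source="radiologist")
        combined = combine_predictions(model, reader, labels, policy="and_positive")
        assert combined.calls == {"m": MAP, "h": HEALTHY}

    def test_oracle_union_reader_catches_model_miss(self):
        labels = self._pair()
        model = Prediction(calls={"m": HEALTHY, "h": HEALTHY})
        reader = Prediction(calls={"m": MAP, "h": HEALTHY}, source="radiologist")
        combined = combine_predictions(model, reader, labels, policy="oracle_union")
        assert combined.calls["m"] == MAP  # TP via the reader

    def test_oracle_union_model_corrects_reader_overcall(self):
        labels = self._pair()
        model = Prediction(calls={"m": MAP, "h": HEALTHY})
        reader = Prediction(calls={"m": MAP, "h": MAP}, source="radiologist")
        combined = combine_predictions(model, reader, labels, policy="oracle_union")
        assert combined.calls["h"] == HEALTHY  # TN via the model

    def test_both_wrong_stays_wrong(self):
        labels = self._pair()
        model = Prediction(calls={"m": HEALTHY, "h": HEALTHY})
        reader = Prediction(calls={"m": HEALTHY, "h": HEALTHY}, source="radiologist")
        for policy in ("or_positive", "and_positive", "oracle_union"):
            combined = combine_predictions(model, reader, labels, policy=policy)
            assert combined.calls["m"] == HEALTHY  # FN under every policy

    def test_oracle_union_needs_labels(self):
        model = Prediction(calls={"m": MAP})
        reader = Prediction(calls={"m": MAP}, source="radiologist")
        with pytest.raises(ValueError, match="labels"):
            combine_predictions(model, reader, None, policy="oracle_union")

    def test_mismatched_patient_sets(self):
        model = Prediction(calls={"m": MAP})
        reader = Prediction(calls={"x": MAP}, source="radiologist")
        with pytest.raises(ValueError, match="different patients"):
            combine_predictions(model, reader, self._pair(), policy="or_positive")

    def test_unknown_policy(self):
        model = Prediction(calls={"m": MAP})
        with pytest.raises(ValueError, match="policy"):
            combine_predictions(model, model, None, policy="vote")

    def test_oracle_union_accuracy_dominance(self):
        rng = random.Random(77)
        labels = _labels(20, 20)
        for _ in range(100):
            mcalls = {p: rng.choice([MAP, HEALTHY]) for p in labels.status}
            rcalls = {p: rng.choice([MAP, HEALTHY]) for p in labels.status}
            model = Prediction(calls=mcalls)
            reader = Prediction(calls=rcalls, source="radiologist")
            combined = combine_predictions(model, reader, labels, policy="oracle_union")
            accs = {
                src: compute_metrics(confusion_matrix(p, labels)).accuracy
                for src, p in (("m", model), ("r", reader), ("c", combined))
            }
            assert accs["c"] >= max(accs["m"], accs["r"])


class TestReferenceCohort:
    def test_model_matrix_matches_reported(self):
        model, reader, labels = reference_cohort_predictions()
        assert confusion_matrix(model, labels).as_tuple() == (25, 7, 6, 32)

    def test_reader_constraints(self):
        model, reader, labels = reference_cohort_predictions()
        cm = confusion_matrix(reader, labels)
        assert cm.fn == 6 and cm.fp == 2
        shared_fn = [
            p
            for p in labels.map_patients()
            if model.calls[p] == HEALTHY and reader.calls[p] == HEALTHY
        ]
        assert len(shared_fn) == 2
        shared_fp = [
            p
            for p in labels.healthy_patients()
            if model.calls[p] == MAP and reader.calls[p] == MAP
        ]
        assert shared_fp == []

    def test_oracle_union_reproduces_combined_matrix(self):
        model, reader, labels = reference_cohort_predictions()
        combined = combine_predictions(model, reader, labels, policy="oracle_union")
        assert confusion_matrix(combined, labels).as_tuple() == (29, 0, 2, 39)
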