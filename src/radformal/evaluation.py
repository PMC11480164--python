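"""Cohort classification, confusion matrices, diagnostic metrics, and
model-plus-reader combination policies.

MAP is the positive class throughout.  The ``oracle_union`` combination is an
idealized adjudication — the combined call is correct whenever at least one
source is correct — and is labeled as such in all outputs; it reconstructs the
counterfactual combined-performance table, not a deployable classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .feature_io import HEALTHY, MAP, CohortLabels
from .formal_model import PatientLTS
from .logic import Formula, evaluate

__all__ = [
    "Prediction",
    "ConfusionMatrix",
    "Metrics",
    "classify_cohort",
    "confusion_matrix",
    "compute_metrics",
    "combine_predictions",
    "reference_cohort_predictions",
    "round_half_up",
]

_POLICIES = ("or_positive", "and_positive", "oracle_union")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.975 -> 0.98), as printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Prediction:
    """One healthy/MAP call per patient from a single source."""

    calls: dict[str, str]
    source: str = "model"
    witnesses: dict[str, Optional[list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("model", "radiologist", "combined"):
            raise ValueError(f"unknown prediction source {self.source!r}")
        for pid, call in self.calls.items():
            if call not in (HEALTHY, MAP):
                raise ValueError(f"invalid call {call!r} for patient {pid!r}")

    def patients(self) -> list[str]:
        return sorted(self.calls)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with MAP as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class Metrics:
    """Diagnostic metrics; ``None`` marks an undefined (0-denominator) value."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        return {
            k: (None if v is None else round_half_up(v, ndigits))
            for k, v in self.__dict__.items()
        }

    def as_percent(self) -> dict[str, Optional[float]]:
        """Whole-percent presentation (0.8143 -> 81)."""
        return {
            k: (None if v is None else round_half_up(100.0 * v, 0))
            for k, v in self.__dict__.items()
        }


def classify_cohort(models: Sequence[PatientLTS], rule) -> Prediction:
    """Call MAP for every patient whose chain satisfies the rule's formula."""
    formula: Formula = rule.formula if hasattr(rule, "formula") else rule
    ids = [m.patient_id for m in models]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids in model list")
    calls: dict[str, str] = {}
    witnesses: dict[str, Optional[list[str]]] = {}
    for m in sorted(models, key=lambda m: m.patient_id):
        res = evaluate(m, formula)
        calls[m.patient_id] = MAP if res.satisfied else HEALTHY
        witnesses[m.patient_id] = res.witness
    return Prediction(calls=calls, source="model", witnesses=witnesses)


def confusion_matrix(
    pred: Prediction,
    labels: CohortLabels,
    exclude: Iterable[str] = (),
) -> ConfusionMatrix:
    """Tally calls against labels over patients not in ``exclude``."""
    excl = set(exclude)
    tp = fp = fn = tn = 0
    for pid, call in pred.calls.items():
        if pid in excl:
            continue
        if pid not in labels.status:
            raise KeyError(f"predicted patient {pid!r} has no label")
        actual = labels.status[pid]
        if actual == MAP:
            if call == MAP:
                tp += 1
            else:
                fn += 1
        else:
            if call == MAP:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, sensitivity, specificity; undefined ratios are None."""
    if cm.n == 0:
        raise ValueError("all-zero confusion matrix")

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    return Metrics(
        accuracy=ratio(cm.tp + cm.tn, cm.n),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
    )


def combine_predictions(
    model: Prediction,
    reader: Prediction,
    labels: Optional[CohortLabels] = None,
    policy: str = "oracle_union",
) -> Prediction:
    """Merge model and radiologist calls under the chosen policy.

    ``or_positive`` calls MAP if either source does; ``and_positive`` only if
    both do; ``oracle_union`` (idealized adjudication, requires labels) emits
    the correct call whenever at least one source is correct and the shared
    wrong call otherwise.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {_POLICIES}")
    if set(model.calls) != set(reader.calls):
        raise ValueError("model and reader predictions cover different patients")
    if policy == "oracle_union" and labels is None:
        raise ValueError("oracle_union requires cohort labels")
    calls: dict[str, str] = {}
    for pid in model.calls:
        a, b = model.calls[pid], reader.calls[pid]
        if policy == "or_positive":
            calls[pid] = MAP if MAP in (a, b) else HEALTHY
        elif policy == "and_positive":
            calls[pid] = MAP if (a == MAP and b == MAP) else HEALTHY
        else:
            truth = labels.status[pid]
            calls[pid] = truth if truth in (a, b) else a  # both wrong: binary, a == b
    return Prediction(calls=calls, source="combined")


def reference_cohort_predictions() -> tuple[Prediction, Prediction, CohortLabels]:
    """Model and reader prediction vectors for the reported 70-patient test set.

    Reconstructed from the published narrative constraints: 31 MAP and 39
    healthy patients; the radiologists miss exactly 6 MAP patients (low CTSI)
    and over-call 2 healthy ones; the model's confusion matrix is
    (tp=25, fp=7, fn=6, tn=32) with exactly 2 of its 6 misses shared with the
    readers and its 7 false positives disjoint from theirs.  Under
    ``oracle_union`` these vectors yield the combined matrix (29, 0, 2, 39).
    """
    map_ids = [f"M{i:02d}" for i in range(1, 32)]
    healthy_ids = [f"H{i:02d}" for i in range(1, 40)]
    labels = CohortLabels(
        status={**{p: MAP for p in map_ids}, **{p: HEALTHY for p in healthy_ids}}
    )
    reader_fn = set(map_ids[:6])  # M01..M06, the 6 low-CTSI misses
    model_fn = set(map_ids[:2]) | set(map_ids[6:10])  # shares exactly M01, M02
    reader_fp = set(healthy_ids[:2])  # H01, H02 over-called
    model_fp = set(healthy_ids[2:9])  # 7 false positives, disjoint from reader's
    model = Prediction(
        calls={
            **{p: (HEALTHY if p in model_fn else MAP) for p in map_ids},
            **{p: (MAP if p in model_fp else HEALTHY) for p in healthy_ids},
        },
        source="model",
    )
    reader = Prediction(
        calls={
            **{p: (HEALTHY if p in reader_fn else MAP) for p in map_ids},
            **{p: (MAP if p in reader_fp else HEALTHY) for p in healthy_ids},
        },
        source="radiologist",
    )
    return model, reader, labels
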