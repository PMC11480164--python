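"""Exemplar-driven synthesis of the classification Property.

For each feature class in a rule spec, every exemplar patient's per-feature
slice series is summarized by its modal level (ties break toward the higher
ordinal).  The class sub-property is the conjunction, over the class's
features, of a disjunction of presence atoms over the exemplars' modal levels;
a full rule OR-composes the class sub-properties.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .discretization import DiscretizedMatrix, Level
from .evaluation import Metrics, classify_cohort, compute_metrics, confusion_matrix
from .feature_io import MAP, CohortLabels, FeaturePanel, normalize_feature_name
from .formal_model import build_patient_model
from .logic import And, Formula, Or, check_monotone, formula_to_text, presence

logger = logging.getLogger(__name__)

__all__ = [
    "RuleSpec",
    "Rule",
    "modal_level",
    "synthesize_class_property",
    "synthesize_rule",
    "rank_rules",
]


@dataclass(frozen=True)
class RuleSpec:
    """Disjuncts of (feature class, exemplar patient ids) to synthesize from."""

    disjuncts: tuple[tuple[str, tuple[str, ...]], ...]

    @staticmethod
    def of(*disjuncts: tuple[str, Sequence[str]]) -> "RuleSpec":
        return RuleSpec(tuple((c, tuple(e)) for c, e in disjuncts))

    @property
    def exemplar_ids(self) -> tuple[str, ...]:
        """All distinct exemplars across disjuncts, sorted."""
        return tuple(sorted({e for _, es in self.disjuncts for e in es}))

    def describe(self) -> str:
        return " OR ".join(f"{c}:{','.join(es)}" for c, es in self.disjuncts)

    def validate(self, panel: FeaturePanel, labels: Optional[CohortLabels] = None) -> None:
        for cls, exemplars in self.disjuncts:
            if cls not in panel.classes:
                raise KeyError(f"unknown feature class {cls!r}")
            if not exemplars:
                raise ValueError(f"disjunct {cls!r} has no exemplars")
            if labels is not None:
                for e in exemplars:
                    if e not in labels.status:
                        raise KeyError(f"exemplar {e!r} not in cohort labels")
                    if labels.status[e] != MAP:
                        raise ValueError(f"exemplar {e!r} is not labeled {MAP}")


@dataclass
class Rule:
    """A named, closed, monotone formula plus the provenance that rebuilds it."""

    name: str
    formula: Formula
    spec: RuleSpec
    # per disjunct: feature -> sorted level names used in the disjunction
    level_sets: list[dict[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_monotone(self.formula)

    @property
    def text(self) -> str:
        return formula_to_text(self.formula)

    def provenance(self) -> dict:
        return {
            "name": self.name,
            "spec": self.describe_spec(),
            "disjuncts": [
                {"class": cls, "exemplars": list(exemplars), "levels": levels}
                for (cls, exemplars), levels in zip(self.spec.disjuncts, self.level_sets)
            ],
            "formula": self.text,
        }

    def describe_spec(self) -> str:
        return self.spec.describe()


def modal_level(levels: Sequence[Level]) -> Level:
    """Most frequent level of a series; ties break toward the higher ordinal."""
    if not levels:
        raise ValueError("empty level series")
    counts = Counter(int(lv) for lv in levels)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return Level(best[0])


def synthesize_class_property(
    class_name: str,
    exemplar_ids: Sequence[str],
    dm: DiscretizedMatrix,
    panel: FeaturePanel,
) -> Formula:
    """Build ``AND_f OR_{l in L(f)} presence(f__l)`` over the class's features,
    where L(f) collects the exemplars' modal levels of f."""
    phi, _ = _class_property(class_name, exemplar_ids, dm, panel)
    return phi


def _class_property(
    class_name: str,
    exemplar_ids: Sequence[str],
    dm: DiscretizedMatrix,
    panel: FeaturePanel,
) -> tuple[Formula, dict[str, list[str]]]:
    features = panel.class_features(class_name)
    if not exemplar_ids:
        raise ValueError("no exemplars given")
    present = set(dm.patients())
    for e in exemplar_ids:
        if e not in present:
            raise KeyError(f"exemplar {e!r} not in discretized matrix")
    conjuncts: list[Formula] = []
    level_sets: dict[str, list[str]] = {}
    for feat in features:
        modal = {modal_level(dm.levels(e, feat)) for e in exemplar_ids}
        ordered = sorted(modal)
        level_sets[feat] = [lv.name for lv in ordered]
        atoms = [presence(f"{normalize_feature_name(feat)}__{lv.name}") for lv in ordered]
        disj = atoms[0]
        for a in atoms[1:]:
            disj = Or(disj, a)
        conjuncts.append(disj)
    phi = conjuncts[0]
    for c in conjuncts[1:]:
        phi = And(phi, c)
    return phi, level_sets


def synthesize_rule(
    spec: RuleSpec,
    dm: DiscretizedMatrix,
    panel: FeaturePanel,
    labels: Optional[CohortLabels] = None,
    name: Optional[str] = None,
) -> Rule:
    """OR-compose class sub-properties per the spec; provenance is recorded."""
    spec.validate(panel, labels)
    parts: list[Formula] = []
    level_sets: list[dict[str, list[str]]] = []
    for cls, exemplars in spec.disjuncts:
        phi, levels = _class_property(cls, exemplars, dm, panel)
        parts.append(phi)
        level_sets.append(levels)
    formula = parts[0]
    for p in parts[1:]:
        formula = Or(formula, p)
    return Rule(
        name=name or spec.describe(),
        formula=formula,
        spec=spec,
        level_sets=level_sets,
    )


def rank_rules(
    candidate_specs: Sequence[RuleSpec],
    dm: DiscretizedMatrix,
    panel: FeaturePanel,
    labels: CohortLabels,
    metric: str = "accuracy",
) -> list[tuple[RuleSpec, Metrics]]:
    """Score each candidate on the cohort minus its own exemplars; sort by the
    chosen metric descending, then fewer exemplars, then lexicographic spec."""
    if not candidate_specs:
        raise ValueError("empty candidate list")
    if metric not in ("accuracy", "sensitivity"):
        raise ValueError(f"unsupported ranking metric {metric!r}")
    scored: list[tuple[RuleSpec, Metrics]] = []
    models = {
        pid: build_patient_model(dm, pid, panel)
        for pid in dm.patients()
        if pid in labels.status
    }
    for spec in candidate_specs:
        rule = synthesize_rule(spec, dm, panel, labels)
        exemplars = set(spec.exemplar_ids)
        eligible = [m for pid, m in models.items() if pid not in exemplars]
        pred = classify_cohort(eligible, rule)
        cm = confusion_matrix(pred, labels, exclude=exemplars)
        scored.append((spec, compute_metrics(cm)))

    def key(item):
        spec, metrics = item
        score = getattr(metrics, metric)
        return (
            -(score if score is not None else -1.0),
            len(spec.exemplar_ids),
            spec.describe(),
        )

    return sorted(scored, key=key)


def enumerate_specs(
    classes: Sequence[str],
    exemplar_pool: Sequence[str],
    max_exemplars_per_class: int = 2,
    max_disjuncts: int = 2,
    cap: int = 500,
) -> list[RuleSpec]:
    """All (class, exemplar-subset) disjunct combinations up to the caps."""
    singles = [
        (cls, combo)
        for cls in classes
        for r in range(1, max_exemplars_per_class + 1)
        for combo in itertools.combinations(sorted(exemplar_pool), r)
    ]
    specs: list[RuleSpec] = []
    for r in range(1, max_disjuncts + 1):
        for combo in itertools.combinations(singles, r):
            if len({c for c, _ in combo}) < len(combo):
                continue  # one disjunct per class
            specs.append(RuleSpec(tuple(combo)))
            if len(specs) >= cap:
                logger.info("candidate enumeration capped at %d specs", cap)
                return specs
    return specs
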