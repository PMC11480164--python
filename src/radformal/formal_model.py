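"""Linear labeled transition systems for patients, with CCS text serialization.

A patient's discretized slice series becomes a single chain: slices are visited
in ascending index order and, within each slice, features are emitted in
canonical panel order.  Each transition carries one (feature, level) action.
The chain is serialized as a minimal CCS dialect — prefixing with ``.``, the
terminal process ``nil``, ``;``-terminated defining equations — and parses back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .discretization import DiscretizedMatrix, Level
from .feature_io import FeaturePanel, normalize_feature_name

__all__ = [
    "Action",
    "PatientLTS",
    "build_patient_model",
    "action_alphabet",
    "serialize_ccs",
    "parse_ccs",
]


@dataclass(frozen=True)
class Action:
    """A (feature, level) observation; canonical name ``<feature>__<level>``.

    The feature is stored normalized (lowercase alphanumerics) so that actions
    compare equal regardless of the spelling they were built from.
    """

    feature: str
    level: Level

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature", normalize_feature_name(self.feature))

    @property
    def name(self) -> str:
        return f"{self.feature}__{self.level.name}"

    @staticmethod
    def from_name(name: str) -> "Action":
        m = re.fullmatch(r"([a-z0-9]+)__([a-z_]+)", name)
        if not m:
            raise ValueError(f"malformed action name {name!r}")
        return Action(feature=m.group(1), level=Level[m.group(2)])


@dataclass
class PatientLTS:
    """A linear chain 0 → 1 → ... → N with one action per transition."""

    patient_id: str
    transitions: list[tuple[int, Action, int]]

    def __post_init__(self) -> None:
        for k, (src, _, dst) in enumerate(self.transitions):
            if src != k or dst != k + 1:
                raise ValueError(
                    f"not a linear chain: transition {k} is ({src} -> {dst})"
                )

    @property
    def n_states(self) -> int:
        return len(self.transitions) + 1

    @property
    def initial_state(self) -> int:
        return 0

    def trace(self) -> list[str]:
        """The unique maximal action-name trace from the initial state."""
        return [a.name for _, a, _ in self.transitions]


def build_patient_model(
    dm: DiscretizedMatrix, patient_id: str, panel: FeaturePanel
) -> PatientLTS:
    """Build the chain for one patient from its discretized entries.

    Deterministic: slice order ascending, panel order within a slice.  Raises if
    the patient is absent, has no slices, or lacks a panel feature on a slice.
    """
    sub = dm.data[dm.data["patient_id"] == patient_id]
    if sub.empty:
        raise KeyError(f"patient {patient_id!r} not in discretized matrix")
    by_slice = {
        s: dict(zip(g["feature_name"], g["level"]))
        for s, g in sub.groupby("slice_index")
    }
    slices = sorted(by_slice)
    if not slices:
        raise ValueError(f"patient {patient_id!r} has zero slices")
    transitions: list[tuple[int, Action, int]] = []
    k = 0
    for s in slices:
        row = by_slice[s]
        for feat in panel.features:
            if feat not in row:
                raise ValueError(
                    f"patient {patient_id!r} slice {s} lacks feature {feat!r}"
                )
            transitions.append((k, Action(feat, Level(int(row[feat]))), k + 1))
            k += 1
    return PatientLTS(patient_id=patient_id, transitions=transitions)


def action_alphabet(lts: PatientLTS) -> set[str]:
    """The set of action names occurring on the chain's transitions."""
    return {a.name for _, a, _ in lts.transitions}


def _pid_token(patient_id: str) -> str:
    tok = re.sub(r"[^A-Za-z0-9_]", "_", patient_id)
    return tok or "p"


def serialize_ccs(lts: PatientLTS) -> str:
    """Render the chain as CCS defining equations, one per state."""
    pid = _pid_token(lts.patient_id)
    lines = [
        f"P{pid}_{src} = {a.name}.P{pid}_{dst};" for src, a, dst in lts.transitions
    ]
    lines.append(f"P{pid}_{lts.n_states - 1} = nil;")
    return "\n".join(lines) + "\n"


_EQ_RE = re.compile(
    r"P(?P<pid>[A-Za-z0-9_]+?)_(?P<src>\d+)\s*=\s*"
    r"(?:(?P<act>[a-z0-9_]+)\.P(?P=pid)_(?P<dst>\d+)|(?P<nil>nil))\s*;"
)


def parse_ccs(text: str) -> PatientLTS:
    """Parse one serialized chain back into a :class:`PatientLTS`.

    Inverse of :func:`serialize_ccs` for patient ids made of word characters.
    """
    transitions: list[tuple[int, Action, int]] = []
    pid = None
    terminal = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _EQ_RE.fullmatch(line)
        if not m:
            raise ValueError(f"malformed CCS equation: {line!r}")
        if pid is None:
            pid = m.group("pid")
        elif m.group("pid") != pid:
            raise ValueError("multiple process families in one chain text")
        if m.group("nil"):
            terminal = int(m.group("src"))
        else:
            transitions.append(
                (int(m.group("src")), Action.from_name(m.group("act")), int(m.group("dst")))
            )
    if pid is None:
        raise ValueError("no CCS equations found")
    transitions.sort(key=lambda t: t[0])
    lts = PatientLTS(patient_id=pid, transitions=transitions)
    if terminal != lts.n_states - 1:
        raise ValueError("terminal nil equation missing or misplaced")
    return lts
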