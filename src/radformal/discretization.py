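"""Equal-width five-level discretization of cohort feature values.

Each feature gets six edges spanning its cohort-wide [min, max]; the five
resulting ordinal levels are named very_low, low, basal, high, very_high.
Intervals are half-open ``[e_i, e_{i+1})`` except the last, which is closed.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_io import FeatureMatrix, FeaturePanel

logger = logging.getLogger(__name__)

__all__ = [
    "Level",
    "DiscretizationScheme",
    "DiscretizedMatrix",
    "fit_discretization",
    "assign_level",
    "discretize_matrix",
]

N_LEVELS = 5


class Level(enum.IntEnum):
    """Ordinal intensity level of a discretized feature value."""

    very_low = 0
    low = 1
    basal = 2
    high = 3
    very_high = 4

    def __str__(self) -> str:  # action-name friendly
        return self.name


@dataclass
class DiscretizationScheme:
    """Per-feature bin edges ``e0 < e1 < ... < e5`` plus degenerate flags.

    A feature is degenerate when its cohort minimum equals its maximum; every
    value of a degenerate feature maps to :attr:`Level.basal`.
    """

    edges: dict[str, np.ndarray]
    degenerate: dict[str, bool] = field(default_factory=dict)
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        for feat, e in self.edges.items():
            e = np.asarray(e, dtype=float)
            self.edges[feat] = e
            if len(e) != self.n_levels + 1:
                raise ValueError(f"feature {feat!r}: expected {self.n_levels + 1} edges")
            if not self.degenerate.get(feat, False):
                if not np.all(np.diff(e) > 0):
                    raise ValueError(f"feature {feat!r}: edges not strictly increasing")
                widths = np.diff(e)
                span = e[-1] - e[0]
                if span > 0 and np.max(np.abs(widths - span / self.n_levels)) > 1e-9 * max(
                    1.0, abs(span)
                ):
                    raise ValueError(f"feature {feat!r}: bin widths not equal")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.edges)

    def to_json(self) -> str:
        return json.dumps(
            {
                f: {"edges": list(map(float, e)), "degenerate": self.degenerate.get(f, False)}
                for f, e in self.edges.items()
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "DiscretizationScheme":
        if isinstance(text, Path):
            text = text.read_text()
        raw = json.loads(text)
        return cls(
            edges={f: np.asarray(d["edges"], float) for f, d in raw.items()},
            degenerate={f: bool(d["degenerate"]) for f, d in raw.items()},
        )


def fit_discretization(
    fm: FeatureMatrix, panel: FeaturePanel, n_levels: int = N_LEVELS
) -> DiscretizationScheme:
    """Fit equal-width edges over [cohort min, cohort max] for every panel feature.

    Requires a complete (post-filter) matrix; raises if any panel feature is
    absent or carries non-finite values.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    df = fm.data
    edges: dict[str, np.ndarray] = {}
    degenerate: dict[str, bool] = {}
    grouped = df.groupby("feature_name")["value"]
    lo, hi = grouped.min(), grouped.max()
    for feat in panel.features:
        if feat not in lo.index:
            raise ValueError(f"panel feature {feat!r} absent from matrix")
        a, b = float(lo[feat]), float(hi[feat])
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError(f"feature {feat!r} has non-finite values; filter first")
        if a == b:
            degenerate[feat] = True
            edges[feat] = np.full(n_levels + 1, a)
            logger.info("feature %r is degenerate (constant %g)", feat, a)
        else:
            degenerate[feat] = False
            edges[feat] = np.linspace(a, b, n_levels + 1)
    return DiscretizationScheme(edges=edges, degenerate=degenerate, n_levels=n_levels)


def assign_level(value: float, feature: str, scheme: DiscretizationScheme) -> Level:
    """Map one value to its ordinal level under the fitted scheme.

    Out-of-range values clamp to the extreme levels with a logged warning, so a
    frozen scheme can be applied to new patients.
    """
    if feature not in scheme.edges:
        raise KeyError(f"feature {feature!r} not in scheme")
    if not np.isfinite(value):
        raise ValueError(f"non-finite value {value!r} for feature {feature!r}")
    if scheme.degenerate.get(feature, False):
        return Level.basal
    e = scheme.edges[feature]
    if value < e[0] or value > e[-1]:
        logger.warning(
            "value %g outside fitted range [%g, %g] for %r; clamping",
            value, e[0], e[-1], feature,
        )
    # right-open bins, closed top: searchsorted(side="right") - 1, clipped
    idx = int(np.searchsorted(e, value, side="right")) - 1
    return Level(int(np.clip(idx, 0, scheme.n_levels - 1)))


@dataclass
class DiscretizedMatrix:
    """Same index set as a FeatureMatrix, with integer ``level`` entries."""

    data: pd.DataFrame  # patient_id, slice_index, feature_name, level

    def __post_init__(self) -> None:
        need = ["patient_id", "slice_index", "feature_name", "level"]
        if list(self.data.columns) != need:
            self.data = self.data.loc[:, need]
        self.data = self.data.sort_values(
            ["patient_id", "slice_index", "feature_name"], kind="mergesort"
        ).reset_index(drop=True)

    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def levels(self, patient_id: str, feature: str) -> list[Level]:
        """Level series for one (patient, feature), in ascending slice order."""
        sub = self.data[
            (self.data["patient_id"] == patient_id)
            & (self.data["feature_name"] == feature)
        ].sort_values("slice_index")
        if sub.empty:
            raise KeyError(f"no entries for patient {patient_id!r}, feature {feature!r}")
        return [Level(int(v)) for v in sub["level"]]

    def __len__(self) -> int:
        return len(self.data)


def discretize_matrix(fm: FeatureMatrix, scheme: DiscretizationScheme) -> DiscretizedMatrix:
    """Apply :func:`assign_level` to every entry; deterministic and vectorized."""
    df = fm.data
    unknown = set(df["feature_name"].unique()) - set(scheme.edges)
    if unknown:
        raise KeyError(f"matrix features missing from scheme: {sorted(unknown)}")
    if df["value"].isna().any():
        raise ValueError("matrix contains missing values; filter incomplete patients first")
    out = df[["patient_id", "slice_index", "feature_name"]].copy()
    levels = np.empty(len(df), dtype=np.int64)
    for feat, idx in df.groupby("feature_name").indices.items():
        vals = df["value"].to_numpy()[idx]
        if scheme.degenerate.get(feat, False):
            levels[idx] = int(Level.basal)
            continue
        e = scheme.edges[feat]
        if ((vals < e[0]) | (vals > e[-1])).any():
            logger.warning("values outside fitted range for %r; clamping", feat)
        lv = np.searchsorted(e, vals, side="right") - 1
        levels[idx] = np.clip(lv, 0, scheme.n_levels - 1)
    out["level"] = levels
    return DiscretizedMatrix(out)
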