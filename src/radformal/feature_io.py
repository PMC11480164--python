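"""Cohort feature-table I/O, the canonical feature panel, and completeness filtering.

The pipeline consumes a per-(patient, slice) radiomic feature table produced by an
upstream extractor.  This module defines the fixed 22-feature / 6-class panel the
classifier operates on, reads wide or long (tidy) CSV tables into a validated
:class:`FeatureMatrix`, and excludes patients whose panel coverage is incomplete.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FeaturePanel",
    "FeatureMatrix",
    "CohortLabels",
    "ExclusionReport",
    "normalize_feature_name",
    "canonical_panel",
    "read_feature_table",
    "read_labels",
    "filter_incomplete_patients",
]

HEALTHY = "healthy"
MAP = "MAP"

FEATURE_CLASSES = ("FIRST", "GLCM", "GLDM", "GLSZM", "SHAPE", "GLRLM")

# Fixed panel: 6 feature families, 22 features total.  GrayLevelNonUniformity
# exists in both the run-length and size-zone catalogues; here it belongs to GLRLM.
_PANEL: dict[str, tuple[str, ...]] = {
    "FIRST": ("10Percentile", "Mean", "Median", "Skewness", "Uniformity"),
    "GLCM": ("Imc2", "JointEntropy", "SumEntropy", "MaximumProbability"),
    "GLDM": ("DependenceEntropy", "LowGrayLevelEmphasis", "DependenceNonUniformity"),
    "GLSZM": ("ZoneEntropy", "SmallAreaHighGrayLevelEmphasis", "SizeZoneNonUniformity"),
    "SHAPE": ("Maximum2DDiameterRow", "MinorAxisLength", "SurfaceArea"),
    "GLRLM": (
        "GrayLevelNonUniformity",
        "LowGrayLevelRunEmphasis",
        "RunEntropy",
        "ShortRunLowGrayLevelEmphasis",
    ),
}


class FormatError(ValueError):
    """Raised for malformed input tables (bad header, duplicates, bad values)."""


def normalize_feature_name(name: str) -> str:
    """Canonicalize a feature name: lowercase, alphanumerics only.

    ``"Joint entropy"``, ``"JointEntropy"`` and ``"joint_entropy"`` all map to
    ``"jointentropy"``, so prose names and extractor camel case interoperate.
    """
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


@dataclass(frozen=True)
class FeaturePanel:
    """An ordered map from feature class to its ordered feature names."""

    classes: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if tuple(self.classes) != FEATURE_CLASSES:
            raise ValueError(
                f"panel must have exactly the classes {FEATURE_CLASSES}, got {tuple(self.classes)}"
            )
        names = [normalize_feature_name(f) for fs in self.classes.values() for f in fs]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique across the panel")

    @property
    def features(self) -> tuple[str, ...]:
        """All feature names in canonical panel order (class by class)."""
        return tuple(f for fs in self.classes.values() for f in fs)

    @property
    def normalized_features(self) -> tuple[str, ...]:
        return tuple(normalize_feature_name(f) for f in self.features)

    def class_of(self, feature: str) -> str:
        key = normalize_feature_name(feature)
        for cls, fs in self.classes.items():
            if key in (normalize_feature_name(f) for f in fs):
                return cls
        raise KeyError(f"feature {feature!r} not in panel")

    def class_features(self, class_name: str) -> tuple[str, ...]:
        if class_name not in self.classes:
            raise KeyError(f"unknown feature class {class_name!r}")
        return tuple(self.classes[class_name])

    def resolve(self, name: str) -> str:
        """Map an arbitrary spelling to the panel's canonical feature name."""
        key = normalize_feature_name(name)
        for f in self.features:
            if normalize_feature_name(f) == key:
                return f
        raise KeyError(f"feature {name!r} not in panel")


def canonical_panel() -> FeaturePanel:
    """Return the fixed 6-class, 22-feature panel used throughout."""
    return FeaturePanel(classes=dict(_PANEL))


_COLUMNS = ("patient_id", "slice_index", "feature_name", "value")


@dataclass
class FeatureMatrix:
    """Tidy per-(patient, slice, feature) value table.

    ``data`` has columns ``patient_id`` (str), ``slice_index`` (int),
    ``feature_name`` (canonical str), ``value`` (float; NaN encodes a missing
    measurement, which drives patient exclusion downstream).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FeatureMatrix frame lacks columns {missing}")
        df = df.loc[:, list(_COLUMNS)].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["slice_index"] = df["slice_index"].astype(np.int64)
        if (df["slice_index"] < 0).any():
            raise ValueError("slice_index must be non-negative")
        df["feature_name"] = df["feature_name"].astype(str)
        df["value"] = df["value"].astype(float)
        if np.isinf(df["value"].to_numpy()).any():
            raise ValueError("feature values must be finite where present")
        if df.duplicated(subset=["patient_id", "slice_index", "feature_name"]).any():
            raise ValueError("duplicate (patient_id, slice_index, feature_name) entries")
        # deterministic canonical order, invariant to input row order
        df = df.sort_values(
            ["patient_id", "slice_index", "feature_name"], kind="mergesort"
        ).reset_index(drop=True)
        self.data = df

    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def slices(self, patient_id: str) -> list[int]:
        sub = self.data.loc[self.data["patient_id"] == patient_id, "slice_index"]
        if sub.empty:
            raise KeyError(f"patient {patient_id!r} not in matrix")
        return sorted(sub.unique())

    def slice_counts(self) -> dict[str, int]:
        return {
            pid: int(n)
            for pid, n in self.data.groupby("patient_id")["slice_index"].nunique().items()
        }

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        """Write in long (tidy) form; NaN values serialize as empty cells."""
        self.data.to_csv(path, index=False)


@dataclass
class CohortLabels:
    """Per-patient status (healthy / MAP), optional CTSI grade and radiologist call."""

    status: Mapping[str, str]
    ctsi: Mapping[str, int] = field(default_factory=dict)
    radiologist_call: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, s in self.status.items():
            if s not in (HEALTHY, MAP):
                raise ValueError(f"patient {pid!r} has status {s!r}; expected healthy/MAP")
        for pid, g in self.ctsi.items():
            if self.status.get(pid) != MAP:
                raise ValueError(f"ctsi given for non-MAP patient {pid!r}")
            if not 0 <= int(g) <= 3:
                raise ValueError(f"ctsi {g!r} out of range 0-3 for patient {pid!r}")
        for pid, c in self.radiologist_call.items():
            if c not in (HEALTHY, MAP):
                raise ValueError(f"radiologist call {c!r} invalid for patient {pid!r}")

    def is_map(self, patient_id: str) -> bool:
        return self.status[patient_id] == MAP

    def map_patients(self) -> list[str]:
        return sorted(p for p, s in self.status.items() if s == MAP)

    def healthy_patients(self) -> list[str]:
        return sorted(p for p, s in self.status.items() if s == HEALTHY)

    def restrict(self, patient_ids: Iterable[str]) -> "CohortLabels":
        keep = set(patient_ids)
        return CohortLabels(
            status={p: s for p, s in self.status.items() if p in keep},
            ctsi={p: g for p, g in self.ctsi.items() if p in keep},
            radiologist_call={p: c for p, c in self.radiologist_call.items() if p in keep},
        )

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for pid in sorted(self.status):
            rows.append(
                {
                    "patient_id": pid,
                    "status": self.status[pid],
                    "ctsi": self.ctsi.get(pid, ""),
                    "radiologist_call": self.radiologist_call.get(pid, ""),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ExclusionReport:
    """Patients dropped for incomplete panel coverage, with offending features."""

    excluded: dict[str, list[str]]
    retained_ids: list[str]

    @property
    def excluded_patient_ids(self) -> list[str]:
        return sorted(self.excluded)

    def to_json(self) -> str:
        return json.dumps(
            [
                {"patient_id": pid, "missing": sorted(feats)}
                for pid, feats in sorted(self.excluded.items())
            ],
            indent=2,
        )


def _read_csv(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, dtype=str, keep_default_na=False)
    if isinstance(source, str):  # pragma: no cover - defensive
        return pd.read_csv(io.StringIO(source), dtype=str, keep_default_na=False)
    return pd.read_csv(source, dtype=str, keep_default_na=False)


_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def _parse_value(raw: str, row: int, column: str) -> float:
    text = raw.strip()
    if text.lower() in _MISSING_TOKENS:
        return float("nan")
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"non-numeric value {raw!r} at row {row}, column {column!r}"
        ) from None


def read_feature_table(source, panel: FeaturePanel) -> FeatureMatrix:
    """Read a wide or long feature CSV into a :class:`FeatureMatrix`.

    Wide form has header ``patient_id,slice_index,<feature>...``; long form has
    ``patient_id,slice_index,feature_name,value`` and is auto-detected from the
    header.  Panel features are matched case-/punctuation-insensitively; extra
    columns are ignored with a log note.  Missing cells and NA-like tokens load
    as NaN (handled by the exclusion filter), any other non-numeric text is a
    :class:`FormatError`.
    """
    try:
        df = _read_csv(source)
    except pd.errors.EmptyDataError:
        raise FormatError("empty input: missing header row") from None
    cols = list(df.columns)
    norm_cols = [normalize_feature_name(c) for c in cols]
    if "patientid" not in norm_cols or "sliceindex" not in norm_cols:
        raise FormatError(
            "missing header: expected 'patient_id' and 'slice_index' columns, "
            f"got {cols}"
        )
    colmap = dict(zip(norm_cols, cols))
    pid_col, slice_col = colmap["patientid"], colmap["sliceindex"]

    is_long = "featurename" in norm_cols and "value" in norm_cols
    if is_long:
        records = _load_long(df, panel, colmap, pid_col, slice_col)
    else:
        records = _load_wide(df, panel, cols, norm_cols, pid_col, slice_col)
    if not records:
        raise FormatError("no feature entries found in input")
    return FeatureMatrix(pd.DataFrame.from_records(records, columns=list(_COLUMNS)))


def _parse_slice(raw: str, row: int) -> int:
    try:
        idx = int(str(raw).strip())
    except ValueError:
        raise FormatError(f"non-integer slice_index {raw!r} at row {row}") from None
    if idx < 0:
        raise FormatError(f"negative slice_index {idx} at row {row}")
    return idx


def _load_wide(df, panel, cols, norm_cols, pid_col, slice_col):
    known = dict(zip(panel.normalized_features, panel.features))
    feature_cols: list[tuple[str, str]] = []  # (raw column, canonical name)
    ignored = []
    for raw, norm in zip(cols, norm_cols):
        if raw in (pid_col, slice_col):
            continue
        if norm in known:
            feature_cols.append((raw, known[norm]))
        else:
            ignored.append(raw)
    if ignored:
        logger.info("ignoring %d non-panel column(s): %s", len(ignored), ignored)
    seen: set[tuple[str, int]] = set()
    records = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(cols, row))
        pid = str(row[pid_col]).strip()
        sl = _parse_slice(row[slice_col], row_idx)
        if (pid, sl) in seen:
            raise FormatError(f"duplicate (patient, slice) row ({pid!r}, {sl}) at row {row_idx}")
        seen.add((pid, sl))
        for raw_col, canon in feature_cols:
            records.append(
                (pid, sl, canon, _parse_value(row[raw_col], row_idx, raw_col))
            )
    return records


def _load_long(df, panel, colmap, pid_col, slice_col):
    feat_col, val_col = colmap["featurename"], colmap["value"]
    known = dict(zip(panel.normalized_features, panel.features))
    records = []
    ignored: set[str] = set()
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        pid = str(row[pid_col]).strip()
        sl = _parse_slice(row[slice_col], row_idx)
        norm = normalize_feature_name(row[feat_col])
        if norm not in known:
            ignored.add(str(row[feat_col]))
            continue
        records.append((pid, sl, known[norm], _parse_value(row[val_col], row_idx, val_col)))
    if ignored:
        logger.info("ignoring %d non-panel feature(s): %s", len(ignored), sorted(ignored))
    return records


def read_labels(source) -> CohortLabels:
    """Read a ``patient_id,status[,ctsi][,radiologist_call]`` CSV."""
    df = _read_csv(source)
    norm = {normalize_feature_name(c): c for c in df.columns}
    if "patientid" not in norm or "status" not in norm:
        raise FormatError("labels file must have 'patient_id' and 'status' columns")
    status, ctsi, reader = {}, {}, {}
    for _, row in df.iterrows():
        pid = str(row[norm["patientid"]]).strip()
        status[pid] = str(row[norm["status"]]).strip()
        if "ctsi" in norm:
            raw = str(row[norm["ctsi"]]).strip()
            if raw.lower() not in _MISSING_TOKENS:
                ctsi[pid] = int(float(raw))
        if "radiologistcall" in norm:
            raw = str(row[norm["radiologistcall"]]).strip()
            if raw.lower() not in _MISSING_TOKENS:
                reader[pid] = raw
    return CohortLabels(status=status, ctsi=ctsi, radiologist_call=reader)


def filter_incomplete_patients(
    fm: FeatureMatrix, panel: FeaturePanel
) -> tuple[FeatureMatrix, ExclusionReport]:
    """Drop every patient with a missing or non-finite panel value on any slice.

    A feature is missing for a patient either when some (slice, feature) entry is
    NaN or when the feature has no entry at all for one of the patient's slices.
    Returns the retained matrix and a report naming the offending features.
    """
    if len(fm) == 0:
        raise ValueError("empty feature matrix")
    required = set(panel.features)
    excluded: dict[str, set[str]] = {}

    nan_rows = fm.data[fm.data["value"].isna() & fm.data["feature_name"].isin(required)]
    for pid, feats in nan_rows.groupby("patient_id")["feature_name"]:
        excluded.setdefault(pid, set()).update(feats)

    # features absent from some slice of a patient
    counts = (
        fm.data[fm.data["feature_name"].isin(required)]
        .groupby(["patient_id", "feature_name"])["slice_index"]
        .nunique()
    )
    for pid, n_slices in fm.slice_counts().items():
        have = counts.loc[pid] if pid in counts.index.get_level_values(0) else pd.Series(dtype=int)
        for feat in required:
            if int(have.get(feat, 0)) < n_slices:
                excluded.setdefault(pid, set()).add(feat)

    retained_ids = [p for p in fm.patients() if p not in excluded]
    if not retained_ids:
        logger.warning("all %d patients excluded as incomplete", len(excluded))
        retained = FeatureMatrix(fm.data.iloc[0:0].copy())
    else:
        retained = FeatureMatrix(
            fm.data[fm.data["patient_id"].isin(retained_ids)].reset_index(drop=True)
        )
    report = ExclusionReport(
        excluded={p: sorted(f) for p, f in excluded.items()}, retained_ids=retained_ids
    )
    if excluded:
        logger.info(
            "excluded %d incomplete patient(s): %s", len(excluded), sorted(excluded)
        )
    return retained, report
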