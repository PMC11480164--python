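"""Seeded synthetic cohorts with the study's statistical structure.

Healthy and MAP patients get per-slice Gaussian feature values; MAP patients'
discriminative features (all FIRST and SHAPE features by default) are shifted
by ``delta * sigma * (1 + ctsi) / 4``.  Slice counts are drawn per class from
a truncated normal over the configured range.  Everything is reproducible from
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import (
    HEALTHY,
    MAP,
    CohortLabels,
    FeatureMatrix,
    FeaturePanel,
    canonical_panel,
)

__all__ = ["CohortConfig", "generate_cohort", "inject_missing", "severity_multiplier"]

# 95% CI span ~ 2 * 1.96 sd for a normal; used to back out an sd from a range
_CI_Z = 2.0 * 1.959963984540054


def severity_multiplier(ctsi: int) -> float:
    return (1 + ctsi) / 4.0


def _default_discriminative() -> tuple[str, ...]:
    panel = canonical_panel()
    return tuple(panel.class_features("FIRST") + panel.class_features("SHAPE"))


@dataclass
class CohortConfig:
    """Generator parameters; defaults mirror the study cohort's statistics."""

    n_healthy: int = 40
    n_map: int = 40
    healthy_slice_mean: float = 19.7
    healthy_slice_range: tuple[int, int] = (6, 27)
    map_slice_mean: float = 22.7
    map_slice_range: tuple[int, int] = (19, 31)
    baseline_mean_loc: float = 10.0
    baseline_mean_scale: float = 5.0
    feature_sd: float = 1.0
    discriminative: tuple[str, ...] = field(default_factory=_default_discriminative)
    effect_size: float = 3.0  # delta, in pooled-sd units
    ctsi_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_missing_healthy: int = 0
    n_missing_map: int = 0
    missing_feature: str = "Mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_map < 0:
            raise ValueError("patient counts must be non-negative")
        for mean, (lo, hi) in (
            (self.healthy_slice_mean, self.healthy_slice_range),
            (self.map_slice_mean, self.map_slice_range),
        ):
            if not lo <= mean <= hi:
                raise ValueError(f"slice mean {mean} outside range ({lo}, {hi})")
        if abs(sum(self.ctsi_proportions) - 1.0) > 1e-9 or any(
            p < 0 for p in self.ctsi_proportions
        ):
            raise ValueError("ctsi proportions must be non-negative and sum to 1")
        if self.effect_size > 0 and not self.discriminative:
            raise ValueError("effect_size > 0 requires a non-empty discriminative set")
        if self.feature_sd <= 0:
            raise ValueError("feature_sd must be positive")
        if self.n_missing_healthy > self.n_healthy or self.n_missing_map > self.n_map:
            raise ValueError("missing-patient counts exceed cohort size")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _draw_slice_counts(
    rng: np.random.Generator, n: int, mean: float, lo: int, hi: int
) -> np.ndarray:
    sd = max((hi - lo) / _CI_Z, 0.5)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), max(lo, 1), hi).astype(int)


def generate_cohort(
    cfg: CohortConfig, panel: Optional[FeaturePanel] = None
) -> tuple[FeatureMatrix, CohortLabels]:
    """Generate one cohort; byte-identical for identical config (incl. seed)."""
    panel = panel or canonical_panel()
    rng = np.random.default_rng(cfg.seed)
    features = panel.features
    disc = set()
    for f in cfg.discriminative:
        disc.add(panel.resolve(f))
    baseline = {
        f: mu
        for f, mu in zip(
            features,
            rng.normal(cfg.baseline_mean_loc, cfg.baseline_mean_scale, len(features)),
        )
    }

    healthy_ids = [f"H{i + 1:03d}" for i in range(cfg.n_healthy)]
    map_ids = [f"P{i + 1:03d}" for i in range(cfg.n_map)]
    h_slices = _draw_slice_counts(
        rng, cfg.n_healthy, cfg.healthy_slice_mean, *cfg.healthy_slice_range
    )
    m_slices = _draw_slice_counts(rng, cfg.n_map, cfg.map_slice_mean, *cfg.map_slice_range)
    ctsi = rng.choice(4, size=cfg.n_map, p=np.asarray(cfg.ctsi_proportions))

    records = []
    sd = cfg.feature_sd
    for pid, n_sl in zip(healthy_ids, h_slices):
        for s in range(int(n_sl)):
            noise = rng.normal(0.0, sd, len(features))
            for f, eps in zip(features, noise):
                records.append((pid, s, f, baseline[f] + eps))
    for pid, n_sl, grade in zip(map_ids, m_slices, ctsi):
        shift = cfg.effect_size * sd * severity_multiplier(int(grade))
        for s in range(int(n_sl)):
            noise = rng.normal(0.0, sd, len(features))
            for f, eps in zip(features, noise):
                mu = baseline[f] + (shift if f in disc else 0.0)
                records.append((pid, s, f, mu + eps))

    fm = FeatureMatrix(
        pd.DataFrame.from_records(
            records, columns=["patient_id", "slice_index", "feature_name", "value"]
        )
    )
    labels = CohortLabels(
        status={**{p: HEALTHY for p in healthy_ids}, **{p: MAP for p in map_ids}},
        ctsi={p: int(g) for p, g in zip(map_ids, ctsi)},
    )
    if cfg.n_missing_healthy or cfg.n_missing_map:
        victims = healthy_ids[: cfg.n_missing_healthy] + map_ids[: cfg.n_missing_map]
        fm = inject_missing(fm, victims, cfg.missing_feature, panel=panel)
    return fm, labels


def inject_missing(
    fm: FeatureMatrix,
    patient_ids: Sequence[str],
    feature: str,
    panel: Optional[FeaturePanel] = None,
) -> FeatureMatrix:
    """Blank one feature's values for the given patients (exclusion pathway)."""
    panel = panel or canonical_panel()
    feat = panel.resolve(feature)
    present = set(fm.patients())
    for pid in patient_ids:
        if pid not in present:
            raise KeyError(f"patient {pid!r} not in matrix")
    if not patient_ids:
        return FeatureMatrix(fm.data.copy())
    df = fm.data.copy()
    mask = df["patient_id"].isin(set(patient_ids)) & (df["feature_name"] == feat)
    if not mask.any():
        raise KeyError(f"feature {feature!r} has no entries for the given patients")
    df.loc[mask, "value"] = np.nan
    return FeatureMatrix(df)
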