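"""Core data containers for longitudinal biomarker / time-to-event analyses.

A :class:`LongitudinalDataset` bundles three tables in long format:

``measurements``
    one row per (subject, time, feature) observed abundance,
``subjects``
    one row per subject with event/censoring time, event indicator and
    group label,
``features``
    one row per feature with metadata used by screening prefilters
    (unique peptide count, missing-value count).

A :class:`ScenarioConfig` describes one cell of the simulation benchmark
grid (variance level, slope magnitude, group size, visit schedule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "LongitudinalDataset",
    "ConfigurationError",
    "ValidationError",
]

MEASUREMENT_COLUMNS = ["subject_id", "time", "feature_id", "value"]
SUBJECT_COLUMNS = ["subject_id", "event_time", "status", "group"]
FEATURE_COLUMNS = ["feature_id", "n_peptides", "n_missing"]


class ConfigurationError(ValueError):
    """Invalid scenario or run configuration."""


class ValidationError(ValueError):
    """A dataset table violates the long-format contract."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    Cases get trajectory slope ``+slope_coef``, controls ``-slope_coef``.
    Case event times follow a normal law truncated (by rejection) to the
    interval ``(followup_span, study_end]``; controls are administratively
    censored at ``study_end``.
    """

    n_per_group: int = 50
    n_visits: int = 10
    followup_span: float = 15.0
    slope_coef: float = 0.05
    resid_sd: float = 0.5
    intercept_mean: float = 6.0
    rand_int_sd: float = 0.1
    event_mean: float = 18.0
    event_sd: float = 1.0
    study_end: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.n_visits < 2:
            raise ConfigurationError("n_visits must be >= 2")
        if not (0 < self.followup_span < self.event_mean < self.study_end):
            raise ConfigurationError(
                "need 0 < followup_span < event_mean < study_end, got "
                f"{self.followup_span}, {self.event_mean}, {self.study_end}"
            )
        if self.resid_sd <= 0:
            raise ConfigurationError("resid_sd must be > 0")
        if self.rand_int_sd < 0:
            raise ConfigurationError("rand_int_sd must be >= 0")
        if self.slope_coef < 0:
            raise ConfigurationError("slope_coef must be >= 0")
        if self.event_sd <= 0:
            raise ConfigurationError("event_sd must be > 0")

    @property
    def scenario_id(self) -> str:
        return (
            f"var{self.resid_sd:g}_slope{self.slope_coef:g}_n{self.n_per_group}"
            f"_v{self.n_visits}"
        )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass
class LongitudinalDataset:
    """Long-format repeated measurements plus per-subject survival info."""

    measurements: pd.DataFrame
    subjects: pd.DataFrame
    features: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.measurements = self.measurements[MEASUREMENT_COLUMNS].reset_index(drop=True)
        self.subjects = self.subjects[SUBJECT_COLUMNS].reset_index(drop=True)
        self.features = self.features[FEATURE_COLUMNS].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["subject_id"].to_numpy()

    @property
    def feature_ids(self) -> np.ndarray:
        return self.features["feature_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_measurements(self, feature_id) -> pd.DataFrame:
        return self.measurements[self.measurements["feature_id"] == feature_id]

    def single_feature(self, feature_id) -> "LongitudinalDataset":
        """Restrict to one feature (what per-feature model fits consume)."""
        return LongitudinalDataset(
            measurements=self.feature_measurements(feature_id).reset_index(drop=True),
            subjects=self.subjects.copy(),
            features=self.features[self.features["feature_id"] == feature_id].reset_index(
                drop=True
            ),
            truth=self.truth,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> "LongitudinalDataset":
        """Enforce the long-format invariants; raise ValidationError otherwise."""
        meas, subj, feat = self.measurements, self.subjects, self.features
        if subj["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in subjects table")
        if feat["feature_id"].duplicated().any():
            raise ValidationError("duplicate feature_id in features table")
        known_subjects = set(subj["subject_id"])
        known_features = set(feat["feature_id"])
        bad_subj = set(meas["subject_id"]) - known_subjects
        if bad_subj:
            raise ValidationError(f"measurements reference unknown subjects: {sorted(bad_subj)[:5]}")
        bad_feat = set(meas["feature_id"]) - known_features
        if bad_feat:
            raise ValidationError(f"measurements reference unknown features: {sorted(bad_feat)[:5]}")
        dup = meas.duplicated(subset=["subject_id", "time", "feature_id"])
        if dup.any():
            row = meas[dup].iloc[0]
            raise ValidationError(
                "duplicate (subject, time, feature) measurement: "
                f"({row['subject_id']}, {row['time']}, {row['feature_id']})"
            )
        if not subj["status"].isin([0, 1]).all():
            raise ValidationError("status must be 0/1")
        # no post-event samples for cases
        cases = subj[subj["status"] == 1]
        if len(cases):
            merged = meas.merge(
                cases[["subject_id", "event_time"]], on="subject_id", how="inner"
            )
            late = merged[merged["time"] > merged["event_time"] + 1e-12]
            if len(late):
                row = late.iloc[0]
                raise ValidationError(
                    f"post-event measurement for case subject {row['subject_id']} "
                    f"at time {row['time']} > event_time {row['event_time']}"
                )
        return self

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return (
            self.measurements.equals(other.measurements)
            and self.subjects.equals(other.subjects)
            and self.features.equals(other.features)
        )
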