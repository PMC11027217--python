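"""Shared domain types and constants for the DDI surveillance pipeline.

The pipeline analyzes longitudinal drug-dispensation data at one of two
temporal resolutions:

* ``daily`` — each record carries a start date and a duration in days; two
  drugs are co-administered if their administration day sets share at least
  one day.
* ``monthly`` — each record is one billing month; two drugs are
  co-administered if they are billed in the same calendar month.

Day intervals are half-open ``[start, start + duration)`` throughout.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import pandas as pd

RESOLUTIONS = ("daily", "monthly")
SEVERITIES = ("major", "moderate", "minor")
GENDERS = ("W", "M")

#: 5-year age bins used for all age stratifications.
AGE_BIN_LABELS: tuple[str, ...] = tuple(
    f"{5 * i}-{5 * i + 4}" for i in range(18)
) + ("90+",)
N_AGE_BINS = len(AGE_BIN_LABELS)


class DataError(ValueError):
    """Malformed or inconsistent input data (distinct from usage errors)."""


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class StudyWindow:
    """Observation window of the study.

    ``start`` and ``end`` are inclusive calendar dates; in daily mode the
    window covers the half-open day range ``[start, end + 1 day)``.
    """

    start: _dt.date
    end: _dt.date
    resolution: str = "daily"

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.start > self.end:
            raise ValueError("StudyWindow: start must be <= end")
        if self.resolution not in RESOLUTIONS:
            raise ValueError(
                f"StudyWindow: resolution must be one of {RESOLUTIONS}, "
                f"got {self.resolution!r}"
            )

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    @property
    def end_ts(self) -> pd.Timestamp:
        """Exclusive end bound (day after the last included day)."""
        return pd.Timestamp(self.end) + pd.Timedelta(days=1)

    @property
    def n_days(self) -> int:
        return (pd.Timestamp(self.end) - pd.Timestamp(self.start)).days + 1

    def month_starts(self) -> pd.DatetimeIndex:
        """First day of each calendar month intersecting the window."""
        first = pd.Timestamp(self.start).to_period("M").to_timestamp()
        last = pd.Timestamp(self.end).to_period("M").to_timestamp()
        return pd.date_range(first, last, freq="MS")


@dataclass(frozen=True)
class PlantedEffect:
    """A localized boost (or suppression) of co-dispensation of one pair.

    ``risk_multiplier`` m scales the probability that both pair members are
    dispensed with temporal overlap for patients in the targeted
    gender/age-bin stratum: probability q under m = 1 becomes q * m
    (capped at 1). m = 0 removes all qualifying overlaps.
    """

    drug_a: str
    drug_b: str
    gender: str = "both"  # {"W", "M", "both"}
    age_bin_range: tuple[int, int] = (0, N_AGE_BINS - 1)  # inclusive bin idx
    risk_multiplier: float = 1.0

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError("PlantedEffect: pair members must be distinct")
        if self.gender not in ("W", "M", "both"):
            raise ValueError("PlantedEffect: gender must be W, M or both")
        if self.risk_multiplier < 0:
            raise ValueError("PlantedEffect: risk_multiplier must be >= 0")
        lo, hi = self.age_bin_range
        if not (0 <= lo <= hi <= N_AGE_BINS - 1):
            raise ValueError("PlantedEffect: invalid age_bin_range")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic EHR generator.

    Defaults emulate an 18-month municipal cohort: a Zipf-like drug
    popularity law, overdispersed polypharmacy whose mean rises with age,
    a small set of gender-specific drugs, and a sparse interaction
    reference with severity labels.
    """

    n_patients: int = 1000
    gender_ratio: float = 0.5  # fraction of women
    age_range: tuple[int, int] = (0, 89)  # completed years at study start
    n_drugs: int = 150
    popularity_exponent: float = 1.2
    polypharmacy_slope: float = 0.8  # extra distinct drugs per decade of age
    baseline_mean_drugs: float = 3.0  # mean distinct drugs at age 0
    drug_count_dispersion: float = 5.0  # negative-binomial size parameter
    mean_duration_days: float = 75.0
    refill_prob: float = 0.25  # chance of a second dispensation per drug
    ddi_fraction: float = 0.035
    severity_probs: tuple[float, float, float] = (0.3, 0.5, 0.2)
    gender_specific_fraction: float = 0.02
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    resolution: str = "daily"
    study_window: tuple[_dt.date, _dt.date] = (
        _dt.date(2014, 1, 1),
        _dt.date(2015, 6, 30),
    )
    n_class_alternatives: int = 3
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("SyntheticConfig: n_patients must be >= 1")
        if self.n_drugs < 1:
            raise ValueError("SyntheticConfig: n_drugs must be >= 1")
        if not 0.0 <= self.gender_ratio <= 1.0:
            raise ValueError("SyntheticConfig: gender_ratio must be in [0,1]")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("SyntheticConfig: age_range min must be <= max, >= 0")
        if self.popularity_exponent <= 0:
            raise ValueError("SyntheticConfig: popularity_exponent must be > 0")
        if self.polypharmacy_slope < 0:
            raise ValueError("SyntheticConfig: polypharmacy_slope must be >= 0")
        if self.mean_duration_days <= 0:
            raise ValueError("SyntheticConfig: mean_duration_days must be > 0")
        if not 0.0 <= self.ddi_fraction <= 1.0:
            raise ValueError("SyntheticConfig: ddi_fraction must be in [0,1]")
        probs = self.severity_probs
        if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
            raise ValueError("SyntheticConfig: severity_probs must be 3 values in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("SyntheticConfig: severity_probs must sum to 1")
        if not 0.0 <= self.gender_specific_fraction <= 1.0:
            raise ValueError(
                "SyntheticConfig: gender_specific_fraction must be in [0,1]"
            )
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"SyntheticConfig: resolution must be one of {RESOLUTIONS}")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(
            self.study_window[0], self.study_window[1], self.resolution
        )


@dataclass(frozen=True)
class NullModelConfig:
    """Settings of the age-matched random-dispensation null model."""

    n_reps: int = 100
    sampling: str = "frequency_weighted"  # or "uniform_distinct"
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("NullModelConfig: n_reps must be >= 1")
        if self.sampling not in ("frequency_weighted", "uniform_distinct"):
            raise ValueError(
                "NullModelConfig: sampling must be frequency_weighted or "
                "uniform_distinct"
            )


def age_bin_index(age_years) -> "pd.Series | int":
    """Map completed-years age to a 5-year bin index (18 == '90+')."""
    import numpy as np

    return np.minimum(np.asarray(age_years) // 5, N_AGE_BINS - 1)
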