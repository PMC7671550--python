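"""Cohort filtering and imputation for daily CSMS series.

Patients with too many missing days are excluded (default cut-off: retain
when the missing fraction is at most 37.5%), as are degenerate recorders
whose observed values never vary (e.g. a diary with no symptoms and no
drugs every single day).  Remaining gaps are imputed: leading gaps carry
the first observed value backwards, trailing gaps carry the last observed
value forwards, and interior gaps are filled by linear interpolation
between the flanking observed days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scores import ScoreSeries

__all__ = [
    "Exclusion",
    "CohortTable",
    "missing_fraction",
    "filter_cohort",
    "impute",
    "impute_cohort",
]

DEFAULT_CUTOFF = 0.375


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str  # "cutoff" or "zero_variance"


@dataclass
class CohortTable:
    """Retained per-patient series on a common window plus an exclusion log."""

    series: list
    exclusions: list = field(default_factory=list)

    def __post_init__(self):
        if not self.series:
            raise ValueError("empty cohort")
        t0 = self.series[0].times
        for s in self.series[1:]:
            if not np.array_equal(s.times, t0):
                raise ValueError("all cohort series must share the same time grid")

    @property
    def n_patients(self) -> int:
        return len(self.series)

    @property
    def times(self) -> np.ndarray:
        return self.series[0].times

    @property
    def patient_ids(self) -> list:
        return [s.patient_id for s in self.series]

    def to_matrix(self) -> np.ndarray:
        """Stack values as an (n_patients, n_days) array."""
        return np.vstack([s.values for s in self.series])

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.patient_id, e.reason) for e in self.exclusions],
            columns=["patient_id", "reason"],
        )


def missing_fraction(series: ScoreSeries) -> float:
    """Fraction of the observation window with no usable entry."""
    if series.n_days == 0:
        raise ValueError("empty series")
    return float(series.mask.sum()) / series.n_days


def filter_cohort(
    series,
    cutoff: float = DEFAULT_CUTOFF,
    drop_constant: bool = True,
) -> CohortTable:
    """Apply the missingness cut-off and the zero-variance outlier rule.

    A series is retained when its missing fraction is <= ``cutoff``
    (inclusive: a patient at exactly the cut-off is kept).  With
    ``drop_constant``, series whose observed values have zero variance are
    excluded as degenerate recorders.  Every exclusion is logged with its
    reason.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    retained, excluded = [], []
    for s in series:
        if missing_fraction(s) > cutoff:
            excluded.append(Exclusion(s.patient_id, "cutoff"))
            continue
        obs = s.values[~s.mask]
        if drop_constant and (obs.size == 0 or np.ptp(obs) == 0):
            excluded.append(Exclusion(s.patient_id, "zero_variance"))
            continue
        retained.append(s)
    if not retained:
        raise ValueError("no series retained after filtering")
    return CohortTable(retained, excluded)


def impute(series: ScoreSeries) -> ScoreSeries:
    """Fill missing days; returns a series with an empty mask.

    Leading missing days take the first observed value, trailing ones the
    last observed value, and an interior gap of length w-1 between observed
    values y_t' and y_{t'+w} is filled linearly:
    y_{t'+t''} = y_t' + (y_{t'+w} - y_t') * t'' / w.
    Observed values are never altered, so the operation is idempotent.
    """
    if series.mask.all():
        raise ValueError("cannot impute an all-missing series")
    if not series.mask.any():
        return replace(series, values=series.values.copy(), mask=series.mask.copy())
    obs = ~series.mask
    # np.interp implements exactly these rules: linear interiors, constant
    # extrapolation at both ends.
    filled = np.interp(series.times, series.times[obs], series.values[obs])
    filled[obs] = series.values[obs]
    return replace(series, values=filled, mask=np.zeros_like(series.mask))


def impute_cohort(cohort: CohortTable) -> CohortTable:
    """Impute every retained series, preserving the exclusion log."""
    return CohortTable([impute(s) for s in cohort.series], list(cohort.exclusions))
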