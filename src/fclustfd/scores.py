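"""Symptom–medication scoring for allergic rhinoconjunctivitis diaries.

Daily app entries record six rhinoconjunctivitis symptom intensities on a
0-3 scale (sneezing, rhinorrhea, pruritus, nasal congestion, ocular
pruritus, lacrimation) and the category of rescue medication taken
(0 = none, 1 = antihistamine, 2 = nasal corticosteroid, 3 = oral
corticosteroid).  From these the module computes

* ARTSS — the arithmetic mean of the six symptom intensities, in [0, 3];
* RMS   — the (highest) daily medication category, in {0, 1, 2, 3};
* CSMS  — ARTSS + RMS, in [0, 6], the combined symptom and medication score.

CSMS series are normalized to [0, 1] by dividing by 6; pollen-count series
are normalized by their maximum over the reference window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SYMPTOM_COLUMNS",
    "DailySymptomRecord",
    "ScoreSeries",
    "artss",
    "rms",
    "csms",
    "normalize_csms",
    "normalize_pollen",
    "score_records",
    "to_score_series",
    "read_daily_records",
    "write_score_series",
]

#: Canonical symptom column order: four nasal then two ocular features.
SYMPTOM_COLUMNS = (
    "sneezing",
    "rhinorrhea",
    "pruritus",
    "nasal_congestion",
    "ocular_pruritus",
    "lacrimation",
)

N_SYMPTOMS = len(SYMPTOM_COLUMNS)

#: Raw CSMS scale maximum (ARTSS max 3 + RMS max 3).
CSMS_MAX = 6.0


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


@dataclass(frozen=True)
class DailySymptomRecord:
    """One patient-day of raw diary entries.

    ``symptoms`` holds the six intensities in :data:`SYMPTOM_COLUMNS` order;
    ``None``/NaN marks a missing entry.  ``medication`` is the daily rescue
    medication category (if several drugs were taken, the highest category
    is recorded upstream).
    """

    patient_id: str
    day: int
    symptoms: tuple = field(default=(None,) * N_SYMPTOMS)
    medication: float | None = None

    def __post_init__(self):
        if len(self.symptoms) != N_SYMPTOMS:
            raise ValueError(f"expected {N_SYMPTOMS} symptom values, got {len(self.symptoms)}")
        if self.day < 1:
            raise ValueError("day index must be >= 1")
        for v in self.symptoms:
            if not _is_missing(v) and not (0 <= v <= 3):
                raise ValueError(f"symptom intensity {v!r} outside [0, 3]")
        m = self.medication
        if not _is_missing(m) and m not in (0, 1, 2, 3):
            raise ValueError(f"medication category {m!r} not in {{0, 1, 2, 3}}")


def artss(record: DailySymptomRecord) -> float:
    """Average Rhinoconjunctivitis Total Symptom Score.

    Mean of the six symptom intensities; NaN (a missing-day signal for the
    preprocessing stage) when any of the six is missing.
    """
    if any(_is_missing(v) for v in record.symptoms):
        return float("nan")
    return float(np.mean([float(v) for v in record.symptoms]))


def rms(record: DailySymptomRecord) -> float:
    """Rescue Medication Score (daily medication category).

    A day with symptoms recorded but no medication entry counts as "no
    medication taken", i.e. RMS = 0.  A fully missing day yields NaN.
    """
    if not _is_missing(record.medication):
        return float(record.medication)
    if all(not _is_missing(v) for v in record.symptoms):
        return 0.0
    return float("nan")


def csms(record: DailySymptomRecord) -> float:
    """Combined Symptom and Medication Score: ARTSS + RMS, in [0, 6]."""
    a = artss(record)
    if np.isnan(a):
        return float("nan")
    return a + rms(record)


@dataclass
class ScoreSeries:
    """A per-patient daily CSMS series on days 1..v with a missingness mask.

    ``mask[j]`` is True where day ``times[j]`` is missing (``values[j]`` is
    then NaN).  ``normalized`` distinguishes the raw [0, 6] scale from the
    [0, 1] scale obtained by dividing by 6.
    """

    patient_id: str
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.mask)):
            raise ValueError("times, values and mask must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty series")
        obs = self.values[~self.mask]
        hi = 1.0 if self.normalized else CSMS_MAX
        if obs.size and (np.nanmin(obs) < -1e-12 or np.nanmax(obs) > hi + 1e-12):
            raise ValueError(f"observed values outside [0, {hi}]")

    @property
    def n_days(self) -> int:
        return len(self.times)


def normalize_csms(series: ScoreSeries) -> ScoreSeries:
    """Return the series on the [0, 1] scale (raw CSMS divided by 6)."""
    if series.normalized:
        raise ValueError("series is already normalized")
    return replace(
        series,
        values=series.values / CSMS_MAX,
        mask=series.mask.copy(),
        normalized=True,
    )


def normalize_pollen(counts) -> np.ndarray:
    """Normalize a pollen-count series by its maximum over the window.

    The maximum observed level maps to 1.  Raises if the series has no
    strictly positive count (no scale to divide by).
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty pollen series")
    if np.any(x < 0):
        raise ValueError("negative pollen counts")
    peak = np.nanmax(x)
    if not peak > 0:
        raise ValueError("all-zero pollen series has no scale")
    return x / peak


# ---------------------------------------------------------------------------
# Table-level interface

def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Compute ARTSS, RMS and CSMS for a long-format record table.

    Expects columns ``patient_id``, ``day``, the six symptom columns of
    :data:`SYMPTOM_COLUMNS` and ``medication``; blank cells are missing.
    A day with any symptom entry missing is a missing day (ARTSS is
    undefined without all six features); symptoms present with medication
    absent means RMS = 0.
    """
    missing = [c for c in ("patient_id", "day", *SYMPTOM_COLUMNS, "medication") if c not in records]
    if missing:
        raise ValueError(f"record table lacks columns: {missing}")
    sym = records.loc[:, list(SYMPTOM_COLUMNS)].astype(float)
    if ((sym < 0) | (sym > 3)).any().any():
        raise ValueError("symptom intensities outside [0, 3]")
    med = records["medication"].astype(float)
    if (~med.isin([0, 1, 2, 3]) & med.notna()).any():
        raise ValueError("medication categories outside {0, 1, 2, 3}")

    out = records.loc[:, ["patient_id", "day"]].copy()
    complete = sym.notna().all(axis=1)
    out["artss"] = sym.mean(axis=1).where(complete)
    out["rms"] = med.fillna(0.0).where(complete | med.notna())
    out["csms"] = out["artss"] + out["rms"]
    return out


def to_score_series(scored: pd.DataFrame, n_days: int | None = None) -> list[ScoreSeries]:
    """Pivot a scored table into per-patient :class:`ScoreSeries`.

    All series are placed on the common window 1..v where v defaults to the
    largest day present; days a patient never entered are missing.
    """
    if n_days is None:
        n_days = int(scored["day"].max())
    days = np.arange(1, n_days + 1)
    wide = scored.pivot_table(index="patient_id", columns="day", values="csms", dropna=False)
    wide = wide.reindex(columns=days)
    series = []
    for pid, row in wide.iterrows():
        values = row.to_numpy(dtype=float)
        mask = np.isnan(values)
        series.append(ScoreSeries(str(pid), days, values, mask))
    return series


def read_daily_records(path, sep: str = ",") -> pd.DataFrame:
    """Read a long-format delimited record table (blank cells = missing)."""
    return pd.read_csv(path, sep=sep)


def write_score_series(series: list[ScoreSeries], path, sep: str = ",") -> None:
    """Write CSMS series as a tidy (patient_id, day, csms, missing) table."""
    frames = [
        pd.DataFrame(
            {
                "patient_id": s.patient_id,
                "day": s.times,
                "csms": s.values,
                "missing": s.mask.astype(int),
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
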