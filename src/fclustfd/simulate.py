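"""Synthetic cohorts with known cluster structure.

The generator emulates a pollen-season diary study: each cluster has a
smooth normalized-CSMS template curve on a 30-40 day window, patients are
jittered copies of their cluster template (multiplicative amplitude and
additive shift jitter) plus Gaussian noise, clipped to [0, 1]; days are
then masked completely at random.  Each daily value is decomposed back
into a consistent six-symptom + medication record so the full scoring and
preprocessing pipeline can be exercised end to end.  Pollen-count curves
(grains/m^3) are bell-shaped seasonal bumps; the "pollen-tracking"
template follows the first pollen's normalized curve, planting a cluster
whose symptoms are genuinely correlated with that taxon.

Template shapes (all map day fraction t in [0, 1] to [0, 1]):

* ``flat-low``   — mild, level symptoms at 0.10;
* ``flat-high``  — severe, level symptoms at 0.60;
* ``peak-then-decline`` — early flare near t = 0.3 decaying afterwards;
* ``pollen-tracking``   — baseline 0.12 plus 0.68 x the normalized pollen bump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scores import SYMPTOM_COLUMNS

__all__ = [
    "CohortDesign",
    "generate_cohort",
    "generate_coefficient_blobs",
    "template_curve",
    "pollen_template",
    "decompose_csms",
]


def pollen_template(t, peak_at: float = 0.4, width: float = 0.12) -> np.ndarray:
    """Normalized bell-shaped pollen season curve on day fraction t."""
    t = np.asarray(t, dtype=float)
    return np.exp(-0.5 * ((t - peak_at) / width) ** 2)


def template_curve(name: str, t, pollen=None) -> np.ndarray:
    """Evaluate a named cluster template on day fractions t in [0, 1]."""
    t = np.asarray(t, dtype=float)
    if name == "flat-low":
        return np.full_like(t, 0.10)
    if name == "flat-high":
        return np.full_like(t, 0.60)
    if name == "peak-then-decline":
        return 0.15 + 0.55 * np.exp(-0.5 * ((t - 0.3) / 0.15) ** 2) * (1 - 0.3 * t)
    if name == "pollen-tracking":
        base = pollen_template(t) if pollen is None else np.asarray(pollen, float)
        return 0.12 + 0.68 * base
    raise ValueError(f"unknown template {name!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic diary cohort.

    Defaults emulate the larger of the two study settings: a 40-day window
    with three clusters of 30 patients (severe, mild, pollen-tracking),
    observation noise sd 0.05 on the [0, 1] CSMS scale and 10% of days
    missing completely at random.  Pollen peaks (grains/m^3) are in the
    range reported for a prosperous season.
    """

    templates: tuple = ("flat-high", "flat-low", "pollen-tracking")
    patients_per_cluster: int = 30
    n_days: int = 40
    noise_sd: float = 0.05
    missing_rate: float = 0.10
    amplitude_sd: float = 0.08
    shift_sd: float = 0.03
    pollen_peaks: dict = field(
        default_factory=lambda: {"Gramineae": 200.0, "Olea": 400.0, "Urticaceae": 60.0}
    )
    pollen_peak_days: dict = field(
        default_factory=lambda: {"Gramineae": 0.4, "Olea": 0.45, "Urticaceae": 0.6}
    )
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_days < 2 or self.patients_per_cluster < 1:
            raise ValueError("degenerate design")

    @property
    def n_clusters(self) -> int:
        return len(self.templates)

    @property
    def n_patients(self) -> int:
        return self.n_clusters * self.patients_per_cluster


def decompose_csms(raw: float):
    """Split a raw CSMS target in [0, 6] into six symptoms and a medication.

    The medication category takes the integer excess above the symptom
    scale (0 while the target is within [0, 3]); the remainder is spread
    over the six symptoms as evenly as integer intensities allow.  The
    reconstructed ARTSS + RMS is within 1/12 of the target.
    """
    if not 0 <= raw <= 6:
        raise ValueError("raw CSMS target outside [0, 6]")
    med = 0 if raw <= 3 else min(3, int(np.ceil(raw - 3)))
    total = int(round(6 * (raw - med)))
    total = min(max(total, 0), 18)
    base, extra = divmod(total, 6)
    symptoms = tuple(base + 1 if j < extra else base for j in range(6))
    return symptoms, med


def generate_cohort(design: CohortDesign):
    """Generate (records, labels, pollen) for a :class:`CohortDesign`.

    Returns a long-format daily record table (one row per patient-day,
    missing days have blank symptom and medication cells), the true
    cluster label per patient, and a per-day pollen-count table.
    Deterministic under the design's seed.
    """
    rng = np.random.default_rng(design.seed)
    days = np.arange(1, design.n_days + 1)
    t = (days - 1) / (design.n_days - 1)

    pollen = pd.DataFrame({"day": days})
    for taxon, peak in design.pollen_peaks.items():
        shape = pollen_template(t, peak_at=design.pollen_peak_days[taxon])
        pollen[taxon] = peak * shape
    first_taxon = next(iter(design.pollen_peaks))
    tracking = pollen[first_taxon].to_numpy() / pollen[first_taxon].max()

    rows, labels = [], []
    patient = 0
    for cluster, name in enumerate(design.templates):
        base = template_curve(name, t, pollen=tracking if name == "pollen-tracking" else None)
        for _ in range(design.patients_per_cluster):
            patient += 1
            pid = f"P{patient:03d}"
            labels.append(cluster)
            amp = rng.normal(1.0, design.amplitude_sd)
            shift = rng.normal(0.0, design.shift_sd)
            curve = np.clip(
                amp * base + shift + rng.normal(0.0, design.noise_sd, design.n_days),
                0.0,
                1.0,
            )
            missing = rng.random(design.n_days) < design.missing_rate
            for j, day in enumerate(days):
                if missing[j]:
                    rows.append((pid, int(day)) + (np.nan,) * 6 + (np.nan,))
                else:
                    symptoms, med = decompose_csms(6.0 * curve[j])
                    rows.append((pid, int(day)) + tuple(float(s) for s in symptoms) + (float(med),))

    records = pd.DataFrame(
        rows, columns=["patient_id", "day", *SYMPTOM_COLUMNS, "medication"]
    )
    return records, np.array(labels), pollen


def generate_coefficient_blobs(n_per_cluster: int, centers, spread: float, seed=None):
    """Gaussian blobs in coefficient space around the given centers.

    Direct fixture for the clustering stage: returns ``(C, labels)`` with
    ``n_per_cluster`` points per center.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if len(centers) != len({tuple(c) for c in centers}):
        raise ValueError("centers must be pairwise distinct")
    rng = np.random.default_rng(seed)
    C, labels = [], []
    for l, center in enumerate(centers):
        C.append(center + spread * rng.standard_normal((n_per_cluster, centers.shape[1])))
        labels.extend([l] * n_per_cluster)
    return np.vstack(C), np.array(labels)
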