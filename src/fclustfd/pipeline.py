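"""End-to-end pipeline: score -> filter/impute -> smooth -> cluster -> validate -> associate.

``run_pipeline`` chains every stage on a long-format daily record table
(and optionally a pollen-count table), writes each artifact as delimited
text together with a config snapshot, and is a pure function of
(inputs, config, seed): a rerun with the same seed reproduces every
output bit for bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import preprocessing, scores
from .association import ARpTable, arp_index, cluster_arp_summary
from .clustering import FuzzyKMedoids
from .smoothing import DEFAULT_GRID, GridSearchResult, PenalizedBSplineSmoother, tgcv_grid_search
from .validity import KSelectionResult, adjusted_rand_index, select_k

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sensitivity_analysis"]

log = logging.getLogger("fclustfd")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with the study defaults."""

    missing_cutoff: float = 0.375
    drop_constant: bool = True
    q_options: tuple = (5, 10, 15, 20)
    m_options: tuple = (4, 6)
    lambda_grid: tuple = DEFAULT_GRID
    parsimony_tol: float = 0.0
    fuzziness: float = 1.5
    k_range: tuple = (2, 3, 4, 5)
    n_starts: int = 30
    tol: float = 1e-6
    max_iter: int = 1000
    gamma: float = 1.0
    silhouette_metric: str = "sqeuclidean"
    k_tolerance: float = 0.05
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("q_options", "m_options", "lambda_grid", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    config: PipelineConfig
    cohort: preprocessing.CohortTable
    grid: GridSearchResult
    smoother: PenalizedBSplineSmoother
    coefficients: np.ndarray
    selection: KSelectionResult
    best_model: FuzzyKMedoids
    arp: ARpTable | None = None
    arp_summary: pd.DataFrame | None = None
    pollen_coefficients: np.ndarray | None = None

    @property
    def selected_k(self) -> int:
        return self.selection.best_k

    @property
    def membership(self) -> np.ndarray:
        return self.best_model.membership_

    @property
    def labels(self) -> np.ndarray:
        return self.best_model.labels_

    def membership_frame(self) -> pd.DataFrame:
        U = self.membership
        df = pd.DataFrame(
            U, columns=[f"u_{l + 1}" for l in range(U.shape[1])]
        )
        df.insert(0, "patient_id", self.cohort.patient_ids)
        df["max_cluster"] = self.labels + 1
        df["max_membership"] = U.max(axis=1)
        return df


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(records, config: PipelineConfig | None = None, pollen=None, out_dir=None) -> PipelineResult:
    """Run the full analysis on a long-format record table.

    ``records`` is a DataFrame (or path) with patient_id, day, the six
    symptom columns and medication; ``pollen`` an optional day-indexed
    count table with one column per taxon.  When ``out_dir`` is given,
    every artifact is written there as CSV plus a YAML config snapshot.
    """
    config = config or PipelineConfig()
    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        records = scores.read_daily_records(records)
    if pollen is not None and (isinstance(pollen, (str, bytes)) or hasattr(pollen, "__fspath__")):
        pollen = pd.read_csv(pollen)

    t0 = _stage("score")
    scored = scores.score_records(records)
    series = scores.to_score_series(scored)

    _stage("preprocess")
    cohort = preprocessing.filter_cohort(
        series, cutoff=config.missing_cutoff, drop_constant=config.drop_constant
    )
    cohort = preprocessing.impute_cohort(cohort)
    normalized = [scores.normalize_csms(s) for s in cohort.series]
    cohort = preprocessing.CohortTable(normalized, cohort.exclusions)
    X = cohort.to_matrix()
    times = cohort.times.astype(float)

    _stage("fit")
    grid = tgcv_grid_search(
        X,
        times,
        q_options=config.q_options,
        m_options=config.m_options,
        grid=config.lambda_grid,
        parsimony_tol=config.parsimony_tol,
    )
    q_star, m_star = grid.selected
    smoother = PenalizedBSplineSmoother(
        n_knots=q_star, order=m_star, smoothing=grid.lambda_, times=times
    ).fit(X)
    C = smoother.coef_

    _stage("cluster/validate")
    selection = select_k(
        C,
        config.k_range,
        fuzziness=config.fuzziness,
        gamma=config.gamma,
        metric=config.silhouette_metric,
        tolerance=config.k_tolerance,
        n_starts=config.n_starts,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    best = selection.partitions[selection.best_k]

    arp_table = summary = pollen_C = None
    if pollen is not None:
        _stage("associate")
        taxa = [c for c in pollen.columns if c != "day"]
        pollen_norm = np.vstack(
            [scores.normalize_pollen(pollen[c].to_numpy()) for c in taxa]
        )
        pollen_C = smoother.transform(pollen_norm)
        arp_table = arp_index(
            C,
            pollen_C,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
            patient_ids=cohort.patient_ids,
            pollen_names=taxa,
        )
        summary = cluster_arp_summary(arp_table, best.membership_)

    result = PipelineResult(
        config=config,
        cohort=cohort,
        grid=grid,
        smoother=smoother,
        coefficients=C,
        selection=selection,
        best_model=best,
        arp=arp_table,
        arp_summary=summary,
        pollen_coefficients=pollen_C,
    )
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return result


def _write_artifacts(result: PipelineResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    scores.write_score_series(result.cohort.series, out / "scores.csv")
    result.cohort.exclusion_frame().to_csv(out / "exclusions.csv", index=False)
    coef = pd.DataFrame(
        result.coefficients,
        columns=[f"p{j + 1}" for j in range(result.coefficients.shape[1])],
    )
    coef.insert(0, "patient_id", result.cohort.patient_ids)
    coef.to_csv(out / "coefficients.csv", index=False)
    result.grid.table.to_csv(out / "grid_search.csv", index=False)
    result.selection.table.to_csv(out / "validity.csv", index=False)
    result.membership_frame().to_csv(out / "membership.csv", index=False)
    if result.arp is not None:
        result.arp.arp.to_csv(out / "arp.csv")
        result.arp.correlations.to_csv(out / "arp_correlations.csv")
        result.arp.p_values.to_csv(out / "arp_pvalues.csv")
        result.arp_summary.to_csv(out / "arp_cluster_summary.csv")


def sensitivity_analysis(records, config: PipelineConfig | None = None, cutoffs=(0.25, 0.375, 0.50)) -> pd.DataFrame:
    """Partition stability across missingness cut-offs.

    Reruns the pipeline at each cut-off and reports the ARI between every
    pair of resulting hard partitions (restricted to the patients retained
    by both runs).
    """
    config = config or PipelineConfig()
    results = {}
    for cutoff in cutoffs:
        results[cutoff] = run_pipeline(records, replace(config, missing_cutoff=cutoff))
    rows = []
    items = sorted(results)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            ra, rb = results[a], results[b]
            ids_a = {pid: j for j, pid in enumerate(ra.cohort.patient_ids)}
            common = [pid for pid in rb.cohort.patient_ids if pid in ids_a]
            la = [ra.labels[ids_a[pid]] for pid in common]
            ids_b = {pid: j for j, pid in enumerate(rb.cohort.patient_ids)}
            lb = [rb.labels[ids_b[pid]] for pid in common]
            rows.append((a, b, len(common), adjusted_rand_index(la, lb)))
    return pd.DataFrame(rows, columns=["cutoff_a", "cutoff_b", "n_common", "ARI"])
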