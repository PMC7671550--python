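"""Patient-pollen association via permutation Spearman tests (ARp index).

Whether a patient's symptom course tracks a pollen taxon is assessed on
the B-spline coefficient vectors of the patient and pollen curves (the
coefficients of a smoothed curve are serially dependent, so the classical
correlation test is replaced by a permutation test, which needs only
exchangeability under the null).  For patient i and pollen u the Spearman
correlation r_iu is tested one-sided for positivity with

    p = (1 + #{permuted r >= observed r}) / (n_perm + 1),

permuting one coefficient vector with a seeded generator (the add-one
estimator never reports p = 0).  The ARp index is then

    ARp_iu = 0                      if p_iu > alpha,
    ARp_iu = r_iu / sum of the patient's significant r   otherwise,

so each patient's ARp row sums to 1 over its significant pollens (all
significant r are positive under the one-sided test, hence ARp in
[0, 1]).  Cluster summaries report membership-weighted mean ARp per
pollen over the patients assigned to each cluster, plus the fraction of
those patients with ARp = 1 (a single dominant pollen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .validity import harden

__all__ = [
    "ARpTable",
    "spearman_permutation_test",
    "arp_index",
    "cluster_arp_summary",
]

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05


def _rank_and_check(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError(f"{name} is constant: ranks are undefined")
    return rankdata(x)


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def spearman_permutation_test(x, y, n_perm: int = DEFAULT_N_PERM, seed=None):
    """One-sided permutation test for a positive Spearman correlation.

    Returns ``(r, p)`` where r is the Spearman rank correlation of x and y
    and p tests H1: r > 0 against ``n_perm`` random permutations of y.
    """
    rx = _rank_and_check(x, "x")
    ry = _rank_and_check(y, "y")
    if len(rx) != len(ry):
        raise ValueError("x and y must have equal length")
    r_obs = _pearson_on_ranks(rx, ry)
    rng = np.random.default_rng(seed)
    n = len(rx)
    rxc = rx - rx.mean()
    sx = np.sqrt(rxc @ rxc)
    # permute y's ranks in blocks; correlation reduces to a dot product
    perm_r = np.empty(n_perm)
    block = 512
    ryc = ry - ry.mean()
    sy = np.sqrt(ryc @ ryc)
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm_r[start : start + b] = (ryc[idx] @ rxc) / (sx * sy)
    p = (1.0 + np.count_nonzero(perm_r >= r_obs)) / (n_perm + 1.0)
    return r_obs, float(p)


@dataclass
class ARpTable:
    """Patient-by-pollen association indices with the underlying tests."""

    arp: pd.DataFrame  # patients x pollens, ARp in [0, 1]
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    alpha: float
    n_perm: int

    @property
    def pollens(self) -> list:
        return list(self.arp.columns)


def arp_index(
    patient_coefs,
    pollen_coefs,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
    patient_ids=None,
    pollen_names=None,
) -> ARpTable:
    """Compute the ARp index for every patient and pollen.

    ``patient_coefs`` is (n_patients, s) and ``pollen_coefs`` is
    (n_pollens, s), both from the same basis so coefficients are
    comparable.  Non-significant pairs get ARp = 0; otherwise ARp is the
    patient's significant correlation normalized by the sum of all its
    significant correlations.
    """
    P = np.atleast_2d(np.asarray(patient_coefs, dtype=float))
    G = np.atleast_2d(np.asarray(pollen_coefs, dtype=float))
    if G.shape[0] < 1:
        raise ValueError("need at least one pollen")
    if P.shape[1] != G.shape[1]:
        raise ValueError("patient and pollen coefficient lengths differ")
    if patient_ids is None:
        patient_ids = [f"patient_{i + 1}" for i in range(P.shape[0])]
    if pollen_names is None:
        pollen_names = [f"pollen_{u + 1}" for u in range(G.shape[0])]

    rng = np.random.default_rng(seed)
    r = np.empty((P.shape[0], G.shape[0]))
    p = np.empty_like(r)
    for i in range(P.shape[0]):
        for u in range(G.shape[0]):
            r[i, u], p[i, u] = spearman_permutation_test(
                P[i], G[u], n_perm=n_perm, seed=rng.integers(2**31)
            )
    significant = p <= alpha
    arp = np.zeros_like(r)
    for i in range(P.shape[0]):
        sig = significant[i]
        if sig.any():
            arp[i, sig] = r[i, sig] / r[i, sig].sum()
    make = lambda M: pd.DataFrame(M, index=patient_ids, columns=pollen_names)
    return ARpTable(make(arp), make(r), make(p), alpha, n_perm)


def cluster_arp_summary(table: ARpTable, U, patient_ids=None) -> pd.DataFrame:
    """Membership-weighted cluster summaries of the ARp indices.

    Each patient is assigned to the cluster of its maximum membership; for
    cluster l and pollen u the summary is
    sum_{i in l} u_il * ARp_iu / sum_{i in l} u_il, alongside the
    percentage of the cluster's patients with ARp_iu = 1.  A "Total" row
    summarizes all patients (uniform weights).
    """
    U = np.asarray(U, dtype=float)
    arp = table.arp.to_numpy()
    if U.shape[0] != arp.shape[0]:
        raise ValueError("membership rows do not align with the ARp table")
    labels = harden(U)
    rows, index = [], []
    one = arp >= 1.0 - 1e-12
    for l in range(U.shape[1]):
        members = labels == l
        if not members.any():
            continue
        w = U[members, l]
        mean = (w[:, None] * arp[members]).sum(axis=0) / w.sum()
        pct = 100.0 * one[members].mean(axis=0)
        rows.append(np.concatenate([mean, pct]))
        index.append(f"cluster_{l + 1}")
    rows.append(np.concatenate([arp.mean(axis=0), 100.0 * one.mean(axis=0)]))
    index.append("Total")
    cols = [f"mean_ARp_{c}" for c in table.pollens] + [f"pct_ARp1_{c}" for c in table.pollens]
    return pd.DataFrame(rows, index=index, columns=cols)
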