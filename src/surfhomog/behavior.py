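"""Symptom-severity correlations with cluster-mean regional homogeneity.

Within the patient group, each significant cluster's mean (adjusted) ReHo is
correlated (Pearson) with ADOS/ADI-style subscale scores.  A subscale enters
the analysis only when its coverage — the fraction of all patients with a
non-missing score — strictly exceeds 40%.  Correlations use pairwise-complete
records; p values come from the t transform with n-2 degrees of freedom, and
no multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KNOWN_SUBSCALES",
    "BehaviorResult",
    "subscale_coverage",
    "cluster_mean_reho",
    "correlate_behavior",
    "behavior_table",
]

COVERAGE_THRESHOLD = 0.40  # strict >

KNOWN_SUBSCALES = (
    "ADOS_TOTAL",
    "ADOS_COMM",
    "ADOS_SOCIAL",
    "ADOS_STEREO_BEHAV",
    "ADI_R_SOCIAL_TOTAL_A",
    "ADI_R_VERBAL_TOTAL_BV",
    "ADI_R_RRB_TOTAL_C",
    "ADI_R_ONSET_TOTAL_D",
    "ADOS_GOTHAM_SOC_AFFECT",
    "ADOS_GOTHAM_RRB",
    "ADOS_GOTHAM_TOTAL",
    "ADOS_GOTHAM_SEVERITY",
)


@dataclass
class BehaviorResult:
    cluster_id: int
    subscale: str
    n_used: int
    r: float
    p: float
    coverage: float
    included_by_coverage: bool
    computable: bool = True


def subscale_coverage(phenotypes: pd.DataFrame, subscale: str) -> float:
    """Fraction of patient records with a non-missing value for ``subscale``."""
    if subscale not in phenotypes.columns:
        raise KeyError(
            f"unknown subscale {subscale!r}; known subscales: {sorted(KNOWN_SUBSCALES)}"
        )
    patients = phenotypes[phenotypes["DX_GROUP"] == 1]
    if len(patients) == 0:
        return 0.0
    return float(patients[subscale].notna().mean())


def cluster_mean_reho(maps: np.ndarray, cluster_vertices: np.ndarray) -> np.ndarray:
    """Per-subject mean (adjusted) ReHo over a cluster's vertices."""
    vertices = np.asarray(cluster_vertices, dtype=int)
    if vertices.size == 0:
        raise ValueError("cluster is empty")
    maps = np.asarray(maps, dtype=float)
    return maps[:, vertices].mean(axis=1)


def correlate_behavior(
    cluster_means: np.ndarray, subscale_values: np.ndarray
) -> tuple[float, float, int]:
    """Pearson r and two-sided p over pairwise-complete observations.

    Returns (r, p, n_used); with fewer than 4 complete pairs the result is
    flagged not-computable as (nan, nan, n_used).
    """
    x = np.asarray(cluster_means, dtype=float)
    y = np.asarray(subscale_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return float("nan"), float("nan"), n
    res = stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue), n


def behavior_table(
    maps: np.ndarray,
    phenotypes: pd.DataFrame,
    clusters: dict[int, np.ndarray],
    subscales: tuple[str, ...] = ("ADOS_TOTAL", "ADOS_COMM", "ADOS_SOCIAL",
                                  "ADOS_STEREO_BEHAV"),
    bh_correct: bool = False,
) -> list[BehaviorResult]:
    """All (cluster × subscale) correlations within the patient group.

    ``maps`` rows must align with ``phenotypes`` rows; only patients
    (DX_GROUP 1) contribute.  Subscales failing the >40% coverage rule are
    reported but flagged excluded.  With ``bh_correct`` the p values of
    included, computable pairs are Benjamini–Hochberg adjusted.
    """
    patients = (phenotypes["DX_GROUP"] == 1).to_numpy()
    results: list[BehaviorResult] = []
    for cid, vertices in clusters.items():
        means = cluster_mean_reho(np.asarray(maps)[patients], vertices)
        for name in subscales:
            cov = subscale_coverage(phenotypes, name)
            included = cov > COVERAGE_THRESHOLD
            vals = phenotypes.loc[patients, name].to_numpy(dtype=float)
            r, p, n = correlate_behavior(means, vals)
            results.append(BehaviorResult(
                cluster_id=cid, subscale=name, n_used=n, r=r, p=p,
                coverage=cov, included_by_coverage=included,
                computable=np.isfinite(r),
            ))
    if bh_correct:
        live = [res for res in results if res.included_by_coverage and res.computable]
        if live:
            order = np.argsort([res.p for res in live])
            m = len(live)
            adj = np.empty(m)
            prev = 1.0
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                prev = min(prev, live[i].p * m / (rank_pos + 1))
                adj[i] = prev
            for i, res in enumerate(live):
                res.p = float(adj[i])
    return results
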