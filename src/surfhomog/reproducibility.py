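"""Site-effect maps and leave-one-site-out (LOSOV) replication of group effects.

Multi-site cohorts carry scanner/protocol variability; the group GLM models
site as a covariate, and LOSOV quantifies how robust the patient-vs-control
map is to removing any single site: the group analysis (nuisance adjustment,
GLM, cluster definition, permutation correction) is rerun once per held-out
site, and each vertex's replication count is the number of folds in which it
falls inside a corrected-significant cluster whose sign matches the
full-sample effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_stats import (
    adjust_reho,
    cluster_correct,
    find_clusters,
    fit_group_glm,
    StatMapSet,
)
from .mesh import SphereMesh

__all__ = ["LOSOVResult", "losov", "site_effect_map"]


@dataclass
class LOSOVResult:
    """Per-vertex replication counts across leave-one-site-out folds."""

    replication_count: np.ndarray  # int, in [0, n_sites]
    fold_masks: dict[str, np.ndarray]  # held-out site -> significant-vertex mask
    n_sites: int
    skipped_folds: list[str] = field(default_factory=list)


def _significant_mask(
    yadj: np.ndarray,
    phenotypes: pd.DataFrame,
    mesh: SphereMesh,
    term: str,
    reference_sign: np.ndarray,
    n_permutations: int,
    seed: int,
    cluster_defining_p: float,
    alpha: float,
) -> np.ndarray:
    """Vertices inside corrected-significant clusters matching the reference sign."""
    fit = fit_group_glm(yadj, phenotypes)
    clusters = find_clusters(fit.signed_log_p_maps[term], mesh, cluster_defining_p)
    mask = np.zeros(yadj.shape[1], dtype=bool)
    if not clusters:
        return mask
    result = cluster_correct(
        clusters, yadj, phenotypes, mesh, term=term, alpha=alpha,
        n_permutations=n_permutations, seed=seed,
        cluster_defining_p=cluster_defining_p,
    )
    for c in result.significant_clusters():
        agree = reference_sign[c.vertices] == c.sign
        mask[c.vertices[agree]] = True
    return mask


def losov(
    maps: np.ndarray,
    phenotypes: pd.DataFrame,
    jacobians: np.ndarray,
    mesh: SphereMesh,
    term: str = "group",
    n_permutations: int = 200,
    seed: int = 0,
    cluster_defining_p: float = 0.01,
    alpha: float = 0.05,
) -> LOSOVResult:
    """Leave each site out in turn and count per-vertex replications.

    ``maps`` is the raw subjects × vertices ReHo stack; nuisance adjustment is
    redone within every fold (the adjustment is sample-dependent).  The
    replication sign reference is the full-sample group t-map.  One seed
    sequence is split across folds so the whole run is reproducible.
    """
    sites = sorted(phenotypes["SITE_ID"].unique())
    if len(sites) < 3:
        raise ValueError("LOSOV needs at least 3 sites")
    maps = np.asarray(maps, dtype=float)
    jacobians = np.asarray(jacobians, dtype=float)

    yadj_full = adjust_reho(maps, phenotypes, jacobians)
    fit_full = fit_group_glm(yadj_full, phenotypes)
    reference_sign = np.sign(fit_full.stat[term]).astype(int)

    seeds = np.random.SeedSequence(seed).spawn(len(sites))
    counts = np.zeros(maps.shape[1], dtype=np.int64)
    fold_masks: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for site, child in zip(sites, seeds):
        keep = (phenotypes["SITE_ID"] != site).to_numpy()
        sub_pheno = phenotypes.loc[keep].reset_index(drop=True)
        remaining = sub_pheno.groupby("SITE_ID")["DX_GROUP"].nunique()
        if len(remaining) < 2 or (remaining == 2).sum() < 2:
            skipped.append(site)
            warnings.warn(f"LOSOV fold without site {site} has a degenerate design; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        yadj = adjust_reho(maps[keep], sub_pheno, jacobians[keep])
        fold_seed = int(child.generate_state(1)[0] % (2**31))
        mask = _significant_mask(
            yadj, sub_pheno, mesh, term, reference_sign,
            n_permutations, fold_seed, cluster_defining_p, alpha,
        )
        fold_masks[site] = mask
        counts += mask
    return LOSOVResult(
        replication_count=counts, fold_masks=fold_masks,
        n_sites=len(sites), skipped_folds=skipped,
    )


def site_effect_map(yadj: np.ndarray, phenotypes: pd.DataFrame) -> StatMapSet:
    """Vertexwise joint F test of the site dummy block (with its signed-log-p
    map signed by the largest-magnitude site contrast)."""
    if phenotypes["SITE_ID"].nunique() < 2:
        raise ValueError("site effects need at least 2 sites")
    return fit_group_glm(yadj, phenotypes)
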