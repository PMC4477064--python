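"""Two-stage group statistics on vertexwise ReHo maps.

Stage 1 (adjust_reho) removes per-subject nuisance effects — global mean
ReHo, mean framewise displacement, BBR registration cost, and the vertexwise
white-surface Jacobian — by across-subject least squares at every vertex,
with the nuisance covariates mean-centered so the grand mean is preserved.

Stage 2 (fit_group_glm) fits, per vertex,

    Yadj = b1*age + b2*site + b3*fIQ + b4*Group + b5*Group*age + e

with site dummy-coded (reference = first site alphabetically), Group
effect-coded (+1 patient, -1 control) and age mean-centered before forming
the interaction, so b4 is the group effect at mean age.  Group and
interaction terms get t and two-sided p maps plus -sign(t)*log10(p); the
site block gets a joint F test.

Multiple comparisons are handled clusterwise: supra-threshold vertices at a
cluster-defining p (default 0.01, two-sided, positive and negative clusters
separated) are grouped into edge-connected components, and each component's
extent is referred to the permutation distribution of the maximum extent
under within-site group-label exchange.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import SphereMesh

__all__ = [
    "StatMapSet",
    "Cluster",
    "ClusterResult",
    "adjust_reho",
    "build_group_design",
    "fit_group_glm",
    "signed_log_p",
    "find_clusters",
    "cluster_correct",
]

_TINY_P = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# stage 1: nuisance adjustment

def adjust_reho(
    maps: np.ndarray,
    phenotypes: pd.DataFrame,
    jacobians: np.ndarray,
) -> np.ndarray:
    """Remove gm/meanFD/mcBBR/Jacobian effects from a subjects × vertices stack.

    The Jacobian enters vertexwise (each vertex's fit uses that vertex's JAC
    across subjects); the other three nuisances are subject scalars.  The
    intercept is retained, so Yadj keeps the grand mean of Y.
    """
    y = np.asarray(maps, dtype=float)
    jac = np.asarray(jacobians, dtype=float)
    if y.ndim != 2 or jac.shape != y.shape:
        raise ValueError("maps and jacobians must both be subjects × vertices")
    n_sub, n_vert = y.shape
    gm = y.mean(axis=1)
    fd = phenotypes["MEAN_FD"].to_numpy(dtype=float)
    bbr = phenotypes["MC_BBR"].to_numpy(dtype=float)
    if len(fd) != n_sub:
        raise ValueError("phenotype rows must match the map stack")
    if n_sub < 5 + 4:
        raise ValueError("need at least 5 more subjects than nuisance terms")

    scalars = np.column_stack([gm, fd, bbr])
    scalars_c = scalars - scalars.mean(axis=0)
    names = ["gm", "meanFD", "mcBBR"]
    # a column with (numerically) no across-subject variance carries no effect
    sds = scalars_c.std(axis=0)
    tol = 1e-10 * (1.0 + np.abs(scalars.mean(axis=0)))
    sds = np.where(sds <= tol, 0.0, sds)
    degenerate = [names[i] for i in range(3) if sds[i] == 0]
    corr = np.corrcoef(scalars_c[:, sds > 0].T) if (sds > 0).sum() > 1 else np.eye(1)
    if np.any(np.abs(corr - np.eye(len(corr))) > 1 - 1e-10):
        raise ValueError(f"collinear nuisance columns among {names}")

    jac_c = jac - jac.mean(axis=0)

    # batched normal equations: shared scalar block + per-vertex Jacobian column
    xs = scalars_c[:, sds > 0]  # drop constant scalars (their effect is nil anyway)
    if degenerate:
        warnings.warn(f"nuisance columns with no variance skipped: {degenerate}",
                      RuntimeWarning, stacklevel=2)
    q = xs.shape[1]
    a = xs.T @ xs  # q × q shared
    b = xs.T @ jac_c  # q × V
    c = np.einsum("sv,sv->v", jac_c, jac_c)  # V
    xtx = np.empty((n_vert, q + 1, q + 1))
    xtx[:, :q, :q] = a
    xtx[:, :q, q] = b.T
    xtx[:, q, :q] = b.T
    xtx[:, q, q] = c
    # guard (numerically) zero Jacobian variance at a vertex
    zero_jac = c <= 1e-18 * np.maximum(1.0, np.einsum("sv,sv->v", jac, jac))
    xtx[zero_jac, q, q] = 1.0

    xty = np.empty((n_vert, q + 1))
    xty[:, :q] = (xs.T @ y).T
    xty[:, q] = np.einsum("sv,sv->v", jac_c, y)
    xty[zero_jac, q] = 0.0

    try:
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]  # V × (q+1)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"collinear nuisance columns among {names + ['JAC']}") from err

    fitted = xs @ beta[:, :q].T + jac_c * beta[:, q][None, :]
    return y - fitted


# ---------------------------------------------------------------------------
# stage 2: group GLM

@dataclass
class StatMapSet:
    """Vertexwise betas, t/F, p and signed log10(p) maps for each model term."""

    terms: list[str]
    beta: dict[str, np.ndarray]
    stat: dict[str, np.ndarray]  # t (or F for 'site')
    p: dict[str, np.ndarray]
    signed_log_p_maps: dict[str, np.ndarray]
    df_resid: int
    residuals: np.ndarray | None = None


def build_group_design(phenotypes: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Design matrix for the group GLM and metadata about its columns.

    Columns: intercept, site dummies (all sites after the first alphabetical),
    centered age, fIQ, group (+1 patient / -1 control), group × centered age.
    """
    sites = sorted(phenotypes["SITE_ID"].unique())
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    dx = phenotypes["DX_GROUP"].to_numpy()
    group = np.where(dx == 1, 1.0, -1.0)
    for s in sites:
        in_site = phenotypes["SITE_ID"] == s
        if len(set(dx[np.asarray(in_site)])) < 2:
            warnings.warn(f"site {s} contains a single diagnostic group",
                          RuntimeWarning, stacklevel=2)
    age = phenotypes["AGE_AT_SCAN"].to_numpy(dtype=float)
    age_c = age - age.mean()
    fiq = phenotypes["FIQ"].to_numpy(dtype=float)
    dummies = np.column_stack([
        (phenotypes["SITE_ID"] == s).to_numpy(dtype=float) for s in sites[1:]
    ]) if len(sites) > 1 else np.empty((len(phenotypes), 0))
    x = np.column_stack([np.ones(len(phenotypes)), dummies, age_c, fiq, group,
                         group * age_c])
    n_site_cols = len(sites) - 1
    meta = {
        "sites": sites,
        "site_cols": list(range(1, 1 + n_site_cols)),
        "age_col": 1 + n_site_cols,
        "fiq_col": 2 + n_site_cols,
        "group_col": 3 + n_site_cols,
        "interaction_col": 4 + n_site_cols,
        "group_vector": group,
        "age_centered": age_c,
    }
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("group design matrix is rank deficient")
    return x, meta


def _ols_fit(x: np.ndarray, y: np.ndarray):
    """OLS of (subjects × vertices) y on shared design x; returns beta, resid,
    sigma2, the inverse Gram matrix and residual df."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # p × V
    resid = y - x @ beta
    df = n - p
    if df <= 0:
        raise ValueError("more model terms than subjects")
    sigma2 = np.einsum("sv,sv->v", resid, resid) / df
    return beta, resid, sigma2, xtx_inv, df


def _t_and_p(beta_row, sigma2, inv_jj, df):
    se = np.sqrt(np.maximum(sigma2 * inv_jj, 1e-300))
    t = beta_row / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def fit_group_glm(
    yadj: np.ndarray, phenotypes: pd.DataFrame, keep_residuals: bool = False
) -> StatMapSet:
    """Vertexwise OLS of the adjusted ReHo stack on the group design."""
    y = np.asarray(yadj, dtype=float)
    if y.ndim != 2 or y.shape[0] != len(phenotypes):
        raise ValueError("yadj must be subjects × vertices, rows matching phenotypes")
    x, meta = build_group_design(phenotypes)
    beta, resid, sigma2, xtx_inv, df = _ols_fit(x, y)

    terms = ["age", "fiq", "group", "group_x_age", "site"]
    beta_maps, stat_maps, p_maps, slp_maps = {}, {}, {}, {}
    for term, col in (("age", meta["age_col"]), ("fiq", meta["fiq_col"]),
                      ("group", meta["group_col"]),
                      ("group_x_age", meta["interaction_col"])):
        t, p = _t_and_p(beta[col], sigma2, xtx_inv[col, col], df)
        beta_maps[term] = beta[col]
        stat_maps[term] = t
        p_maps[term] = p
        slp_maps[term] = signed_log_p(t, p)

    # joint F test for the site dummy block via the reduced model
    site_cols = meta["site_cols"]
    if site_cols:
        keep = [j for j in range(x.shape[1]) if j not in site_cols]
        xr = x[:, keep]
        _, resid_r, _, _, _ = _ols_fit(xr, y)
        rss_f = np.einsum("sv,sv->v", resid, resid)
        rss_r = np.einsum("sv,sv->v", resid_r, resid_r)
        qf = len(site_cols)
        f = ((rss_r - rss_f) / qf) / np.maximum(rss_f / df, 1e-300)
        f = np.maximum(f, 0.0)
        pf = stats.f.sf(f, qf, df)
        # sign from the largest-|beta| site contrast at each vertex
        site_betas = beta[site_cols]
        sign = np.sign(site_betas[np.abs(site_betas).argmax(axis=0),
                                  np.arange(y.shape[1])])
        beta_maps["site"] = site_betas
        stat_maps["site"] = f
        p_maps["site"] = pf
        with np.errstate(divide="ignore"):
            slp_maps["site"] = -sign * np.log10(np.maximum(pf, _TINY_P))

    return StatMapSet(
        terms=terms, beta=beta_maps, stat=stat_maps, p=p_maps,
        signed_log_p_maps=slp_maps, df_resid=df,
        residuals=resid if keep_residuals else None,
    )


def signed_log_p(t_map: np.ndarray, p_map: np.ndarray) -> np.ndarray:
    """-sign(t) * log10(p): positive where patients exceed controls."""
    t = np.asarray(t_map, dtype=float)
    p = np.asarray(p_map, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to the smallest positive float",
                      RuntimeWarning, stacklevel=2)
        p = np.maximum(p, _TINY_P)
    with np.errstate(divide="ignore"):
        return -np.sign(t) * np.log10(np.maximum(p, _TINY_P))


# ---------------------------------------------------------------------------
# clusters

@dataclass
class Cluster:
    vertices: np.ndarray
    sign: int  # +1 patients > controls, -1 otherwise
    peak_vertex: int
    peak_signed_log_p: float
    corrected_p: float | None = None

    @property
    def vertex_count(self) -> int:
        return int(len(self.vertices))

    @property
    def significant(self) -> bool:
        return self.corrected_p is not None and self.corrected_p < 0.05


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cluster_defining_p: float
    alpha: float
    method: str
    n_permutations: int
    statistic: str = "extent"
    null_max_extents: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters
                if c.corrected_p is not None and c.corrected_p < self.alpha]


def _masked_components(mask: np.ndarray, edges: np.ndarray) -> list[np.ndarray]:
    """Connected components of the supra-threshold subgraph (union-find)."""
    verts = np.flatnonzero(mask)
    if verts.size == 0:
        return []
    parent = {int(v): int(v) for v in verts}

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    sel = mask[edges[:, 0]] & mask[edges[:, 1]]
    for u, v in edges[sel]:
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[ru] = rv
    groups: dict[int, list[int]] = {}
    for v in verts:
        groups.setdefault(find(int(v)), []).append(int(v))
    return [np.array(sorted(g), dtype=np.int64) for g in groups.values()]


def find_clusters(
    slp_map: np.ndarray, mesh: SphereMesh, cluster_defining_p: float = 0.01
) -> list[Cluster]:
    """Edge-connected components of supra-threshold vertices, by sign.

    A vertex is supra-threshold when |signed log10 p| exceeds
    -log10(cluster_defining_p); positive and negative vertices are clustered
    separately.
    """
    if not 0 < cluster_defining_p < 1:
        raise ValueError("cluster_defining_p must lie in (0, 1)")
    slp = np.asarray(slp_map, dtype=float)
    thr = -math.log10(cluster_defining_p)
    edges = mesh.edges
    clusters = []
    for sign in (1, -1):
        mask = (sign * slp) > thr
        for comp in _masked_components(mask, edges):
            peak_local = comp[np.abs(slp[comp]).argmax()]
            clusters.append(Cluster(
                vertices=comp, sign=sign, peak_vertex=int(peak_local),
                peak_signed_log_p=float(slp[peak_local]),
            ))
    clusters.sort(key=lambda c: -c.vertex_count)
    return clusters


def _cluster_stat(comp: np.ndarray, t_vals: np.ndarray, t_crit: float,
                  statistic: str) -> float:
    """Extent (vertex count) or exceedance mass Σ(|t| − t_crit) of a cluster."""
    if statistic == "extent":
        return float(len(comp))
    return float(np.sum(np.abs(t_vals[comp]) - t_crit))


def _max_extent(t_vals: np.ndarray, t_crit: float, edges: np.ndarray,
                statistic: str = "extent") -> float:
    best = 0.0
    for sign in (1, -1):
        mask = (sign * t_vals) > t_crit
        for comp in _masked_components(mask, edges):
            best = max(best, _cluster_stat(comp, t_vals, t_crit, statistic))
    return best


def _count_within_site_permutations(phenotypes: pd.DataFrame) -> float:
    total = 1.0
    for _, grp in phenotypes.groupby("SITE_ID"):
        n = len(grp)
        k = int((grp["DX_GROUP"] == 1).sum())
        total *= math.comb(n, k)
        if total > 1e12:
            return math.inf
    return total


def _permute_groups_within_site(
    phenotypes: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Randomly reassign the ±1 group labels within each site."""
    group = np.where(phenotypes["DX_GROUP"].to_numpy() == 1, 1.0, -1.0)
    out = group.copy()
    for _, idx in phenotypes.groupby("SITE_ID").indices.items():
        out[idx] = rng.permutation(out[idx])
    return out


def cluster_correct(
    clusters: list[Cluster],
    yadj: np.ndarray,
    phenotypes: pd.DataFrame,
    mesh: SphereMesh,
    term: str = "group",
    alpha: float = 0.05,
    n_permutations: int = 500,
    seed: int = 0,
    cluster_defining_p: float = 0.01,
    statistic: str = "extent",
) -> ClusterResult:
    """Permutation clusterwise correction for the group or interaction term.

    Group labels are exchanged within site; for each permutation the GLM is
    refit and the maximum supra-threshold cluster statistic (either sign) is
    recorded.  A cluster's corrected p is the fraction of the null (observed
    statistic included) whose maximum reaches its own value, so corrected
    p >= 1/(n_permutations + 1) always.

    ``statistic`` is "extent" (vertex count; matches how clusters are usually
    tabulated) or "mass" (Σ(|t| − t_crit) over the cluster).  On small meshes
    the extent null is coarsely discrete, which makes extent-based corrected
    p values conservative; the continuous mass statistic restores near-nominal
    family-wise calibration.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if term not in ("group", "group_x_age"):
        raise ValueError("term must be 'group' or 'group_x_age'")
    if statistic not in ("extent", "mass"):
        raise ValueError("statistic must be 'extent' or 'mass'")
    y = np.asarray(yadj, dtype=float)
    x, meta = build_group_design(phenotypes)
    col = meta["group_col"] if term == "group" else meta["interaction_col"]
    edges = mesh.edges
    rng = np.random.default_rng(seed)

    notes = []
    n_distinct = _count_within_site_permutations(phenotypes)
    n_perm = n_permutations
    if n_distinct < n_permutations:
        n_perm = int(n_distinct)
        notes.append(
            f"only {n_perm} distinct within-site label assignments exist; "
            f"ran {n_perm} random draws instead of {n_permutations}"
        )

    # observed clusters are scored with the same t map and threshold as the null
    beta_o, _, sigma2_o, inv_o, df = _ols_fit(x, y)
    t_obs = beta_o[col] / np.sqrt(np.maximum(sigma2_o * inv_o[col, col], 1e-300))
    t_crit = stats.t.ppf(1.0 - cluster_defining_p / 2.0, df)

    age_c = meta["age_centered"]
    null_max = np.empty(n_perm, dtype=float)
    xp = x.copy()
    for i in range(n_perm):
        gperm = _permute_groups_within_site(phenotypes, rng)
        xp[:, meta["group_col"]] = gperm
        xp[:, meta["interaction_col"]] = gperm * age_c
        beta_p, _, sigma2_p, inv_p, _ = _ols_fit(xp, y)
        t_p = beta_p[col] / np.sqrt(np.maximum(sigma2_p * inv_p[col, col], 1e-300))
        null_max[i] = _max_extent(t_p, t_crit, edges, statistic)

    out_clusters = []
    for c in clusters:
        observed = _cluster_stat(c.vertices, t_obs, t_crit, statistic)
        exceed = int(np.sum(null_max >= observed))
        corrected = (1 + exceed) / (n_perm + 1)
        out_clusters.append(Cluster(
            vertices=c.vertices, sign=c.sign, peak_vertex=c.peak_vertex,
            peak_signed_log_p=c.peak_signed_log_p, corrected_p=float(corrected),
        ))
    return ClusterResult(
        clusters=out_clusters, cluster_defining_p=cluster_defining_p, alpha=alpha,
        method="permutation", n_permutations=n_perm, statistic=statistic,
        null_max_extents=null_max, notes=notes,
    )
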