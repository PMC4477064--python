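"""End-to-end pipeline: QC filter → conditioning → ReHo → adjustment → group
GLM → cluster inference → optional LOSOV and behavior stages.

A PipelineConfig captures every knob; a run writes its outputs plus a
manifest (config hash, seed, per-output SHA-256) so reruns with the same
config and inputs are verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from .group_stats import adjust_reho, cluster_correct, find_clusters, fit_group_glm
from .io import load_cohort, write_qc_report
from .mesh import build_icosphere, build_neighbor_table
from .prep import friston24, prep_chain, qc_filter
from .reho import compute_reho
from .reproducibility import losov
from .synthetic import Cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("surfhomog")


@dataclass
class PipelineConfig:
    cohort_dir: str = ""
    output_dir: str = "surfhomog_out"
    mesh_order: int = 2
    ring_order: int = 1
    prep_steps: tuple[str, ...] = ("despike", "scale", "regress", "bandpass", "detrend")
    despike_clip_sigma: float = 4.0
    scale_target: float = 10000.0
    bandpass_low: float = 0.01
    bandpass_high: float = 0.1
    qc_max_tran: float = 2.0
    qc_max_rot: float = 2.0
    qc_max_fd: float = 0.4
    qc_max_bbr: float = 0.75
    cluster_defining_p: float = 0.01
    cluster_alpha: float = 0.05
    cluster_statistic: str = "extent"  # or "mass"
    n_permutations: int = 200
    run_losov: bool = False
    run_behavior: bool = False
    behavior_subscales: tuple[str, ...] = ("ADOS_TOTAL", "ADOS_COMM",
                                           "ADOS_SOCIAL", "ADOS_STEREO_BEHAV")
    seed: int = 0

    def validate(self) -> None:
        if self.ring_order not in (1, 2):
            raise ValueError("ring_order must be 1 or 2")
        if not 0 < self.cluster_defining_p < 1:
            raise ValueError("cluster_defining_p must lie in (0, 1)")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must lie in (0, 1)")
        if self.cohort_dir and not Path(self.cohort_dir).exists():
            raise FileNotFoundError(f"cohort_dir does not exist: {self.cohort_dir}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("prep_steps", "behavior_subscales"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prep_steps"] = list(self.prep_steps)
        d["behavior_subscales"] = list(self.behavior_subscales)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cluster_table(results: dict[str, object], mesh) -> pd.DataFrame:
    rows = []
    for term, res in results.items():
        for i, c in enumerate(res.clusters):
            peak_xyz = mesh.vertices[c.peak_vertex]
            rows.append({
                "term": term, "cluster_id": i, "vertex_count": c.vertex_count,
                "peak_vertex": c.peak_vertex,
                "peak_x": peak_xyz[0], "peak_y": peak_xyz[1], "peak_z": peak_xyz[2],
                "peak_signed_log_p": c.peak_signed_log_p,
                "corrected_p": c.corrected_p,
                "significant": c.corrected_p is not None and c.corrected_p < res.alpha,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute every stage on a cohort (loaded from ``config.cohort_dir``
    unless passed in); returns the run manifest dict (also written to
    output_dir/manifest.json)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = build_icosphere(config.mesh_order)
    if cohort is None:
        if not config.cohort_dir:
            raise ValueError("no cohort given and cohort_dir is empty")
        cohort = load_cohort(config.cohort_dir, mesh)
    if cohort.mesh.n_vertices != mesh.n_vertices:
        mesh = cohort.mesh

    outputs: dict[str, Path] = {}

    # --- QC -----------------------------------------------------------------
    records = [s.qc for s in cohort.subjects]
    retained, excluded = qc_filter(
        records, max_tran=config.qc_max_tran, max_rot=config.qc_max_rot,
        max_fd=config.qc_max_fd, max_bbr=config.qc_max_bbr,
    )
    write_qc_report(out / "qc_report.csv", records)
    outputs["qc_report"] = out / "qc_report.csv"
    log.info("QC: retained %d / %d subjects", len(retained), len(records))
    if not retained:
        raise RuntimeError("no subjects pass QC")
    keep_ids = set(retained)
    subjects = [s for s in cohort.subjects if s.subject_id in keep_ids]
    pheno = cohort.phenotypes[cohort.phenotypes["SUB_ID"].isin(keep_ids)]
    pheno = pheno.reset_index(drop=True)

    # --- prep + ReHo --------------------------------------------------------
    table = build_neighbor_table(mesh, ring_order=config.ring_order)
    maps = np.empty((len(subjects), mesh.n_vertices))
    jac = np.empty_like(maps)
    for i, sub in enumerate(subjects):
        log.info("prep+reho: %s", sub.subject_id)
        nuisance = np.hstack([friston24(sub.motion), sub.confounds])
        ts = prep_chain(
            sub.bold, nuisance=nuisance, steps=config.prep_steps,
            clip_sigma=config.despike_clip_sigma, scale_target=config.scale_target,
            low=config.bandpass_low, high=config.bandpass_high,
        )
        maps[i] = compute_reho(ts, table).values
        jac[i] = sub.jacobian
    np.save(out / "reho_stack.npy", maps)
    outputs["reho_stack"] = out / "reho_stack.npy"

    # --- adjustment + GLM ---------------------------------------------------
    yadj = adjust_reho(maps, pheno, jac)
    np.save(out / "yadj_stack.npy", yadj)
    outputs["yadj_stack"] = out / "yadj_stack.npy"
    fit = fit_group_glm(yadj, pheno)
    for term in ("group", "group_x_age", "site"):
        np.save(out / f"slp_{term}.npy", fit.signed_log_p_maps[term])
        outputs[f"slp_{term}"] = out / f"slp_{term}.npy"

    # --- clusters -----------------------------------------------------------
    cluster_results = {}
    for term in ("group", "group_x_age"):
        raw = find_clusters(fit.signed_log_p_maps[term], mesh,
                            config.cluster_defining_p)
        cluster_results[term] = cluster_correct(
            raw, yadj, pheno, mesh, term=term, alpha=config.cluster_alpha,
            n_permutations=config.n_permutations, seed=config.seed,
            cluster_defining_p=config.cluster_defining_p,
            statistic=config.cluster_statistic,
        )
    ctable = _cluster_table(cluster_results, mesh)
    ctable.to_csv(out / "clusters.csv", index=False)
    outputs["clusters"] = out / "clusters.csv"

    # --- optional stages ----------------------------------------------------
    if config.run_losov:
        lres = losov(maps, pheno, jac, mesh, n_permutations=config.n_permutations,
                     seed=config.seed, cluster_defining_p=config.cluster_defining_p,
                     alpha=config.cluster_alpha)
        np.save(out / "losov_counts.npy", lres.replication_count)
        outputs["losov_counts"] = out / "losov_counts.npy"

    if config.run_behavior:
        sig = {
            i: c.vertices
            for i, c in enumerate(cluster_results["group"].significant_clusters())
        }
        rows = []
        if sig:
            for res in behavior_mod.behavior_table(
                yadj, pheno, sig, subscales=config.behavior_subscales
            ):
                rows.append(dataclasses.asdict(res) |
                            {"cluster_vertices": len(sig[res.cluster_id])})
        pd.DataFrame(rows).to_csv(out / "behavior.csv", index=False)
        outputs["behavior"] = out / "behavior.csv"

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects_input": len(records),
        "n_subjects_retained": len(retained),
        "excluded": {k: v for k, v in excluded.items()},
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
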