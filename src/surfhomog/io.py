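"""File formats and cohort/phenotype I/O.

Surface metrics travel as GIFTI functional files (.func.gii / .gii), FreeSurfer
MGH scalar overlays (.mgh / .mgz), or plain NumPy arrays (.npy); meshes as
GIFTI .surf.gii or FreeSurfer binary geometry (see mesh module).  Phenotypes
are CSVs following the ABIDE column convention: DX_GROUP 1 = patient (ASD),
2 = control, with SUB_ID, SITE_ID, AGE_AT_SCAN, FIQ required and behavioral
subscale columns optional (missing cells stay missing, never zero).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import BoldSurface, QCRecord
from .synthetic import Cohort, CohortDesign, MotionTrace, SubjectData
from .mesh import SphereMesh

__all__ = [
    "read_surface_metric",
    "write_surface_metric",
    "read_phenotypes",
    "write_qc_report",
    "save_cohort",
    "load_cohort",
    "load_sample_composition",
    "sample_composition_to_phenotypes",
]

REQUIRED_PHENO_COLUMNS = ("SUB_ID", "SITE_ID", "DX_GROUP", "AGE_AT_SCAN", "FIQ")


# ---------------------------------------------------------------------------
# surface metric files

def write_surface_metric(path, values: np.ndarray) -> None:
    """Write a per-vertex map (V,) or time-series matrix (V × T)."""
    import nibabel as nib

    path = str(path)
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim not in (1, 2):
        raise ValueError("surface metric must be 1-D or 2-D")
    if path.endswith(".gii"):
        img = nib.gifti.GiftiImage()
        if arr.ndim == 1:
            frames = [arr]
        else:
            frames = [arr[:, t] for t in range(arr.shape[1])]
        for frame in frames:
            img.add_gifti_data_array(nib.gifti.GiftiDataArray(
                frame.astype(np.float32), intent="NIFTI_INTENT_NONE"))
        nib.save(img, path)
    elif path.endswith((".mgh", ".mgz")):
        shaped = arr[:, None, None] if arr.ndim == 1 else arr[:, None, None, :]
        nib.save(nib.freesurfer.MGHImage(shaped.astype(np.float32), np.eye(4)), path)
    elif path.endswith(".npy"):
        np.save(path, arr)
    else:
        raise ValueError(f"unknown surface metric format: {path}")


def read_surface_metric(path, expected_n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex map or time-series matrix, validating the vertex count."""
    import nibabel as nib

    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        frames = [np.asarray(d.data, dtype=float) for d in img.darrays]
        arr = frames[0] if len(frames) == 1 else np.column_stack(frames)
    elif path.endswith((".mgh", ".mgz")):
        data = np.asarray(nib.load(path).get_fdata(), dtype=float)
        arr = data.reshape(data.shape[0], -1)
        if arr.shape[1] == 1:
            arr = arr.ravel()
    elif path.endswith(".npy"):
        arr = np.load(path)
    else:
        raise ValueError(f"unknown surface metric format: {path}")
    if expected_n_vertices is not None and arr.shape[0] != expected_n_vertices:
        raise ValueError(
            f"{path}: file has {arr.shape[0]} vertices, expected {expected_n_vertices}"
        )
    return arr


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path) -> pd.DataFrame:
    """Typed phenotype table from CSV; missing behavior cells stay NaN."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing required column(s): {missing}")
    if df["SUB_ID"].duplicated().any():
        dupes = df.loc[df["SUB_ID"].duplicated(), "SUB_ID"].tolist()
        raise ValueError(f"duplicate SUB_ID values: {dupes}")
    bad_dx = set(df["DX_GROUP"].unique()) - {1, 2}
    if bad_dx:
        raise ValueError(f"DX_GROUP must be 1 (patient) or 2 (control); found {bad_dx}")
    df["SUB_ID"] = df["SUB_ID"].astype(str)
    df["SITE_ID"] = df["SITE_ID"].astype(str)
    df["AGE_AT_SCAN"] = df["AGE_AT_SCAN"].astype(float)
    df["FIQ"] = df["FIQ"].astype(float)
    return df


def write_qc_report(path, records: list[QCRecord]) -> None:
    rows = []
    for rec in records:
        ok, reasons = rec.evaluate()
        rows.append({
            "SUB_ID": rec.subject_id, "MAX_TRAN": rec.max_tran,
            "MAX_ROT": rec.max_rot, "MEAN_FD": rec.mean_fd, "MC_BBR": rec.mc_bbr,
            "PASSED": ok, "REASONS": ";".join(reasons),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# printed sample-composition table (site-level counts and age summaries)

def load_sample_composition() -> pd.DataFrame:
    """Site-level composition of the multi-site autism sample: per-site
    patient/control counts and age mean ± sd, as published."""
    with importlib.resources.files("surfhomog.data").joinpath(
        "abide_sample_composition.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def sample_composition_to_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Expand site-level counts into one phenotype row per subject.

    Individual ages/fIQs are not published at subject level, so each subject
    carries the site age mean and the sample-window center fIQ; this expansion
    serves count/site arithmetic through the standard phenotype reader, not
    subject-level modeling.
    """
    rows = []
    counter = 0
    for _, site in table.iterrows():
        for dx, n in ((1, int(site["ASD_N"])), (2, int(site["HC_N"]))):
            for _ in range(n):
                counter += 1
                rows.append({
                    "SUB_ID": f"tab{counter:04d}",
                    "SITE_ID": site["SITE_ID"],
                    "DX_GROUP": dx,
                    "AGE_AT_SCAN": float(site["AGE_MEAN"]),
                    "FIQ": 108.0,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort directory layout

def save_cohort(cohort: Cohort, directory, metric_format: str = "npy") -> Path:
    """Write a cohort: one surface time-series file, motion TSV, confound TSV
    and Jacobian file per subject, plus phenotypes.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"npy": ".npy", "gifti": ".func.gii", "mgh": ".mgh"}[metric_format]
    for sub in cohort.subjects:
        write_surface_metric(directory / f"{sub.subject_id}_bold{ext}", sub.bold.signal)
        write_surface_metric(directory / f"{sub.subject_id}_jacobian{ext}", sub.jacobian)
        motion = pd.DataFrame(
            sub.motion.as_matrix(),
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        )
        motion.to_csv(directory / f"{sub.subject_id}_motion.tsv", sep="\t", index=False)
        np.savetxt(directory / f"{sub.subject_id}_confounds.tsv", sub.confounds,
                   delimiter="\t", header="wm\tcsf", comments="")
    cohort.phenotypes.to_csv(directory / "phenotypes.csv", index=False)
    meta = {"repetition_time": cohort.design.repetition_time,
            "n_vertices": cohort.mesh.n_vertices,
            "metric_format": metric_format}
    pd.Series(meta).to_json(directory / "cohort_meta.json")
    return directory


def load_cohort(directory, mesh: SphereMesh) -> Cohort:
    """Read a cohort directory back into the in-memory bundle."""
    directory = Path(directory)
    meta = pd.read_json(directory / "cohort_meta.json", typ="series")
    if int(meta["n_vertices"]) != mesh.n_vertices:
        raise ValueError(
            f"cohort was written for {int(meta['n_vertices'])} vertices, "
            f"mesh has {mesh.n_vertices}"
        )
    ext = {"npy": ".npy", "gifti": ".func.gii", "mgh": ".mgh"}[str(meta["metric_format"])]
    tr = float(meta["repetition_time"])
    pheno = read_phenotypes(directory / "phenotypes.csv")
    subjects = []
    for _, row in pheno.iterrows():
        sid = row["SUB_ID"]
        signal = read_surface_metric(directory / f"{sid}_bold{ext}", mesh.n_vertices)
        jac = read_surface_metric(directory / f"{sid}_jacobian{ext}", mesh.n_vertices)
        motion_df = pd.read_csv(directory / f"{sid}_motion.tsv", sep="\t")
        motion = MotionTrace(translations=motion_df.iloc[:, :3].to_numpy(),
                             rotations=motion_df.iloc[:, 3:].to_numpy())
        confounds = np.loadtxt(directory / f"{sid}_confounds.tsv", delimiter="\t",
                               skiprows=1)
        qc = QCRecord(subject_id=sid, max_tran=row.get("MAX_TRAN"),
                      max_rot=row.get("MAX_ROT"), mean_fd=row.get("MEAN_FD"),
                      mc_bbr=row.get("MC_BBR"))
        subjects.append(SubjectData(
            subject_id=sid, site=row["SITE_ID"],
            group="patient" if row["DX_GROUP"] == 1 else "control",
            age=float(row["AGE_AT_SCAN"]), fiq=float(row["FIQ"]),
            bold=BoldSurface(signal=signal, repetition_time=tr, subject_id=sid),
            motion=motion, jacobian=np.asarray(jac, dtype=float).ravel(),
            confounds=np.atleast_2d(confounds), qc=qc,
        ))
    design = CohortDesign(n_sites=pheno["SITE_ID"].nunique(),
                          subjects_per_site_per_group=1,
                          n_timepoints=max(20, subjects[0].bold.n_timepoints),
                          repetition_time=tr)
    return Cohort(mesh=mesh, design=design, subjects=subjects, phenotypes=pheno)
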