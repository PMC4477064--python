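"""Synthetic multi-site surface cohorts with known ground-truth effects.

Emulates the statistical structure the downstream analysis assumes, at desk
scale: spherical-mesh BOLD time series whose local homogeneity (hence ReHo)
is controlled by iterative one-ring mean smoothing of independent Gaussian
fields, AR(1) temporal noise, site-specific homogeneity offsets, a seeded
patient-vs-control effect region, a region with opposite-signed age slopes
per group, random-walk motion traces whose QC metrics straddle the exclusion
thresholds, per-vertex Jacobian maps, and ADOS-like symptom scores with a
specified correlation to regional ReHo.

Because Kendall's W has no simple closed-form inverse in the smoothing
amount, a Monte-Carlo calibration curve (smoothing amount -> expected mean
ReHo) is estimated once per design and inverted by interpolation; regional
and per-subject homogeneity targets are then expressed as per-vertex
smoothing-amount maps.  Smoothing amounts are continuous: ``a`` applies
``floor(a)`` full one-ring mean passes plus a fractional blend, per vertex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import lfilter

from .mesh import SphereMesh, build_neighbor_table
from .prep import BoldSurface, QCRecord, motion_metrics
from .reho import compute_reho

__all__ = [
    "CohortDesign",
    "MotionTrace",
    "SubjectData",
    "Cohort",
    "simulate_subject_timeseries",
    "simulate_motion_trace",
    "simulate_cohort",
    "calibrate_smoothing",
]

ADOS_SUBSCALES = ("ADOS_TOTAL", "ADOS_COMM", "ADOS_SOCIAL", "ADOS_STEREO_BEHAV")

# BOLD-like units: constant baseline plus ~1% fluctuations keeps every
# intensity positive for grand-mean scaling without affecting ranks.
_BASELINE = 1000.0
_FLUCT_SD = 10.0

_FIQ_MEAN, _FIQ_SD = 108.0, 15.0  # sample window: fIQ within 2 sd of 108 ± 15


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per retained frame."""

    translations: np.ndarray  # T × 3, mm
    rotations: np.ndarray  # T × 3, degrees

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be T × 3")
        if not (np.all(np.isfinite(self.translations)) and np.all(np.isfinite(self.rotations))):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.translations.shape[0])

    def as_matrix(self) -> np.ndarray:
        return np.hstack([self.translations, self.rotations])


@dataclass
class CohortDesign:
    """Ground-truth generating parameters of a two-group multi-site cohort.

    Homogeneity effects are expressed in ReHo units (Kendall's W): patients
    gain ``effect_size_delta`` mean ReHo inside ``effect_region``, plus a
    stable per-patient trait offset with sd ``effect_trait_sd`` (the
    subject-level severity variation that symptom scores track — without it,
    between-patient differences in regional ReHo would be pure measurement
    noise and no correlation could survive preprocessing); inside
    ``interaction_region`` ReHo drifts with age at ``age_slope_patient`` /
    ``age_slope_control`` (ReHo units per year, group-specific); each site
    adds ``site_offsets[s]`` everywhere.  ``smoothing_iters_base`` sets the
    baseline local spatial autocorrelation and ``ar1_phi`` the temporal one.
    """

    n_sites: int = 4
    subjects_per_site_per_group: int = 5
    age_range: tuple[float, float] = (8.0, 30.0)
    effect_region: np.ndarray = dataclass_field(default_factory=lambda: np.array([], dtype=int))
    effect_size_delta: float = 0.0
    effect_trait_sd: float = 0.03
    interaction_region: np.ndarray = dataclass_field(default_factory=lambda: np.array([], dtype=int))
    age_slope_patient: float = 0.0
    age_slope_control: float = 0.0
    site_offsets: np.ndarray | None = None
    smoothing_iters_base: float = 2.0
    ar1_phi: float = 0.3
    n_timepoints: int = 120
    repetition_time: float = 2.0
    ados_correlation_rho: float = 0.0
    confound_weight_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.effect_region = np.asarray(self.effect_region, dtype=int)
        self.interaction_region = np.asarray(self.interaction_region, dtype=int)
        if self.site_offsets is None:
            self.site_offsets = np.zeros(self.n_sites)
        self.site_offsets = np.asarray(self.site_offsets, dtype=float)
        if self.subjects_per_site_per_group < 1:
            raise ValueError("need at least 1 subject per site per group")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 timepoints")
        if len(self.site_offsets) != self.n_sites:
            raise ValueError("site_offsets length must equal n_sites")
        if not (0 <= self.ar1_phi < 1):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.effect_size_delta != 0 and self.effect_region.size == 0:
            raise ValueError("nonzero effect_size_delta with empty effect_region")
        if (self.age_slope_patient != 0 or self.age_slope_control != 0) and (
            self.interaction_region.size == 0
        ):
            raise ValueError("nonzero age slopes with empty interaction_region")

    def validate_for_mesh(self, mesh: SphereMesh) -> None:
        for name, region in (("effect_region", self.effect_region),
                             ("interaction_region", self.interaction_region)):
            if region.size and (region.min() < 0 or region.max() >= mesh.n_vertices):
                raise ValueError(f"{name} contains invalid vertex indices for this mesh")


@dataclass
class SubjectData:
    subject_id: str
    site: str
    group: str  # "patient" | "control"
    age: float
    fiq: float
    bold: BoldSurface
    motion: MotionTrace
    jacobian: np.ndarray  # per-vertex white-surface Jacobian
    confounds: np.ndarray  # timepoints × 2 WM/CSF mean series
    qc: QCRecord


@dataclass
class Cohort:
    """Bundle of per-subject data plus the phenotype table and ground truth."""

    mesh: SphereMesh
    design: CohortDesign
    subjects: list[SubjectData]
    phenotypes: pd.DataFrame

    @property
    def site_names(self) -> list[str]:
        return sorted(self.phenotypes["SITE_ID"].unique())


# ---------------------------------------------------------------------------
# field simulation

def _one_ring_mean_operator(mesh: SphereMesh) -> sp.csr_matrix:
    """Row-stochastic closed one-ring averaging operator (I + A, normalized)."""
    adj = mesh.adjacency.astype(float)
    closed = adj + sp.identity(mesh.n_vertices, format="csr")
    inv_deg = 1.0 / np.asarray(closed.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ closed


def _smooth_with_amounts(x: np.ndarray, op: sp.csr_matrix, amount: np.ndarray) -> np.ndarray:
    """Apply per-vertex fractional one-ring smoothing amounts to columns of x."""
    a = np.asarray(amount, dtype=float)
    if np.any(a < 0):
        raise ValueError("smoothing amounts must be nonnegative")
    kmax = int(np.ceil(a.max())) if a.size else 0
    for k in range(kmax):
        w = np.clip(a - k, 0.0, 1.0)[:, None]
        if not np.any(w):
            break
        x = x + w * (op @ x - x)
    return x


def _ar1_colored(innov: np.ndarray, phi: float) -> np.ndarray:
    """Color each row with a stationary-variance AR(1) recursion."""
    if phi == 0:
        return innov
    return lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi], innov, axis=1)


def _simulate_field(
    mesh: SphereMesh,
    op: sp.csr_matrix,
    amount: np.ndarray,
    ar1_phi: float,
    n_timepoints: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vertices × timepoints fluctuation field with the given smoothing map."""
    innov = rng.standard_normal((mesh.n_vertices, n_timepoints))
    field = _smooth_with_amounts(innov, op, amount)
    return _ar1_colored(field, ar1_phi)


def simulate_subject_timeseries(
    mesh: SphereMesh,
    smoothing_iters: float = 2.0,
    ar1_phi: float = 0.3,
    n_timepoints: int = 120,
    seed: int = 0,
    repetition_time: float = 2.0,
    subject_id: str = "sim",
) -> BoldSurface:
    """One subject's surface BOLD series with homogeneous spatial smoothing.

    ``smoothing_iters`` rounds (possibly fractional) of closed one-ring mean
    filtering of independent Gaussian fields set the spatial autocorrelation
    — and therefore the expected ReHo; with 0 rounds and ``ar1_phi`` = 0 the
    vertexwise series are independent and E[ReHo1] = 1/K ≈ 1/7.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if smoothing_iters < 0:
        raise ValueError("smoothing_iters must be nonnegative")
    rng = np.random.default_rng(seed)
    op = _one_ring_mean_operator(mesh)
    amount = np.full(mesh.n_vertices, float(smoothing_iters))
    field = _simulate_field(mesh, op, amount, ar1_phi, n_timepoints, rng)
    signal = _BASELINE + _FLUCT_SD * field
    return BoldSurface(signal=signal, repetition_time=repetition_time, subject_id=subject_id)


# ---------------------------------------------------------------------------
# calibration: smoothing amount -> expected mean ReHo

_CAL_GRID = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0])
_calibration_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def calibrate_smoothing(
    mesh: SphereMesh,
    ar1_phi: float,
    n_timepoints: int,
    amounts: np.ndarray = _CAL_GRID,
    n_reps: int = 3,
    seed: int = 12345,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo curve of whole-mesh mean ring-1 ReHo vs smoothing amount.

    Cached per (mesh size, phi, n_timepoints) so repeated cohort simulations
    under one design reuse it.  The curve is strictly increasing in the
    smoothing amount, so it can be inverted by linear interpolation.
    """
    key = (mesh.n_vertices, round(float(ar1_phi), 6), int(n_timepoints),
           tuple(np.round(amounts, 6)), n_reps, seed)
    if key in _calibration_cache:
        return _calibration_cache[key]
    op = _one_ring_mean_operator(mesh)
    table = build_neighbor_table(mesh, ring_order=1)
    rng = np.random.default_rng(seed)
    means = np.empty(len(amounts))
    for i, a in enumerate(amounts):
        vals = []
        for _ in range(n_reps):
            amount = np.full(mesh.n_vertices, float(a))
            fld = _simulate_field(mesh, op, amount, ar1_phi, n_timepoints, rng)
            ts = BoldSurface(signal=_BASELINE + _FLUCT_SD * fld,
                             repetition_time=2.0, subject_id="cal")
            vals.append(compute_reho(ts, table).global_mean)
        means[i] = np.mean(vals)
    # enforce monotonicity against Monte-Carlo jitter before inversion
    means = np.maximum.accumulate(means)
    result = (np.asarray(amounts, dtype=float), means)
    _calibration_cache[key] = result
    return result


def _dilate_region(mesh: SphereMesh, region: np.ndarray, rings: int = 1) -> np.ndarray:
    """Region plus its ``rings``-ring halo on the mesh graph."""
    out = set(int(v) for v in region)
    frontier = set(out)
    adj = mesh.adjacency
    for _ in range(rings):
        new = set()
        for v in frontier:
            new.update(adj.indices[adj.indptr[v]: adj.indptr[v + 1]].tolist())
        frontier = new - out
        out |= new
    return np.array(sorted(out), dtype=int)


def _amount_for_reho(target: np.ndarray, amounts: np.ndarray, rehos: np.ndarray) -> np.ndarray:
    """Invert the calibration curve; targets outside its range are clipped."""
    target = np.asarray(target, dtype=float)
    if np.any(target < rehos[0] - 0.02) or np.any(target > rehos[-1] + 0.02):
        warnings.warn("homogeneity target outside calibration range; clipping",
                      RuntimeWarning, stacklevel=2)
    return np.interp(target, rehos, amounts)


# ---------------------------------------------------------------------------
# motion

def simulate_motion_trace(
    n_timepoints: int,
    spike_prob: float = 0.03,
    seed: int = 0,
    step_sd_tran: float = 0.02,
    step_sd_rot: float = 0.02,
    spike_scale: float = 1.0,
) -> MotionTrace:
    """Slowly drifting translations (mm) and rotations (degrees) with
    occasional transient spikes; deterministic per seed.

    Positions follow a mean-reverting walk (AR(1), coefficient 0.95) driven by
    per-frame innovations of the given sd; a spike displaces single frames by
    N(0, spike_scale) on every axis, mimicking abrupt head jerks.
    """
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps_t = rng.normal(0.0, step_sd_tran, size=(n_timepoints, 3))
    steps_r = rng.normal(0.0, step_sd_rot, size=(n_timepoints, 3))
    steps_t[0] = 0.0
    steps_r[0] = 0.0
    pos_t = lfilter([1.0], [1.0, -0.95], steps_t, axis=0)
    pos_r = lfilter([1.0], [1.0, -0.95], steps_r, axis=0)
    spikes = rng.random(n_timepoints) < spike_prob
    spikes[0] = False
    if spikes.any():
        k = int(spikes.sum())
        pos_t[spikes] += rng.normal(0.0, spike_scale, size=(k, 3))
        pos_r[spikes] += rng.normal(0.0, spike_scale, size=(k, 3))
    return MotionTrace(translations=pos_t, rotations=pos_r)


# ---------------------------------------------------------------------------
# cohort

def _truncated_fiq(rng: np.random.Generator) -> float:
    """fIQ around 108 sd 15, redrawn into the ±2 sd window [78, 138]."""
    while True:
        v = rng.normal(_FIQ_MEAN, _FIQ_SD)
        if abs(v - _FIQ_MEAN) <= 2 * _FIQ_SD:
            return float(v)


def _ados_scores(
    region_reho: np.ndarray, rho: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Integer ADOS-like subscores correlating with regional ReHo at ~rho.

    Each subscale is a linear mix of the standardized region-mean ReHo and
    independent noise (sample-standardized, so the pre-rounding sample
    correlation is exactly rho), shifted/scaled to a plausible nonnegative
    integer range.
    """
    n = len(region_reho)
    z = region_reho - region_reho.mean()
    sd = z.std()
    z = z / sd if sd > 0 else np.zeros(n)
    out = {}
    scales = {"ADOS_TOTAL": (12.0, 4.0), "ADOS_COMM": (4.0, 1.5),
              "ADOS_SOCIAL": (8.0, 2.5), "ADOS_STEREO_BEHAV": (2.0, 1.0)}
    for name in ADOS_SUBSCALES:
        eps = rng.standard_normal(n)
        if n > 1:
            eps = eps - eps.mean()
            # orthogonalize against z so the mixed correlation is exact
            if sd > 0:
                eps = eps - z * (eps @ z) / (z @ z)
            esd = eps.std()
            eps = eps / esd if esd > 0 else eps
        mixed = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        center, spread = scales[name]
        out[name] = np.maximum(0, np.round(center + spread * mixed)).astype(int)
    return out


def simulate_cohort(mesh: SphereMesh, design: CohortDesign) -> Cohort:
    """Generate the full two-group multi-site cohort bundle.

    Per-subject homogeneity is a per-vertex smoothing-amount map obtained by
    inverting the calibration curve at the subject's target ReHo: baseline +
    site offset everywhere, plus the group effect in ``effect_region`` and
    the group-specific age drift in ``interaction_region`` (age centered at
    the middle of ``age_range``).  QC metrics derive from simulated motion
    traces via the package's own metric definitions, so the QC filter is
    exercised end to end.  Fully reproducible from ``design.seed``.
    """
    design.validate_for_mesh(mesh)
    base_seq = np.random.SeedSequence(design.seed)
    pheno_rng = np.random.default_rng(base_seq.spawn(1)[0])
    op = _one_ring_mean_operator(mesh)
    table = build_neighbor_table(mesh, ring_order=1)

    effects_present = (
        design.effect_size_delta != 0
        or (design.effect_region.size > 0 and design.effect_trait_sd > 0)
        or design.age_slope_patient != 0
        or design.age_slope_control != 0
        or np.any(design.site_offsets != 0)
    )
    if effects_present:
        amounts_grid, rehos_grid = calibrate_smoothing(
            mesh, design.ar1_phi, design.n_timepoints
        )
        base_reho = float(np.interp(design.smoothing_iters_base, amounts_grid, rehos_grid))
    else:
        amounts_grid = rehos_grid = None
        base_reho = np.nan

    age_lo, age_hi = design.age_range
    age_mid = 0.5 * (age_lo + age_hi)
    site_names = [f"SITE{i + 1:02d}" for i in range(design.n_sites)]

    # Elevated-homogeneity targets are painted on the region plus a one-ring
    # halo so every region vertex's closed neighborhood carries the target
    # smoothing; ReHo is a neighborhood property, and without the halo the
    # region boundary would be strongly attenuated.
    effect_zone = (_dilate_region(mesh, design.effect_region)
                   if design.effect_region.size else design.effect_region)
    interaction_zone = (_dilate_region(mesh, design.interaction_region)
                        if design.interaction_region.size else design.interaction_region)

    subjects: list[SubjectData] = []
    rows = []
    sub_counter = 0
    n_subjects = design.n_sites * 2 * design.subjects_per_site_per_group
    child_seqs = base_seq.spawn(n_subjects)

    for s_idx, site in enumerate(site_names):
        for group in ("patient", "control"):
            for _ in range(design.subjects_per_site_per_group):
                seq = child_seqs[sub_counter]
                rng = np.random.default_rng(seq)
                sub_counter += 1
                sid = f"sub{sub_counter:04d}"
                age = float(pheno_rng.uniform(age_lo, age_hi))
                fiq = _truncated_fiq(pheno_rng)

                if effects_present:
                    target = np.full(mesh.n_vertices, base_reho + design.site_offsets[s_idx])
                    if group == "patient" and effect_zone.size:
                        trait = pheno_rng.normal(0.0, design.effect_trait_sd)
                        target[effect_zone] += design.effect_size_delta + trait
                    if interaction_zone.size:
                        slope = (design.age_slope_patient if group == "patient"
                                 else design.age_slope_control)
                        target[interaction_zone] += slope * (age - age_mid)
                    amount = _amount_for_reho(target, amounts_grid, rehos_grid)
                else:
                    amount = np.full(mesh.n_vertices, design.smoothing_iters_base)

                field = _simulate_field(mesh, op, amount, design.ar1_phi,
                                        design.n_timepoints, rng)
                # weakly mixed WM/CSF-like confound series for the regression
                # step; scaled by the per-vertex field sd so the relative
                # contamination is uniform across smoothing levels
                confounds = _ar1_colored(rng.standard_normal((2, design.n_timepoints)), 0.5).T
                if design.confound_weight_sd > 0:
                    wts = rng.normal(0.0, design.confound_weight_sd, size=(mesh.n_vertices, 2))
                    field_sd = field.std(axis=1, keepdims=True)
                    field = field + field_sd * (wts @ confounds.T)
                signal = _BASELINE + _FLUCT_SD * field
                bold = BoldSurface(signal=signal, repetition_time=design.repetition_time,
                                   subject_id=sid)

                motion = simulate_motion_trace(
                    design.n_timepoints,
                    spike_prob=0.03,
                    seed=int(rng.integers(2**31)),
                    step_sd_tran=float(abs(rng.normal(0.0, 0.03)) + 0.008),
                    step_sd_rot=float(abs(rng.normal(0.0, 0.03)) + 0.008),
                    spike_scale=float(rng.uniform(0.1, 0.6)),
                )
                max_tran, max_rot, mean_fd = motion_metrics(motion)
                mc_bbr = float(np.clip(rng.normal(0.5, 0.13), 0.02, 1.2))
                qc = QCRecord(subject_id=sid, max_tran=max_tran, max_rot=max_rot,
                              mean_fd=mean_fd, mc_bbr=mc_bbr)

                jac_innov = rng.standard_normal((mesh.n_vertices, 1))
                jac = 1.0 + 0.08 * _smooth_with_amounts(
                    jac_innov, op, np.full(mesh.n_vertices, 3.0)
                ).ravel()

                subjects.append(SubjectData(
                    subject_id=sid, site=site, group=group, age=age, fiq=fiq,
                    bold=bold, motion=motion, jacobian=jac, confounds=confounds, qc=qc,
                ))
                rows.append({
                    "SUB_ID": sid, "SITE_ID": site,
                    "DX_GROUP": 1 if group == "patient" else 2,
                    "AGE_AT_SCAN": age, "FIQ": fiq, "SEX": 1,
                    "MAX_TRAN": max_tran, "MAX_ROT": max_rot,
                    "MEAN_FD": mean_fd, "MC_BBR": mc_bbr,
                })

    pheno = pd.DataFrame(rows)

    # symptom scores for patients only, tied to mean ReHo in the effect region
    patient_idx = [i for i, s in enumerate(subjects) if s.group == "patient"]
    region = design.effect_region if design.effect_region.size else np.arange(mesh.n_vertices)
    region_means = np.array([
        compute_reho(subjects[i].bold, table).values[region].mean() for i in patient_idx
    ])
    ados = _ados_scores(region_means, design.ados_correlation_rho, pheno_rng)
    for name in ADOS_SUBSCALES:
        col = np.full(len(subjects), np.nan)
        col[patient_idx] = ados[name]
        pheno[name] = col

    return Cohort(mesh=mesh, design=design, subjects=subjects, phenotypes=pheno)
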