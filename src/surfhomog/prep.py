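"""Surface time-series conditioning and motion/registration quality control.

Implements the surface-level subset of a resting-state functional pipeline:
tanh despiking, grand-mean intensity scaling to 10,000, Friston-24 motion
expansion, nuisance regression, 0.01–0.1 Hz band-pass filtering, and
linear+quadratic detrending — applied in that order by default — plus the
four-quantity motion/registration QC filter (maxTran ≤ 2 mm, maxRot ≤ 2°,
meanFD ≤ 0.4 mm, mcBBR < 0.75).

Volume-space steps (slice timing, realignment, surface projection, BBR
registration itself) are out of scope: inputs are already vertices ×
timepoints matrices, and mcBBR arrives as a precomputed scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BoldSurface",
    "QCRecord",
    "despike",
    "grand_mean_scale",
    "friston24",
    "regress_nuisance",
    "bandpass",
    "detrend",
    "motion_metrics",
    "qc_filter",
    "prep_chain",
    "QC_MAX_TRAN_MM",
    "QC_MAX_ROT_DEG",
    "QC_MAX_FD_MM",
    "QC_MAX_BBR",
]

# exclusion thresholds of the motion/registration QC filter
QC_MAX_TRAN_MM = 2.0
QC_MAX_ROT_DEG = 2.0
QC_MAX_FD_MM = 0.4
QC_MAX_BBR = 0.75

FD_ROTATION_RADIUS_MM = 50.0  # Power convention: rotations on a 50 mm sphere


@dataclass
class BoldSurface:
    """One subject's surface-sampled BOLD signal.

    signal : vertices × timepoints matrix (arbitrary BOLD units)
    repetition_time : sampling interval in seconds
    """

    signal: np.ndarray
    repetition_time: float
    subject_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a vertices × timepoints matrix")
        if self.signal.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return int(self.signal.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.signal.shape[1])


@dataclass
class QCRecord:
    """Per-subject motion/registration quality metrics and the pass flag."""

    subject_id: str
    max_tran: float | None  # mm
    max_rot: float | None  # degrees
    mean_fd: float | None  # mm
    mc_bbr: float | None  # dimensionless BBR cost

    def evaluate(
        self,
        max_tran: float = QC_MAX_TRAN_MM,
        max_rot: float = QC_MAX_ROT_DEG,
        max_fd: float = QC_MAX_FD_MM,
        max_bbr: float = QC_MAX_BBR,
    ) -> tuple[bool, list[str]]:
        """Apply the four exclusion criteria; missing metrics always exclude.

        Boundary semantics follow the stated inequalities: the three motion
        metrics pass at their threshold (≤) while mcBBR must be strictly
        below its threshold.
        """
        metrics = {
            "maxTran": self.max_tran,
            "maxRot": self.max_rot,
            "meanFD": self.mean_fd,
            "mcBBR": self.mc_bbr,
        }
        missing = [k for k, m in metrics.items() if m is None or not np.isfinite(m)]
        if missing:
            return False, ["missing-qc"]
        reasons = []
        if self.max_tran > max_tran:
            reasons.append("maxTran")
        if self.max_rot > max_rot:
            reasons.append("maxRot")
        if self.mean_fd > max_fd:
            reasons.append("meanFD")
        if self.mc_bbr >= max_bbr:  # strict < to pass
            reasons.append("mcBBR")
        return len(reasons) == 0, reasons

    @property
    def passed(self) -> bool:
        return self.evaluate()[0]


def _motion_arrays(motion) -> tuple[np.ndarray, np.ndarray]:
    """Accept a MotionTrace-like object or a (T, 6) array."""
    if hasattr(motion, "translations"):
        tr = np.asarray(motion.translations, dtype=float)
        ro = np.asarray(motion.rotations, dtype=float)
    else:
        m = np.asarray(motion, dtype=float)
        if m.ndim != 2 or m.shape[1] != 6:
            raise ValueError(f"motion must have 6 columns, got shape {m.shape}")
        tr, ro = m[:, :3], m[:, 3:]
    if tr.shape != ro.shape or tr.shape[1] != 3:
        raise ValueError("translations and rotations must both be T × 3")
    return tr, ro


def despike(ts: BoldSurface, clip_sigma: float = 4.0) -> BoldSurface:
    """Compress outliers with a hyperbolic-tangent soft clip.

    Per vertex, with m the median and s = 1.4826·MAD the robust sd, values
    beyond the band m ± c (c = clip_sigma·s) map to m + c·tanh((x−m)/c);
    values inside the band pass unchanged.  Output extremes are bounded by
    m ± c.  Constant series (s = 0) are returned unchanged.
    """
    if clip_sigma <= 0:
        raise ValueError("clip_sigma must be positive")
    x = ts.signal
    m = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - m), axis=1, keepdims=True)
    c = clip_sigma * 1.4826 * mad
    out = x.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        clipped = m + c * np.tanh((x - m) / np.where(c > 0, c, 1.0))
    beyond = (np.abs(x - m) > c) & (c > 0)
    out[beyond] = clipped[beyond]
    return replace(ts, signal=out)


def grand_mean_scale(ts: BoldSurface, target: float = 10000.0) -> BoldSurface:
    """Rescale so the overall (4D) mean intensity equals ``target``."""
    mean = ts.signal.mean()
    if mean <= 0:
        raise ValueError(f"overall mean must be positive, got {mean:g}")
    return replace(ts, signal=ts.signal * (target / mean))


def friston24(motion) -> np.ndarray:
    """Friston 24-parameter motion expansion: [m, m_lag, m², m_lag²].

    The lagged series is padded with a zero first row.  Accepts a MotionTrace
    or a (T, 6) array; returns a (T, 24) nuisance matrix.
    """
    tr, ro = _motion_arrays(motion)
    m = np.hstack([tr, ro])
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def regress_nuisance(ts: BoldSurface, regressors: np.ndarray) -> BoldSurface:
    """Per-vertex least-squares residuals, temporal mean preserved.

    An intercept is added internally; the design (with intercept) must be full
    column rank, otherwise the collinear columns are named in the error.
    """
    x = np.asarray(regressors, dtype=float)
    if x.ndim != 2 or x.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"regressors must have {ts.n_timepoints} rows, got shape {x.shape}"
        )
    design = np.column_stack([np.ones(x.shape[0]), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    y = ts.signal.T  # T × V
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = (resid + y.mean(axis=0, keepdims=True)).T
    return replace(ts, signal=out)


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Greedy scan for columns adding no rank (0 = intercept)."""
    bad, kept = [], []
    for j in range(design.shape[1]):
        trial = design[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(j)
    return bad


def bandpass(ts: BoldSurface, low: float = 0.01, high: float = 0.1) -> BoldSurface:
    """Ideal discrete-Fourier band-pass: retain bins with low ≤ f ≤ high.

    The temporal mean is removed before filtering and restored afterwards.
    Linear in the signal.
    """
    nyquist = 1.0 / (2.0 * ts.repetition_time)
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got [{low}, {high}]")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz is at/above Nyquist {nyquist:g} Hz")
    x = ts.signal
    mean = x.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x - mean, axis=1)
    freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.repetition_time)
    keep = (freqs >= low) & (freqs <= high)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=ts.n_timepoints, axis=1) + mean
    return replace(ts, signal=out)


def detrend(ts: BoldSurface, order: int = 2) -> BoldSurface:
    """Remove polynomial trends up to ``order`` (default linear + quadratic),
    restoring each vertex's temporal mean."""
    n = ts.n_timepoints
    if n <= order + 1:
        raise ValueError(f"need more than {order + 1} timepoints, got {n}")
    t = np.arange(n, dtype=float)
    design = np.column_stack([t**p for p in range(order + 1)])
    y = ts.signal.T
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = (resid + y.mean(axis=0, keepdims=True)).T
    return replace(ts, signal=out)


def motion_metrics(motion) -> tuple[float, float, float]:
    """(maxTran mm, maxRot degrees, meanFD mm) of a motion trace.

    maxTran is the largest framewise Euclidean translation norm; maxRot the
    largest per-axis absolute rotation; meanFD the Power framewise
    displacement (|Δ translations| plus |Δ rotations| expressed as arc length
    on a 50 mm sphere), averaged over frames 2..T.
    """
    tr, ro = _motion_arrays(motion)
    if tr.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not (np.all(np.isfinite(tr)) and np.all(np.isfinite(ro))):
        raise ValueError("motion trace contains non-finite values")
    max_tran = float(np.linalg.norm(tr, axis=1).max())
    max_rot = float(np.abs(ro).max())
    dtr = np.diff(tr, axis=0)
    dro = np.deg2rad(np.diff(ro, axis=0))
    fd = np.abs(dtr).sum(axis=1) + FD_ROTATION_RADIUS_MM * np.abs(dro).sum(axis=1)
    return max_tran, max_rot, float(fd.mean())


def qc_filter(
    records: list[QCRecord],
    max_tran: float = QC_MAX_TRAN_MM,
    max_rot: float = QC_MAX_ROT_DEG,
    max_fd: float = QC_MAX_FD_MM,
    max_bbr: float = QC_MAX_BBR,
) -> tuple[list[str], dict[str, list[str]]]:
    """Split subjects into retained ids and {excluded id: violated criteria}."""
    retained, excluded = [], {}
    for rec in records:
        ok, reasons = rec.evaluate(max_tran, max_rot, max_fd, max_bbr)
        if ok:
            retained.append(rec.subject_id)
        else:
            excluded[rec.subject_id] = reasons
    return retained, excluded


DEFAULT_PREP_STEPS = ("despike", "scale", "regress", "bandpass", "detrend")


def prep_chain(
    ts: BoldSurface,
    nuisance: np.ndarray | None = None,
    steps: tuple[str, ...] = DEFAULT_PREP_STEPS,
    clip_sigma: float = 4.0,
    scale_target: float = 10000.0,
    low: float = 0.01,
    high: float = 0.1,
) -> BoldSurface:
    """Apply the conditioning steps in the given order (default: despike →
    grand-mean scale → nuisance regression → band-pass → detrend).

    ``nuisance`` holds the timepoints × p confound matrix (e.g. Friston-24
    expansion plus WM/CSF mean columns); the regression step is skipped when
    it is None.
    """
    for step in steps:
        if step == "despike":
            ts = despike(ts, clip_sigma=clip_sigma)
        elif step == "scale":
            ts = grand_mean_scale(ts, target=scale_target)
        elif step == "regress":
            if nuisance is not None:
                ts = regress_nuisance(ts, nuisance)
        elif step == "bandpass":
            ts = bandpass(ts, low=low, high=high)
        elif step == "detrend":
            ts = detrend(ts)
        else:
            raise ValueError(f"unknown prep step {step!r}")
    return ts
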