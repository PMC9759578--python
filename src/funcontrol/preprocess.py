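"""Motion-aware postprocessing of ROI BOLD timeseries.

Implements the standard connectivity-oriented cleaning chain applied to
each run after minimal preprocessing and ROI extraction:

1. framewise displacement (FD) from the six rigid-body parameters,
   both raw and from respiration-notch-filtered parameters;
2. censoring of high-motion frames (FD threshold, short-segment pruning);
3. spectral (Lomb-Scargle) interpolation of censored frames so temporal
   filters see no gaps;
4. zero-phase band-pass filtering of data and of the 36-column confound
   matrix (6 motion + global + white matter + CSF, each with temporal
   derivative, square, and squared derivative);
5. ordinary-least-squares nuisance regression fit on retained frames;
6. re-censoring: interpolated frames exist only to stabilize filtering
   and never enter covariance estimation;
7. run- and task-level quality control (mean notch FD, good-frame
   minima), then per-run detrend / z-score and concatenation across runs
   within a task.

The pipeline order interpolate -> filter -> regress -> re-censor is part
of the contract: reordering changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MotionRecord",
    "RunTimeseries",
    "ConfoundMatrix",
    "QCStatus",
    "framewise_displacement",
    "notch_filter_motion",
    "alias_band",
    "censor_mask",
    "build_confound_matrix",
    "spectral_interpolate",
    "bandpass",
    "nuisance_regress",
    "qc_run",
    "qc_task",
    "finalize_task_timeseries",
    "clean_run",
    "extract_roi_timeseries",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
DEFAULT_ROTATION_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_MIN_CONTIGUOUS = 5
DEFAULT_NOTCH_BAND_HZ = (0.31, 0.41)
DEFAULT_BANDPASS_HZ = (0.009, 0.08)
DEFAULT_RUN_MEAN_FD_LIMIT_MM = 0.5
DEFAULT_MIN_GOOD_PER_RUN = 50
DEFAULT_MIN_GOOD_PER_TASK = 150


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionRecord:
    """Six rigid-body motion parameters for one run plus derived FD series.

    ``params`` is 6 x T (translations in mm, rotations in radians).
    ``fd_raw`` is FD of the parameters as given; ``fd_notch`` is FD after
    notch filtering the parameters to suppress respiration-band content.
    FD at frame 0 is defined as 0.
    """

    params: np.ndarray
    fd_raw: np.ndarray
    fd_notch: np.ndarray
    tr_seconds: float

    @classmethod
    def from_params(
        cls,
        params: np.ndarray,
        tr_seconds: float,
        rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM,
        notch_band_hz: tuple[float, float] = DEFAULT_NOTCH_BAND_HZ,
    ) -> "MotionRecord":
        params = _check_motion_params(params)
        fd_raw = framewise_displacement(params, rotation_radius)
        filtered = notch_filter_motion(params, notch_band_hz, tr_seconds)
        fd_notch = framewise_displacement(filtered, rotation_radius)
        return cls(params=params, fd_raw=fd_raw, fd_notch=fd_notch, tr_seconds=tr_seconds)


@dataclass(frozen=True)
class QCStatus:
    included: bool
    reason: str
    mean_fd_notch: float
    n_good: int


@dataclass(frozen=True)
class RunTimeseries:
    """ROI x T matrix for one run with its censor mask and QC status."""

    data: np.ndarray
    censor_mask: np.ndarray
    tr_seconds: float
    qc: QCStatus | None = None
    roi_ids: tuple = field(default=())

    @property
    def n_good(self) -> int:
        return int(np.sum(self.censor_mask))


@dataclass(frozen=True)
class ConfoundMatrix:
    """36 x T nuisance-regressor table with labeled rows.

    Nine base signals (six motion parameters, global, white matter, CSF)
    each expanded as {raw, temporal derivative, square, squared
    derivative}.  Derivatives are backward differences with first
    element 0; squares are elementwise.
    """

    values: np.ndarray
    labels: tuple

    @property
    def n_columns(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.T, columns=list(self.labels))


# ---------------------------------------------------------------------------
# framewise displacement and censoring
# ---------------------------------------------------------------------------


def _check_motion_params(params: np.ndarray) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[0] != 6:
        raise ValueError(
            f"motion parameters must be a 6 x T array "
            f"(3 translations mm, 3 rotations rad), got shape {params.shape}"
        )
    if params.shape[1] < 2:
        raise ValueError("need at least 2 frames to compute displacement")
    return params


def framewise_displacement(
    params: np.ndarray, rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement in mm.

    Sum over the six parameters of the absolute backward difference,
    rotations converted to arc length on a sphere of ``rotation_radius``
    (default 50 mm).  ``fd[0] = 0`` by convention.
    """
    params = _check_motion_params(params)
    scaled = params.copy()
    scaled[3:] *= rotation_radius
    diffs = np.abs(np.diff(scaled, axis=1))
    fd = np.zeros(params.shape[1])
    fd[1:] = diffs.sum(axis=0)
    return fd


def alias_band(band_hz: tuple[float, float], tr_seconds: float) -> tuple[float, float]:
    """Map a physical frequency band to its image under sampling aliasing.

    Respiration (~0.3-0.4 Hz) is above the Nyquist frequency of typical
    BOLD sampling (0.25 Hz at TR 2 s) but still appears in the sampled
    motion traces at the aliased frequency ``|f - fs * round(f / fs)|``.
    Band edges are mapped individually and re-ordered.  Bands already
    below Nyquist map to themselves.
    """
    fs = 1.0 / tr_seconds
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ValueError(f"band edges must satisfy 0 < low < high, got {band_hz}")
    mapped = sorted(abs(f - fs * round(f / fs)) for f in (lo, hi))
    if mapped[0] == mapped[1] or mapped[0] <= 0 or mapped[1] >= fs / 2:
        raise ValueError(
            f"band {band_hz} Hz maps to degenerate image {tuple(mapped)} "
            f"at sampling rate {fs} Hz"
        )
    return (mapped[0], mapped[1])


def notch_filter_motion(
    params: np.ndarray,
    band_hz: tuple[float, float] = DEFAULT_NOTCH_BAND_HZ,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase band-stop filter of the motion parameters.

    The stop band is first mapped through :func:`alias_band` so a
    physical respiration band above Nyquist lands on its aliased image.
    A second-order Butterworth band-stop is applied forward-backward
    (``filtfilt``), preserving phase and DC.
    """
    params = _check_motion_params(params)
    lo, hi = alias_band(band_hz, tr_seconds)
    nyq = 0.5 / tr_seconds
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="bandstop")
    return sps.filtfilt(b, a, params, axis=1)


def censor_mask(
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_contiguous: int = DEFAULT_MIN_CONTIGUOUS,
) -> np.ndarray:
    """Boolean retention mask: True = frame kept.

    Frames with ``fd > threshold_mm`` are censored; afterwards every
    maximal run of retained frames shorter than ``min_contiguous`` is
    censored as well.  An all-False mask is a legal output.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be > 0")
    if min_contiguous < 1:
        raise ValueError("min_contiguous must be >= 1")
    fd = np.asarray(fd, dtype=float)
    mask = fd <= threshold_mm
    # prune retained segments shorter than min_contiguous
    out = mask.copy()
    t = 0
    T = len(mask)
    while t < T:
        if mask[t]:
            start = t
            while t < T and mask[t]:
                t += 1
            if t - start < min_contiguous:
                out[start:t] = False
        else:
            t += 1
    return out


# ---------------------------------------------------------------------------
# confounds
# ---------------------------------------------------------------------------


def _backward_diff(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[..., 1:] = np.diff(x, axis=-1)
    return d


def build_confound_matrix(
    motion: np.ndarray,
    global_sig: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
) -> ConfoundMatrix:
    """36-parameter confound table from nine base signals.

    Base signals: 6 motion parameters plus global, white-matter and CSF
    signals.  Expansions per base: raw, backward-difference derivative
    (first element 0), elementwise square, and square of the derivative.
    """
    motion = _check_motion_params(motion)
    T = motion.shape[1]
    extras = []
    for name, sig in (("global", global_sig), ("wm", wm), ("csf", csf)):
        sig = np.asarray(sig, dtype=float).ravel()
        if sig.shape[0] != T:
            raise ValueError(
                f"{name} signal length {sig.shape[0]} does not match motion length {T}"
            )
        extras.append(sig)
    base = np.vstack([motion, np.vstack(extras)])
    base_labels = list(MOTION_COLUMNS) + ["global", "wm", "csf"]
    deriv = _backward_diff(base)
    rows, labels = [], []
    for expansion, block in (
        ("", base),
        ("_derivative", deriv),
        ("_power2", base**2),
        ("_derivative_power2", deriv**2),
    ):
        rows.append(block)
        labels.extend(f"{lbl}{expansion}" for lbl in base_labels)
    return ConfoundMatrix(values=np.vstack(rows), labels=tuple(labels))


# ---------------------------------------------------------------------------
# spectral interpolation and temporal filtering
# ---------------------------------------------------------------------------


def spectral_interpolate(
    data: np.ndarray,
    mask: np.ndarray,
    tr_seconds: float,
    oversample: int = 2,
    max_frequency_factor: float = 0.5,
) -> np.ndarray:
    """Replace censored frames with a least-squares spectral reconstruction.

    A Lomb-Scargle-type fit: the retained frames are jointly regressed on
    sine/cosine pairs over an oversampled frequency grid, and the fitted
    spectrum is evaluated at every frame.  The joint fit (minimum-norm
    least squares via SVD) interpolates through gaps rather than
    attenuating them, which a bin-by-bin periodogram fit would do.  The
    grid ceiling is ``max_frequency_factor`` x Nyquist (default half):
    the reconstruction exists to stabilize the subsequent low-frequency
    band-pass, and an all-the-way-to-Nyquist dictionary behaves like a
    white-noise prior that refuses to bridge even single-frame gaps.
    Retained frames are returned unchanged; only censored frames are
    substituted.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    T = data.shape[1]
    if mask.shape[0] != T:
        raise ValueError("mask length must match number of frames")
    n_good = int(mask.sum())
    if n_good < 2:
        raise ValueError(f"spectral interpolation requires >= 2 retained frames, got {n_good}")
    if n_good == T:
        return data.copy()

    t_all = np.arange(T) * tr_seconds
    t_good = t_all[mask]
    X = data[:, mask]
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean

    span = t_good[-1] - t_good[0]
    df = 1.0 / (oversample * span)
    fmax = max_frequency_factor * 0.5 / tr_seconds
    freqs = np.arange(df, fmax + df / 2, df)
    w = 2.0 * np.pi * freqs[None, :]  # 1 x F

    design_good = np.concatenate(
        [np.sin(t_good[:, None] * w), np.cos(t_good[:, None] * w)], axis=1
    )  # Tgood x 2F
    # generous singular-value cutoff: directions the censored sampling
    # barely observes are dropped instead of amplified, keeping the
    # interpolant stable under last-digit input perturbations
    beta, *_ = np.linalg.lstsq(design_good, Xc.T, rcond=1e-6)
    design_all = np.concatenate(
        [np.sin(t_all[:, None] * w), np.cos(t_all[:, None] * w)], axis=1
    )
    recon = (design_all @ beta).T + mean

    out = data.copy()
    out[:, ~mask] = recon[:, ~mask]
    return out


def bandpass(
    data: np.ndarray,
    band_hz: tuple[float, float] = DEFAULT_BANDPASS_HZ,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass along time."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lo, hi = band_hz
    nyq = 0.5 / tr_seconds
    if not (0 < lo < hi < nyq):
        raise ValueError(
            f"band must satisfy 0 < low < high < Nyquist ({nyq} Hz), got {band_hz}"
        )
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass")
    return sps.filtfilt(b, a, data, axis=1)


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------


def nuisance_regress(
    data: np.ndarray,
    confounds: ConfoundMatrix,
    mask: np.ndarray,
) -> tuple[np.ndarray, tuple]:
    """OLS removal of confounds, fit on retained frames only.

    The coefficients are estimated from retained frames and the fitted
    model is evaluated at every frame, so residuals exist everywhere but
    are orthogonal to the confounds exactly on the retained frames.
    Collinear confound columns are dropped (QR with pivoting) and their
    labels returned.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    C = confounds.values
    if C.shape[1] != data.shape[1]:
        raise ValueError("confounds and data must have the same number of frames")
    if mask.shape[0] != data.shape[1]:
        raise ValueError("mask length must match number of frames")
    Xg = C[:, mask].T  # Tgood x k
    # rank-revealing column selection
    from scipy.linalg import qr

    norms = np.linalg.norm(Xg, axis=0)
    nonzero = norms > 0
    keep = np.flatnonzero(nonzero)
    dropped: list[str] = [confounds.labels[i] for i in np.flatnonzero(~nonzero)]
    if keep.size:
        _, R, piv = qr(Xg[:, keep], mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xg.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > tol))
        kept = np.sort(keep[piv[:rank]])
        dropped.extend(confounds.labels[i] for i in keep[piv[rank:]])
    else:
        kept = np.array([], dtype=int)
    if kept.size == 0:
        return data.copy(), tuple(dropped)
    beta, *_ = np.linalg.lstsq(C[kept][:, mask].T, data[:, mask].T, rcond=None)
    residual = data - beta.T @ C[kept]
    return residual, tuple(dropped)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def qc_run(
    fd_notch: np.ndarray,
    mask: np.ndarray,
    run_mean_fd_limit: float = DEFAULT_RUN_MEAN_FD_LIMIT_MM,
    min_good: int = DEFAULT_MIN_GOOD_PER_RUN,
) -> QCStatus:
    """Run-level inclusion decision.

    Excluded when mean notch-filtered FD exceeds ``run_mean_fd_limit``
    (default 0.5 mm) or fewer than ``min_good`` (default 50) retained
    frames survive censoring.
    """
    mean_fd = float(np.mean(fd_notch))
    n_good = int(np.sum(mask))
    if mean_fd > run_mean_fd_limit:
        return QCStatus(False, "mean FD", mean_fd, n_good)
    if n_good < min_good:
        return QCStatus(False, "good timepoints", mean_fd, n_good)
    return QCStatus(True, "", mean_fd, n_good)


def qc_task(
    runs: Sequence[RunTimeseries],
    min_good_total: int = DEFAULT_MIN_GOOD_PER_TASK,
) -> tuple[bool, str, list[RunTimeseries]]:
    """Task-level decision over the included runs of one (session, context).

    Runs individually excluded by :func:`qc_run` do not contribute; the
    task is excluded when the included runs hold fewer than
    ``min_good_total`` (default 150) good frames altogether.
    """
    included = [r for r in runs if r.qc is not None and r.qc.included]
    total_good = sum(r.n_good for r in included)
    if total_good < min_good_total:
        return False, f"only {total_good} good timepoints across runs", included
    return True, "", included


# ---------------------------------------------------------------------------
# finalization
# ---------------------------------------------------------------------------


def _detrend_zscore(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linear detrend (fit on retained frames) then z-score on retained frames."""
    T = data.shape[1]
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(X[mask], data[:, mask].T, rcond=None)
    out = data - beta.T @ X.T
    mu = out[:, mask].mean(axis=1, keepdims=True)
    sd = out[:, mask].std(axis=1, keepdims=True)
    # a residual that is numerically zero (e.g. a pure trend) stays zero
    # rather than being blown up by division with float noise
    floor = 1e-10 * max(1.0, float(np.abs(data).max()))
    sd[sd <= floor] = 1.0
    return (out - mu) / sd


def finalize_task_timeseries(
    runs: Sequence[RunTimeseries],
) -> tuple[np.ndarray, np.ndarray]:
    """Detrend, standardize and concatenate runs within one task.

    Each run is linearly detrended and z-scored using retained-frame
    statistics, then runs are concatenated in acquisition order.
    Returns the concatenated ROI x T_task matrix and the combined
    retention mask; censored frames must be excluded from any downstream
    covariance computation.
    """
    if not runs:
        raise ValueError("no runs to finalize")
    n_rois = runs[0].data.shape[0]
    roi_ids = runs[0].roi_ids
    for r in runs:
        if r.data.shape[0] != n_rois or r.roi_ids != roi_ids:
            raise ValueError("all runs must share the same ROI set")
        if r.tr_seconds != runs[0].tr_seconds:
            raise ValueError("all runs must share the same TR")
    pieces, masks = [], []
    for r in runs:
        if r.n_good < 2:
            raise ValueError("a run with fewer than 2 retained frames cannot be standardized")
        pieces.append(_detrend_zscore(r.data, r.censor_mask))
        masks.append(r.censor_mask)
    return np.concatenate(pieces, axis=1), np.concatenate(masks)


# ---------------------------------------------------------------------------
# per-run orchestration
# ---------------------------------------------------------------------------


def clean_run(
    data: np.ndarray,
    motion: MotionRecord,
    global_sig: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    *,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    min_contiguous: int = DEFAULT_MIN_CONTIGUOUS,
    band_hz: tuple[float, float] = DEFAULT_BANDPASS_HZ,
    run_mean_fd_limit: float = DEFAULT_RUN_MEAN_FD_LIMIT_MM,
    min_good: int = DEFAULT_MIN_GOOD_PER_RUN,
    roi_ids: Sequence = (),
) -> RunTimeseries:
    """Full cleaning chain for one run.

    Censor on notch FD -> spectral interpolation -> band-pass (data and
    confounds) -> nuisance regression on retained frames -> QC.  The
    returned ``censor_mask`` re-censors the interpolated frames.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    tr = motion.tr_seconds
    mask = censor_mask(motion.fd_notch, fd_threshold, min_contiguous)
    qc = qc_run(motion.fd_notch, mask, run_mean_fd_limit, min_good)
    if not qc.included:
        return RunTimeseries(
            data=data, censor_mask=mask, tr_seconds=tr, qc=qc, roi_ids=tuple(roi_ids)
        )
    interpolated = spectral_interpolate(data, mask, tr)
    filtered = bandpass(interpolated, band_hz, tr)
    confounds = build_confound_matrix(motion.params, global_sig, wm, csf)
    confounds_f = ConfoundMatrix(
        values=bandpass(confounds.values, band_hz, tr), labels=confounds.labels
    )
    residual, _dropped = nuisance_regress(filtered, confounds_f, mask)
    return RunTimeseries(
        data=residual, censor_mask=mask, tr_seconds=tr, qc=qc, roi_ids=tuple(roi_ids)
    )


# ---------------------------------------------------------------------------
# ROI extraction from 4-D volumes
# ---------------------------------------------------------------------------


def extract_roi_timeseries(
    volume4d,
    atlas: pd.DataFrame,
    radius_mm: float = 4.0,
) -> tuple[np.ndarray, list]:
    """Mean timeseries within spherical ROIs of a 4-D NIfTI image.

    ``atlas`` needs columns roi_id, x, y, z (world mm) and optionally
    network_label.  For each ROI center, voxels whose world coordinates
    fall within ``radius_mm`` are averaged per frame.  ROIs with no
    in-bounds voxel are flagged missing (NaN rows) and their ids
    returned, supporting atlases whose field of view truncates part of
    the parcellation.
    """
    import nibabel as nib  # local import: volumetric path is optional

    if not isinstance(volume4d, nib.spatialimages.SpatialImage):
        volume4d = nib.load(volume4d)
    vol = np.asarray(volume4d.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {vol.shape}")
    affine = volume4d.affine
    nx, ny, nz, T = vol.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = (affine @ vox.T).T[:, :3]
    flat = vol.reshape(-1, T)

    out = np.full((len(atlas), T), np.nan)
    missing = []
    for row_idx, row in enumerate(atlas.itertuples(index=False)):
        center = np.array([row.x, row.y, row.z], dtype=float)
        d2 = np.sum((world - center) ** 2, axis=1)
        sel = d2 <= radius_mm**2
        if not sel.any():
            missing.append(row.roi_id)
            continue
        out[row_idx] = flat[sel].mean(axis=0)
    return out, missing
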