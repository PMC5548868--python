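"""ROI time-series denoising and functional-connectivity extraction.

Turns per-participant ROI-averaged BOLD time series, head-motion traces and
tissue nuisance signals into scrubbed, denoised vectors of pairwise Pearson
correlations (functional connectivity, FC).

The processing order is fixed: band-pass filter the ROI series, linearly
regress out motion and (band-passed) tissue nuisance signals, then correlate
over the motion-scrubbed frames only.  Filtering and regression always run
on the full series; scrubbing removes frames at correlation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "RoiTimeSeries",
    "MotionTrace",
    "NuisanceSignals",
    "FrameMask",
    "FcVector",
    "edge_pairs",
    "edge_names",
    "mean_relative_displacement",
    "frame_displacement",
    "scrub_mask",
    "bandpass",
    "nuisance_regress",
    "fc_vector",
    "exclude_zero_variance_rois",
    "participant_fc",
    "cohort_fc_matrix",
]

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")
NUISANCE_COLUMNS = ("wm", "csf", "global")

#: Variance below this (over retained frames) marks an ROI as flat.
ZERO_VARIANCE_TOL = 1e-12


@dataclass
class RoiTimeSeries:
    """Frames × ROIs matrix of ROI-averaged BOLD signal."""

    participant_id: str
    data: np.ndarray
    tr_seconds: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D frames × ROIs array")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Frames × 6 head-motion parameters: tx, ty, tz, rx, ry, rz.

    ``rotation_units`` must be declared; rotations in radians or degrees are
    converted to arc length at the head radius when frame displacement is
    computed, ``"mm"`` means the trace already stores mm-equivalent values.
    """

    data: np.ndarray
    rotation_units: str | None = "mm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("motion trace must be frames × 6")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class NuisanceSignals:
    """Frames × 3 tissue signals: white matter, CSF, whole brain."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("nuisance signals must be frames × 3 (wm, csf, global)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class FrameMask:
    """Boolean retention mask over frames; True = frame kept for correlation."""

    retained: np.ndarray

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.ndim != 1:
            raise ValueError("frame mask must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.retained.size

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class FcVector:
    """Strict lower-triangle vector of pairwise Pearson correlations.

    ``edge_index[k] = (i, j)`` with ``i < j``, enumerated row-major over the
    strict lower triangle (the ``np.tril_indices`` order), a bijection
    between edge positions and ROI pairs.
    """

    values: np.ndarray
    roi_names: list[str]
    edge_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_names)
        expected = n * (n - 1) // 2
        if self.values.size != expected:
            raise ValueError(
                f"{self.values.size} edges but {n} ROIs imply {expected}"
            )
        if self.edge_index is None:
            self.edge_index = edge_pairs(n)

    @property
    def n_edges(self) -> int:
        return self.values.size


def edge_pairs(n_rois: int) -> np.ndarray:
    """(K, 2) array of ROI index pairs (i, j), i < j, tril row-major order."""
    rows, cols = np.tril_indices(n_rois, k=-1)
    return np.column_stack([cols, rows])


def edge_names(roi_names: list[str]) -> list[str]:
    """Edge labels ``"ROIi__ROIj"`` in edge-index order."""
    return [f"{roi_names[i]}__{roi_names[j]}" for i, j in edge_pairs(len(roi_names))]


def mean_relative_displacement(motion: MotionTrace) -> np.ndarray:
    """Per-parameter mean absolute frame-to-frame change, mean of |p_{i+1} - p_i|.

    Returns six nonnegative values, one per motion parameter.
    """
    if motion.n_frames < 2:
        raise ValueError("mean relative displacement requires at least 2 frames")
    return np.abs(np.diff(motion.data, axis=0)).mean(axis=0)


def frame_displacement(
    motion: MotionTrace, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Frame displacement: per transition, the sum of |Δp| over all 6 parameters.

    Rotational parameters declared as ``radians`` or ``degrees`` are converted
    to arc length in mm at ``head_radius_mm`` before summing; ``mm`` traces
    are summed as stored.  Returns a vector of length ``frames - 1`` where
    entry t covers the transition from frame t to frame t+1.
    """
    if motion.n_frames < 2:
        raise ValueError("frame displacement requires at least 2 frames")
    units = motion.rotation_units
    if units not in ("mm", "radians", "degrees"):
        raise ValueError(
            "rotation_units must be declared as 'mm', 'radians' or 'degrees'; "
            f"got {units!r}"
        )
    data = motion.data.copy()
    if units == "degrees":
        data[:, 3:] = np.deg2rad(data[:, 3:]) * head_radius_mm
    elif units == "radians":
        data[:, 3:] = data[:, 3:] * head_radius_mm
    return np.abs(np.diff(data, axis=0)).sum(axis=1)


def scrub_mask(fd: np.ndarray, threshold_mm: float = 0.5) -> FrameMask:
    """Motion-scrubbing mask from a frame-displacement vector.

    A transition t → t+1 with FD above ``threshold_mm`` flags frame t+1; the
    flagged frame is removed together with the previous frame and the two
    subsequent frames, i.e. frames {t, t+1, t+2, t+3} clipped to range.
    """
    fd = np.asarray(fd, dtype=float)
    n_frames = fd.size + 1
    retained = np.ones(n_frames, dtype=bool)
    for t in np.flatnonzero(fd > threshold_mm):
        flagged = t + 1
        lo = max(flagged - 1, 0)
        hi = min(flagged + 3, n_frames)  # flagged + two subsequent, exclusive
        retained[lo:hi] = False
    return FrameMask(retained)


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of each column; output is demeaned.

    A 4th-order Butterworth band-pass run forward and backward (filtfilt)
    gives zero phase and ≥ 20 dB attenuation one octave beyond each band
    edge.  Requires at least 30 frames and ``high_hz`` below Nyquist.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n_frames = series.shape[0]
    if n_frames < 30:
        raise ValueError(f"band-pass needs ≥ 30 frames, got {n_frames}")
    nyquist = 0.5 / tr_seconds
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    sos = sp_signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )
    centered = series - series.mean(axis=0, keepdims=True)
    filtered = sp_signal.sosfiltfilt(sos, centered, axis=0)
    return filtered - filtered.mean(axis=0, keepdims=True)


def nuisance_regress(
    series: np.ndarray,
    motion: MotionTrace,
    nuisance: NuisanceSignals,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Residualize each ROI column against motion and tissue regressors.

    The design matrix is [intercept, 6 motion parameters, band-passed WM,
    CSF and whole-brain signals]; the tissue signals are band-pass filtered
    with the same band as the ROI series before entering the regression.
    Returns least-squares residuals, orthogonal to every regressor.
    """
    series = np.asarray(series, dtype=float)
    n_frames = series.shape[0]
    if motion.n_frames != n_frames or nuisance.n_frames != n_frames:
        raise ValueError(
            f"frame-count mismatch: series {n_frames}, motion {motion.n_frames}, "
            f"nuisance {nuisance.n_frames}"
        )
    tissue = bandpass(nuisance.data, tr_seconds, low_hz, high_hz)
    design = np.column_stack([np.ones(n_frames), motion.data, tissue])
    names = ["intercept", *MOTION_COLUMNS, *NUISANCE_COLUMNS]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR localizes the dependent columns for the error message
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise ValueError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(names[j] for j in bad)
        )
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def fc_vector(series: RoiTimeSeries, mask: FrameMask | None = None) -> FcVector:
    """Pairwise Pearson correlations over retained frames.

    Correlations are computed for every unordered ROI pair over the frames
    retained by ``mask`` (all frames when mask is None).  Fails when fewer
    than 10 frames survive or any ROI is flat over the retained frames.
    """
    if mask is None:
        mask = FrameMask(np.ones(series.n_frames, dtype=bool))
    if mask.n_frames != series.n_frames:
        raise ValueError("mask length does not match frame count")
    if mask.n_retained < 10:
        raise ValueError(
            f"only {mask.n_retained} frames retained; need ≥ 10 for correlation"
        )
    data = series.data[mask.retained]
    variances = data.var(axis=0)
    flat = np.flatnonzero(variances < ZERO_VARIANCE_TOL)
    if flat.size:
        raise ValueError(
            "zero-variance ROI(s) over retained frames: "
            + ", ".join(series.roi_names[k] for k in flat)
        )
    corr = np.corrcoef(data, rowvar=False)
    pairs = edge_pairs(series.n_rois)
    values = np.clip(corr[pairs[:, 0], pairs[:, 1]], -1.0, 1.0)
    return FcVector(values=values, roi_names=list(series.roi_names))


def exclude_zero_variance_rois(
    cohort: list[tuple[RoiTimeSeries, FrameMask | None]],
) -> tuple[list[str], dict[str, list[str]]]:
    """Cohort-wide ROI exclusion: drop an ROI flat in any single participant.

    Returns the retained ROI-name list (order preserved) and a report mapping
    each excluded ROI to the participants in which it was flat.
    """
    if not cohort:
        raise ValueError("empty cohort")
    roi_names = cohort[0][0].roi_names
    report: dict[str, list[str]] = {}
    for series, mask in cohort:
        if series.roi_names != roi_names:
            raise ValueError(
                f"participant {series.participant_id} has a different ROI set"
            )
        keep = mask.retained if mask is not None else slice(None)
        variances = series.data[keep].var(axis=0)
        for k in np.flatnonzero(variances < ZERO_VARIANCE_TOL):
            report.setdefault(roi_names[k], []).append(series.participant_id)
    retained = [name for name in roi_names if name not in report]
    if not retained:
        raise ValueError("all ROIs excluded as zero-variance")
    return retained, report


def participant_fc(
    series: RoiTimeSeries,
    motion: MotionTrace,
    nuisance: NuisanceSignals,
    fd_threshold_mm: float = 0.5,
    head_radius_mm: float = 50.0,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    roi_subset: list[str] | None = None,
) -> tuple[FcVector, FrameMask]:
    """Full single-participant path: band-pass → regress → scrub-aware FC."""
    data = series.data
    if roi_subset is not None:
        idx = [series.roi_names.index(name) for name in roi_subset]
        data = data[:, idx]
        names = list(roi_subset)
    else:
        names = list(series.roi_names)
    filtered = bandpass(data, series.tr_seconds, low_hz, high_hz)
    residual = nuisance_regress(
        filtered, motion, nuisance, series.tr_seconds, low_hz, high_hz
    )
    fd = frame_displacement(motion, head_radius_mm)
    mask = scrub_mask(fd, fd_threshold_mm)
    cleaned = RoiTimeSeries(
        participant_id=series.participant_id,
        data=residual,
        tr_seconds=series.tr_seconds,
        roi_names=names,
    )
    return fc_vector(cleaned, mask), mask


def cohort_fc_matrix(
    participants: list[dict],
    fd_threshold_mm: float = 0.5,
    head_radius_mm: float = 50.0,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
):
    """Participants × edges FC matrix for a cohort, with cohort-wide ROI exclusion.

    ``participants`` is a list of dicts with keys ``series`` (RoiTimeSeries),
    ``motion`` (MotionTrace) and ``nuisance`` (NuisanceSignals).  Returns a
    pandas DataFrame indexed by participant id with edge-name columns, plus a
    per-participant frame-retention report DataFrame.
    """
    import pandas as pd

    masks = []
    for p in participants:
        fd = frame_displacement(p["motion"], head_radius_mm)
        masks.append(scrub_mask(fd, fd_threshold_mm))
    denoised = []
    for p, mask in zip(participants, masks):
        s = p["series"]
        filtered = bandpass(s.data, s.tr_seconds, low_hz, high_hz)
        residual = nuisance_regress(
            filtered, p["motion"], p["nuisance"], s.tr_seconds, low_hz, high_hz
        )
        denoised.append(
            RoiTimeSeries(s.participant_id, residual, s.tr_seconds, list(s.roi_names))
        )
    retained_rois, report = exclude_zero_variance_rois(
        [(s, m) for s, m in zip(denoised, masks)]
    )
    if report:
        warnings.warn(
            f"excluded zero-variance ROIs: {sorted(report)}", stacklevel=2
        )
    rows = []
    for s, mask in zip(denoised, masks):
        idx = [s.roi_names.index(name) for name in retained_rois]
        sub = RoiTimeSeries(s.participant_id, s.data[:, idx], s.tr_seconds, retained_rois)
        rows.append(fc_vector(sub, mask).values)
    fc = pd.DataFrame(
        np.vstack(rows),
        index=[s.participant_id for s in denoised],
        columns=edge_names(retained_rois),
    )
    retention = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in denoised],
            "n_frames": [m.n_frames for m in masks],
            "n_retained": [m.n_retained for m in masks],
        }
    ).set_index("participant_id")
    return fc, retention
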