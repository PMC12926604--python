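"""Temporal quality control for regional BOLD time series.

Implements the per-participant temporal stages that precede connectivity
estimation: zero-phase bandpass filtering, nuisance regression of the six
realignment parameters and their first derivatives, framewise-displacement
(FD) and DVARS computation, frame censoring, and the minimum-usable-data
rule. The pipeline order is fixed: bandpass -> nuisance regression ->
censoring -> correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "MotionTrace",
    "QcReport",
    "bandpass",
    "framewise_displacement",
    "dvars",
    "nuisance_regress",
    "censor",
    "check_minimum_duration",
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
]

#: Default censoring thresholds: FD in mm, DVARS in rescaled signal units.
FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 5.0
#: Minimum usable scan duration in seconds (4.5 minutes).
MINIMUM_USABLE_SECONDS = 270.0
#: Head radius used to convert rotations (radians) to arc-length displacement.
HEAD_RADIUS_MM = 50.0


@dataclass
class RegionalTimeSeries:
    """A timepoints x regions signal matrix with sampling and censor metadata.

    Parameters
    ----------
    values
        Two-dimensional float array, one row per timepoint, one column per
        region, in arbitrary BOLD units.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    region_labels
        Unique label per region (column).
    censor_mask
        Boolean per timepoint; True means the frame is retained. Defaults to
        all-True.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str]
    censor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D timepoints x regions matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        n_t, n_r = self.values.shape
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != n_r:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n_r} regions"
            )
        if len(set(self.region_labels)) != n_r:
            raise ValueError("region labels must be unique")
        if self.censor_mask is None:
            self.censor_mask = np.ones(n_t, dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (n_t,):
            raise ValueError("censor_mask length must equal timepoint count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def retained(self) -> np.ndarray:
        """Signal matrix restricted to retained (non-censored) frames."""
        return self.values[self.censor_mask]


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per frame.

    translations_mm is timepoints x 3 (mm); rotations_rad is timepoints x 3
    (radians).
    """

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_rad = np.asarray(self.rotations_rad, dtype=float)
        for name, arr in (
            ("translations_mm", self.translations_mm),
            ("rotations_rad", self.rotations_rad),
        ):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be timepoints x 3")
        if self.translations_mm.shape[0] != self.rotations_rad.shape[0]:
            raise ValueError("translation and rotation frame counts differ")

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Timepoints x 6 matrix: three translations then three rotations."""
        return np.hstack([self.translations_mm, self.rotations_rad])


@dataclass
class QcReport:
    """Per-participant quality-control summary after censoring."""

    fd_mm: np.ndarray
    dvars: np.ndarray
    n_censored: int
    usable_seconds: float
    passes_minimum: bool


def bandpass(
    ts: RegionalTimeSeries, low_hz: float = 0.009, high_hz: float = 0.08, order: int = 4
) -> RegionalTimeSeries:
    """Zero-phase Butterworth bandpass of every region's signal.

    A forward-backward (``filtfilt``) Butterworth filter of the given order
    is applied per region, preserving pass-band amplitude and removing the
    mean (0 Hz lies outside any pass band).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist} Hz for TR={ts.tr_seconds} s"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return replace(ts, values=filtered)


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame framewise displacement (FD) in millimetres.

    FD_t = sum of absolute backward differences of the three translations
    plus ``head_radius_mm`` times the sum of absolute backward differences
    of the three rotations (arc-length conversion). FD_0 = 0 by convention.
    """
    if motion.n_timepoints < 2:
        raise ValueError("FD requires at least 2 frames")
    d_trans = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + head_radius_mm * d_rot])
    return fd


def _rescale_median(values: np.ndarray, target: float = 1000.0) -> np.ndarray:
    """Rescale the whole matrix so its global median magnitude is ``target``."""
    med = np.median(np.abs(values))
    if med == 0:
        return values
    return values * (target / med)


def dvars(ts: RegionalTimeSeries, normalization: str = "median_1000") -> np.ndarray:
    """Root-mean-square frame-to-frame signal change across regions.

    DVARS_t is the RMS over regions of x_t - x_{t-1}; DVARS_0 = 0. With the
    default ``normalization='median_1000'`` the signal matrix is first
    rescaled to a global median of 1000 so the conventional threshold of 5
    is meaningful; ``'none'`` computes on raw values.
    """
    if ts.n_timepoints < 2:
        raise ValueError("DVARS requires at least 2 frames")
    if normalization == "median_1000":
        vals = _rescale_median(ts.values)
    elif normalization == "none":
        vals = ts.values
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    rms = np.sqrt(np.mean(np.diff(vals, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], rms])


def nuisance_regress(
    ts: RegionalTimeSeries, motion: MotionTrace
) -> RegionalTimeSeries:
    """Residualize every region on the 12 motion regressors plus intercept.

    The design matrix contains the six realignment parameters and their
    first (backward) differences, plus a constant. Residuals are orthogonal
    to every retained regressor; exactly collinear columns are dropped with
    a warning.
    """
    if motion.n_timepoints != ts.n_timepoints:
        raise ValueError("motion trace and time series frame counts differ")
    params = motion.as_matrix()
    derivs = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    design = np.column_stack([np.ones(ts.n_timepoints), params, derivs])

    # Drop collinear columns (keep earliest) so lstsq residuals are exact.
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep: list[int] = []
        for j in range(design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        logger.warning(
            "nuisance design rank-deficient: dropping %d collinear column(s)",
            design.shape[1] - len(keep),
        )
        design = design[:, keep]

    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    residuals = ts.values - design @ beta
    return replace(ts, values=residuals)


def censor(
    ts: RegionalTimeSeries,
    fd: np.ndarray,
    dvars_values: np.ndarray,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD,
    minimum_seconds: float = MINIMUM_USABLE_SECONDS,
) -> tuple[RegionalTimeSeries, QcReport]:
    """Flag high-motion frames and report usable-data totals.

    A frame is censored when FD > ``fd_thresh`` or DVARS > ``dvars_thresh``;
    only the flagged frames are removed (no neighbor augmentation). Returns
    the time series with an updated censor mask and a :class:`QcReport`.
    """
    fd = np.asarray(fd, dtype=float)
    dvars_values = np.asarray(dvars_values, dtype=float)
    if fd.shape != (ts.n_timepoints,) or dvars_values.shape != (ts.n_timepoints,):
        raise ValueError("fd/dvars length must match the time series")
    mask = ~((fd > fd_thresh) | (dvars_values > dvars_thresh))
    mask &= ts.censor_mask
    n_censored = int(ts.n_timepoints - mask.sum())
    usable = float(mask.sum() * ts.tr_seconds)
    report = QcReport(
        fd_mm=fd,
        dvars=dvars_values,
        n_censored=n_censored,
        usable_seconds=usable,
        passes_minimum=usable >= minimum_seconds,
    )
    return replace(ts, censor_mask=mask), report


def check_minimum_duration(
    report: QcReport, minimum_seconds: float = MINIMUM_USABLE_SECONDS
) -> bool:
    """True iff the retained data meets the usable-duration floor (>=)."""
    ok = report.usable_seconds >= minimum_seconds
    if not ok:
        logger.info(
            "participant excluded: %.1f s usable < %.1f s minimum",
            report.usable_seconds,
            minimum_seconds,
        )
    return ok


# ---------------------------------------------------------------------------
# Delimited-text I/O


def write_timeseries(ts: RegionalTimeSeries, path: str | Path) -> None:
    """Write timepoints x regions values as TSV with region-label header."""
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False
    )


def read_timeseries(path: str | Path, tr_seconds: float) -> RegionalTimeSeries:
    """Read a delimited time-series file (header row = region labels)."""
    df = pd.read_csv(path, sep="\t")
    return RegionalTimeSeries(
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_labels=list(df.columns),
    )


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    """Write the 6-column realignment-parameter file (no header)."""
    np.savetxt(path, motion.as_matrix(), fmt="%.8f", delimiter="\t")


def read_motion(path: str | Path) -> MotionTrace:
    """Read a 6-column realignment-parameter text file."""
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got {mat.shape[1]}")
    return MotionTrace(translations_mm=mat[:, :3], rotations_rad=mat[:, 3:])
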