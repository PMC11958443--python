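"""Eye-tracking data-quality metrics and P-CR gaze calibration.

Precision metrics operate on sampled 2D position signals (pupil, CR, or
gaze): RMS-S2S precision is the root-mean-square of Euclidean
sample-to-sample displacements inside a sliding window (200 ms by default),
reported as the median over windows; STD precision is the windowed combined
positional standard deviation sqrt(var_x + var_y), also median-over-windows.
Gaze is calibrated from the pupil-minus-CR vector by per-axis second-order
polynomials with a first-order interaction term (terms 1, x, y, x^2, y^2,
xy), least-squares fit on a fixation grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimedSignal",
    "CalibrationModel",
    "MetricUndefined",
    "AlignmentError",
    "CalibrationError",
    "rms_s2s",
    "std_precision",
    "pcr_vector",
    "fit_calibration",
    "apply_calibration",
    "accuracy_offset",
    "cumulative_detection_rate",
    "mean_pixel_error",
]


class MetricUndefined(ValueError):
    """Raised when a metric has no defined value (too few valid samples)."""


class AlignmentError(ValueError):
    """Raised when two signals' timestamps do not match."""


class CalibrationError(ValueError):
    """Raised for underdetermined or rank-deficient calibration fits."""


@dataclass
class TimedSignal:
    """A sampled 2D position time series; missing samples are NaN rows."""

    t: np.ndarray
    xy: np.ndarray
    fs: float
    unit: str = "px"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (N, 2)")
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.xy).all(axis=1)

    @classmethod
    def from_csv(cls, path, fs: float | None = None, unit: str = "px") -> "TimedSignal":
        """Read columns t, x, y[, valid]; invalid rows become NaN."""
        df = pd.read_csv(path)
        xy = df[["x", "y"]].to_numpy(dtype=np.float64)
        if "valid" in df.columns:
            xy[~df["valid"].astype(bool).to_numpy()] = np.nan
        t = df["t"].to_numpy(dtype=np.float64)
        if fs is None:
            dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
            fs = 1.0 / dt
        return cls(t=t, xy=xy, fs=float(fs), unit=unit)

    def to_csv(self, path) -> None:
        valid = self.valid
        df = pd.DataFrame(
            {"t": self.t, "x": self.xy[:, 0], "y": self.xy[:, 1],
             "valid": valid.astype(int)}
        )
        df.to_csv(Path(path), index=False)


def _window_length(signal: TimedSignal, window: float) -> int:
    n = int(round(window * signal.fs))
    if n < 2:
        raise MetricUndefined(
            f"a {window}s window at {signal.fs} Hz spans fewer than 2 samples"
        )
    return n


def rms_s2s(signal: TimedSignal, window: float = 0.2) -> float:
    """Median windowed RMS of Euclidean sample-to-sample displacements.

    The window slides with a stride of one sample; steps involving a missing
    sample are excluded pairwise, and windows with no valid step are skipped
    before taking the median.
    """
    n = _window_length(signal, window)
    if len(signal) < n:
        raise MetricUndefined("signal shorter than one window")
    d = np.diff(signal.xy, axis=0)
    step_sq = d[:, 0] ** 2 + d[:, 1] ** 2
    valid = np.isfinite(step_sq)
    step_sq = np.where(valid, step_sq, 0.0)
    k = n - 1  # steps per window
    csum = np.concatenate([[0.0], np.cumsum(step_sq)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    sums = csum[k:] - csum[:-k]
    cnts = ccnt[k:] - ccnt[:-k]
    ok = cnts > 0
    if not ok.any():
        raise MetricUndefined("no window contains a valid sample-to-sample step")
    return float(np.median(np.sqrt(sums[ok] / cnts[ok])))


def std_precision(signal: TimedSignal, window: float = 0.2) -> float:
    """Median windowed combined positional SD, sqrt(var_x + var_y).

    Per-axis variances use the unbiased (n-1) estimator over the valid
    samples in each window; windows with fewer than two valid samples are
    skipped.
    """
    n = _window_length(signal, window)
    if len(signal) < n:
        raise MetricUndefined("signal shorter than one window")
    xy = signal.xy
    valid = np.isfinite(xy).all(axis=1)
    v = np.where(valid[:, None], xy, 0.0)
    csum = np.concatenate([np.zeros((1, 2)), np.cumsum(v, axis=0)])
    csq = np.concatenate([np.zeros((1, 2)), np.cumsum(v**2, axis=0)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    sums = csum[n:] - csum[:-n]
    sqs = csq[n:] - csq[:-n]
    cnts = (ccnt[n:] - ccnt[:-n]).astype(np.float64)
    ok = cnts >= 2
    if not ok.any():
        raise MetricUndefined("no window contains two valid samples")
    m = cnts[ok, None]
    var = (sqs[ok] - sums[ok] ** 2 / m) / (m - 1.0)
    var = np.clip(var, 0.0, None)  # guard tiny negatives from cancellation
    return float(np.median(np.sqrt(var.sum(axis=1))))


def pcr_vector(pupil: TimedSignal, cr: TimedSignal) -> TimedSignal:
    """Pupil-minus-CR vector; missing whenever either input is missing."""
    if len(pupil) != len(cr) or not np.allclose(pupil.t, cr.t):
        raise AlignmentError("pupil and CR signals must share timestamps")
    return TimedSignal(t=pupil.t, xy=pupil.xy - cr.xy, fs=pupil.fs,
                       unit=pupil.unit)


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis polynomial coefficients for terms (1, x, y, x^2, y^2, xy)."""

    coef_x: np.ndarray
    coef_y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coef_x) != 6 or len(self.coef_y) != 6:
            raise ValueError("expect 6 coefficients per axis")


def _design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x**2, y**2, x * y])


def fit_calibration(pcr: np.ndarray, targets: np.ndarray) -> CalibrationModel:
    """Least-squares fit of the second-order polynomial map, per output axis.

    ``pcr`` are P-CR vectors (N, 2) at the fixation points; ``targets`` are
    the corresponding screen positions in degrees (N, 2).  Requires at least
    six points in a configuration of full rank (a 3x3 fixation grid
    suffices).
    """
    pcr = np.asarray(pcr, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if len(pcr) < 6:
        raise CalibrationError("need at least 6 calibration points")
    X = _design(pcr)
    if np.linalg.matrix_rank(X) < 6:
        raise CalibrationError("calibration points are degenerate (rank < 6)")
    coef, *_ = np.linalg.lstsq(X, targets, rcond=None)
    return CalibrationModel(coef_x=coef[:, 0], coef_y=coef[:, 1])


def apply_calibration(model: CalibrationModel, pcr: TimedSignal) -> TimedSignal:
    """Map a P-CR signal to gaze degrees; missing samples pass through."""
    X = _design(pcr.xy)
    gaze = np.column_stack([X @ model.coef_x, X @ model.coef_y])
    return TimedSignal(t=pcr.t, xy=gaze, fs=pcr.fs, unit="deg")


def accuracy_offset(
    gaze: TimedSignal,
    target_positions: Sequence[tuple[float, float]],
    fixation_windows: Sequence[tuple[float, float]],
) -> tuple[float, int]:
    """Mean Euclidean offset between median gaze and target, per fixation.

    Each fixation window (t0, t1) is paired with a target position; the
    gaze position for the fixation is the component-wise median over valid
    samples in the window.  Returns (mean offset, number of skipped empty
    windows).
    """
    if len(target_positions) != len(fixation_windows):
        raise ValueError("one target per fixation window required")
    offsets = []
    skipped = 0
    for (t0, t1), tgt in zip(fixation_windows, target_positions):
        sel = (gaze.t >= t0) & (gaze.t <= t1) & gaze.valid
        if not sel.any():
            skipped += 1
            continue
        med = np.median(gaze.xy[sel], axis=0)
        offsets.append(np.hypot(med[0] - tgt[0], med[1] - tgt[1]))
    if not offsets:
        raise MetricUndefined("no fixation window contained valid samples")
    return float(np.mean(offsets)), skipped


def cumulative_detection_rate(
    errors: Sequence[float], thresholds: Sequence[float]
) -> np.ndarray:
    """Fraction of errors at or below each threshold (inclusive)."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise MetricUndefined("no errors to evaluate")
    if np.any(errors < 0):
        raise ValueError("errors must be non-negative")
    return np.array([float(np.mean(errors <= t)) for t in thresholds])


def mean_pixel_error(
    pred: np.ndarray, truth: np.ndarray, scale: float = 1.0
) -> float:
    """Mean Euclidean error after upscaling predictions by ``scale``.

    Pairs with a missing (NaN) prediction or truth are excluded; with no
    valid pair the metric is undefined.
    """
    pred = np.asarray(pred, dtype=np.float64) * scale
    truth = np.asarray(truth, dtype=np.float64)
    err = np.hypot(pred[:, 0] - truth[:, 0], pred[:, 1] - truth[:, 1])
    err = err[np.isfinite(err)]
    if err.size == 0:
        raise MetricUndefined("no valid prediction/truth pairs")
    return float(np.mean(err))
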