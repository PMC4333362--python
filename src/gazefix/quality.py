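"""Recording-level data-quality metrics.

Spatial precision is the sample-to-sample consistency of the recorded gaze,
quantified as the RMS of intersample distances; dispersion is the per-axis
standard deviation; data loss is the fraction of samples with no valid gaze.
All positional metrics are invariant to constant offsets, so spatial
accuracy (calibration offset) does not affect them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import GazeRecording
from .preprocessing import SmoothedTrace

__all__ = [
    "QualityError",
    "DataLossReport",
    "QualityReport",
    "rms_precision",
    "data_loss",
    "sd_dispersion",
    "quality_report",
]


class QualityError(ValueError):
    """Raised when a metric is undefined for the given data."""


def _pairs_mask(trace: SmoothedTrace, mode: str, fixation_intervals) -> np.ndarray:
    """Boolean mask over adjacent sample pairs (i, i+1) entering the RMS."""
    ok = trace.available
    pair_ok = ok[:-1] & ok[1:]
    if mode == "within_fixation":
        if fixation_intervals is None:
            raise QualityError("within_fixation mode needs fixation intervals")
        t = trace.timestamps
        inside = np.zeros(trace.n_samples, dtype=bool)
        for onset, offset in fixation_intervals:
            inside |= (t >= onset) & (t < offset)
        pair_ok &= inside[:-1] & inside[1:]
    elif mode != "all":
        raise ValueError(f"unknown rms_precision mode: {mode!r}")
    return pair_ok


def rms_precision(
    trace: SmoothedTrace,
    dpp: float,
    mode: str = "all",
    fixation_intervals=None,
) -> float:
    """RMS of intersample Euclidean distances (deg) over adjacent available pairs.

    ``mode="within_fixation"`` restricts pairs to the given fixation
    intervals (sequence of ``(onset_ms, offset_ms)``, or objects with
    ``onset``/``offset`` attributes).
    """
    if fixation_intervals is not None:
        fixation_intervals = [
            (iv.onset, iv.offset) if hasattr(iv, "onset") else tuple(iv)
            for iv in fixation_intervals
        ]
    pair_ok = _pairs_mask(trace, mode, fixation_intervals)
    if pair_ok.sum() < 1 or trace.available.sum() < 2:
        raise QualityError("rms_precision undefined: fewer than 2 usable samples")
    dx = np.diff(trace.x)[pair_ok]
    dy = np.diff(trace.y)[pair_ok]
    return float(np.sqrt(np.mean(dx**2 + dy**2)) * dpp)


@dataclass(frozen=True)
class DataLossReport:
    binocular_loss: float  # fraction of samples with neither eye valid
    left_loss: float
    right_loss: float
    n_samples: int


def data_loss(rec: GazeRecording) -> DataLossReport:
    """Fraction of samples with no valid gaze, plus per-eye loss."""
    n = rec.n_samples
    neither = ~(rec.left_valid | rec.right_valid)
    return DataLossReport(
        binocular_loss=float(neither.mean()),
        left_loss=float((~rec.left_valid).mean()),
        right_loss=float((~rec.right_valid).mean()),
        n_samples=n,
    )


def sd_dispersion(trace: SmoothedTrace, dpp: float) -> tuple[float, float]:
    """Per-axis standard deviation of available positions, in degrees.

    Population SD (ddof=0): the dispersion of each sample from the mean,
    which is exactly ``d`` for a trace alternating between ``mean ± d``.
    """
    ok = trace.available
    if ok.sum() < 2:
        raise QualityError("sd_dispersion undefined: fewer than 2 available samples")
    return (
        float(np.std(trace.x[ok]) * dpp),
        float(np.std(trace.y[ok]) * dpp),
    )


@dataclass(frozen=True)
class QualityReport:
    rms_precision: float  # deg; mode given by rms_mode
    rms_mode: str
    sd_dispersion_x: float
    sd_dispersion_y: float
    data_loss_fraction: float
    left_loss: float
    right_loss: float
    single_eye_fraction: float
    n_samples: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def quality_report(
    rec: GazeRecording,
    dpp: float,
    fixation_intervals=None,
    include_single_eye: bool = True,
) -> QualityReport:
    """Compute all quality metrics on the raw combined-eye trace.

    Precision uses ``within_fixation`` mode when fixation intervals are
    supplied (the manufacturer convention: precision during stable gaze),
    else all adjacent available pairs.
    """
    from .preprocessing import combine_eyes

    trace = combine_eyes(rec, include_single_eye=include_single_eye)
    mode = "within_fixation" if fixation_intervals is not None else "all"
    rms = rms_precision(trace, dpp, mode=mode, fixation_intervals=fixation_intervals)
    sdx, sdy = sd_dispersion(trace, dpp)
    loss = data_loss(rec)
    return QualityReport(
        rms_precision=rms,
        rms_mode=mode,
        sd_dispersion_x=sdx,
        sd_dispersion_y=sdy,
        data_loss_fraction=loss.binocular_loss,
        left_loss=loss.left_loss,
        right_loss=loss.right_loss,
        single_eye_fraction=float(trace.single_eye.mean()),
        n_samples=rec.n_samples,
    )
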