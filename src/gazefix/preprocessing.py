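"""Eye combination, bilateral smoothing and per-sample velocity.

The two eyes are averaged into one trace before filtering. The bilateral
filter replaces each available sample by a weighted mean of its temporal
neighbours, where the weight decays with both temporal distance and spatial
distance: jitter (small displacements) is averaged away while saccade-sized
displacements fall outside the range kernel and are left intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io import GazeRecording, ParamError

__all__ = [
    "SmoothedTrace",
    "VelocityTrace",
    "SmoothingParams",
    "load_smoothing",
    "combine_eyes",
    "bilateral_smooth",
    "compute_velocity",
]


@dataclass
class SmoothedTrace:
    """Single combined gaze trace with availability / provenance flags."""

    timestamps: np.ndarray  # ms
    x: np.ndarray  # px, NaN where unavailable
    y: np.ndarray
    available: np.ndarray  # bool
    single_eye: np.ndarray  # bool, exactly one eye contributed
    interpolated: np.ndarray  # bool, set by gap interpolation
    sampling_rate: float
    pupil: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    def copy(self) -> "SmoothedTrace":
        return SmoothedTrace(
            timestamps=self.timestamps.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            available=self.available.copy(),
            single_eye=self.single_eye.copy(),
            interpolated=self.interpolated.copy(),
            sampling_rate=self.sampling_rate,
            pupil=None if self.pupil is None else self.pupil.copy(),
        )


@dataclass
class VelocityTrace:
    """Per-sample gaze velocity in deg/s; NaN where undefined."""

    v: np.ndarray


@dataclass(frozen=True)
class SmoothingParams:
    """Bilateral filter configuration.

    Defaults keep the window shorter than the minimum fixation durations in
    the shipped presets (so the filter cannot bridge events) and block
    averaging across saccade-sized displacements.
    """

    window_ms: float = 100.0
    temporal_sigma_ms: float = 20.0
    range_sigma_deg: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and not (
            self.window_ms > 0 and self.temporal_sigma_ms > 0 and self.range_sigma_deg > 0
        ):
            raise ParamError("smoothing window and sigmas must be positive")


def load_smoothing(source: str | Path | Mapping | None) -> SmoothingParams:
    """Read the optional ``smoothing`` section of a params config."""
    if source is None:
        return SmoothingParams()
    if isinstance(source, SmoothingParams):
        return source
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = dict(raw)
    raw = dict(raw.get("smoothing", raw))
    raw = {k: v for k, v in raw.items() if k in SmoothingParams.__dataclass_fields__}
    return SmoothingParams(**raw)


def combine_eyes(rec: GazeRecording, include_single_eye: bool = True) -> SmoothedTrace:
    """Average the two eyes into one trace.

    Both eyes valid: arithmetic mean. Exactly one valid: that eye's
    coordinates if ``include_single_eye`` (the sample is flagged
    ``single_eye``), otherwise missing. Neither: missing. Pupil values are
    combined with the same rule.
    """
    both = rec.left_valid & rec.right_valid
    left_only = rec.left_valid & ~rec.right_valid
    right_only = rec.right_valid & ~rec.left_valid
    n = rec.n_samples

    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    x[both] = 0.5 * (rec.left_x[both] + rec.right_x[both])
    y[both] = 0.5 * (rec.left_y[both] + rec.right_y[both])
    single = left_only | right_only
    if include_single_eye:
        x[left_only] = rec.left_x[left_only]
        y[left_only] = rec.left_y[left_only]
        x[right_only] = rec.right_x[right_only]
        y[right_only] = rec.right_y[right_only]
        available = both | single
    else:
        available = both
        single = np.zeros(n, dtype=bool)

    pupil = None
    if rec.pupil_left is not None or rec.pupil_right is not None:
        pl = rec.pupil_left if rec.pupil_left is not None else np.full(n, np.nan)
        pr = rec.pupil_right if rec.pupil_right is not None else np.full(n, np.nan)
        with np.errstate(invalid="ignore"):
            pupil = np.where(
                np.isfinite(pl) & np.isfinite(pr),
                0.5 * (pl + pr),
                np.where(np.isfinite(pl), pl, pr),
            )
        pupil[~available] = np.nan

    return SmoothedTrace(
        timestamps=rec.timestamps.copy(),
        x=x,
        y=y,
        available=available,
        single_eye=single & available,
        interpolated=np.zeros(n, dtype=bool),
        sampling_rate=rec.sampling_rate,
        pupil=pupil,
    )


def bilateral_smooth(
    trace: SmoothedTrace,
    smoothing: SmoothingParams | None = None,
    dpp: float = 0.0177,
) -> SmoothedTrace:
    """Bilateral-filter the combined trace; the availability mask is unchanged.

    Each available sample becomes the weighted mean of the available samples
    within ``±window_ms``, with weight
    ``exp(-dt²/2σt²) · exp(-d²/2σr²)`` where ``dt`` is the time offset and
    ``d`` the spatial distance (deg) to the centre sample.
    """
    sp = smoothing or SmoothingParams()
    if not sp.enabled:
        return trace.copy()
    dt_nominal = 1000.0 / trace.sampling_rate
    h = max(1, int(round(sp.window_ms / dt_nominal)))
    n = trace.n_samples

    def windows(a: np.ndarray) -> np.ndarray:
        padded = np.concatenate([np.full(h, np.nan), a, np.full(h, np.nan)])
        return np.lib.stride_tricks.sliding_window_view(padded, 2 * h + 1)

    xw, yw, tw = windows(trace.x), windows(trace.y), windows(trace.timestamps)
    dt = tw - trace.timestamps[:, None]
    d2 = ((xw - trace.x[:, None]) ** 2 + (yw - trace.y[:, None]) ** 2) * dpp**2
    with np.errstate(invalid="ignore"):
        w = np.exp(
            -(dt**2) / (2.0 * sp.temporal_sigma_ms**2)
            - d2 / (2.0 * sp.range_sigma_deg**2)
        )
        w[~np.isfinite(w)] = 0.0
        w[np.abs(dt) > sp.window_ms] = 0.0
        w[~(np.isfinite(xw) & np.isfinite(yw))] = 0.0

    wsum = w.sum(axis=1)
    xn = np.where(w > 0, xw, 0.0)
    yn = np.where(w > 0, yw, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = np.where(wsum > 0, (w * xn).sum(axis=1) / wsum, np.nan)
        ys = np.where(wsum > 0, (w * yn).sum(axis=1) / wsum, np.nan)

    out = trace.copy()
    out.x = np.where(trace.available, xs, np.nan)
    out.y = np.where(trace.available, ys, np.nan)
    return out


def compute_velocity(
    trace: SmoothedTrace, dpp: float, sampling_rate: float | None = None
) -> VelocityTrace:
    """Forward intersample velocity in deg/s.

    ``v[i]`` is the Euclidean distance from sample ``i`` to ``i+1`` scaled by
    ``dpp`` and the sampling rate; the last sample copies its predecessor.
    NaN wherever either endpoint of the difference is missing.
    """
    fs = sampling_rate if sampling_rate is not None else trace.sampling_rate
    with np.errstate(invalid="ignore"):
        dist = np.hypot(np.diff(trace.x), np.diff(trace.y))
    v = dist * dpp * fs
    v = np.append(v, v[-1] if v.size else np.nan)
    return VelocityTrace(v=v)
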