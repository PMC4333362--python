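"""Gap interpolation and velocity-threshold event segmentation.

Samples whose velocity exceeds the threshold are saccadic; maximal runs of
missing samples are gaps; everything in between is a candidate fixation.
Before segmenting for good, short missing-data gaps that lie *within* a
fixation (both flanks are fixations whose centroids nearly coincide) are
filled by linear interpolation, which removes the spurious velocity peaks
such gaps would otherwise create.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import DetectionParams, GazeRecording
from .posthoc import Fixation, FixationSet, _stats_from_trace, posthoc_validate
from .preprocessing import (
    SmoothedTrace,
    SmoothingParams,
    VelocityTrace,
    bilateral_smooth,
    combine_eyes,
    compute_velocity,
)

logger = logging.getLogger("gazefix")

__all__ = [
    "Segment",
    "EventSegmentation",
    "segment_by_velocity",
    "interpolate_gaps",
    "detect_fixations",
    "DetectionResult",
]

GAP, FIXATION, SACCADE = 0, 1, 2
_LABEL_NAMES = {GAP: "gap", FIXATION: "fixation", SACCADE: "saccade"}


@dataclass(frozen=True)
class Segment:
    label: str  # fixation | saccade | gap
    onset: float  # ms, half-open [onset, offset)
    offset: float
    start: int  # sample index, half-open [start, stop)
    stop: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class EventSegmentation:
    """Contiguous, non-overlapping segments tiling the recording."""

    segments: list

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def by_label(self, label: str) -> list:
        return [s for s in self.segments if s.label == label]

    def sample_labels(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=object)
        for s in self.segments:
            out[s.start: s.stop] = s.label
        return out


def _sample_labels(trace: SmoothedTrace, v: VelocityTrace, threshold: float) -> np.ndarray:
    lab = np.full(trace.n_samples, FIXATION, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        lab[v.v > threshold] = SACCADE  # NaN compares false -> stays fixation
    lab[~trace.available] = GAP
    return lab


def segment_by_velocity(
    trace: SmoothedTrace, v: VelocityTrace, velocity_threshold: float
) -> EventSegmentation:
    """Run-length encode per-sample labels into an event segmentation.

    A segment's offset is the onset of the next segment; the final segment
    extends one nominal sample period past the last timestamp so that
    segments tile the full recording.
    """
    lab = _sample_labels(trace, v, velocity_threshold)
    n = lab.size
    if not trace.available.any():
        warnings.warn("all samples missing; no events detected", UserWarning, stacklevel=2)
    dt = 1000.0 / trace.sampling_rate
    starts = np.concatenate([[0], np.flatnonzero(np.diff(lab)) + 1])
    stops = np.concatenate([starts[1:], [n]])
    segments = []
    for s, e in zip(starts, stops):
        onset = float(trace.timestamps[s])
        offset = float(trace.timestamps[e]) if e < n else float(trace.timestamps[-1] + dt)
        segments.append(
            Segment(label=_LABEL_NAMES[int(lab[s])], onset=onset, offset=offset,
                    start=int(s), stop=int(e))
        )
    return EventSegmentation(segments=segments)


def interpolate_gaps(
    trace: SmoothedTrace,
    v: VelocityTrace,
    params: DetectionParams,
    segmentation: EventSegmentation | None = None,
) -> tuple[SmoothedTrace, int]:
    """Fill short in-fixation missing-data gaps by linear interpolation.

    A gap qualifies iff its duration is at most ``interpolation_latency``,
    both flanking segments are fixations, and the Euclidean distance between
    the flanks' centroids (deg) is below
    ``max_interpolation_displacement`` — i.e. the gap plausibly interrupts a
    single fixation rather than hiding a gaze shift. Filled samples are
    flagged ``interpolated``; velocity must be recomputed by the caller.
    Edge gaps (no flank on one side) are never filled. Decisions use the
    pre-interpolation segmentation only (single pass, deterministic).
    """
    if segmentation is None:
        segmentation = segment_by_velocity(trace, v, params.velocity_threshold)
    segs = segmentation.segments
    out = trace.copy()
    n_filled = 0
    for k, seg in enumerate(segs):
        if seg.label != "gap" or k == 0 or k == len(segs) - 1:
            continue
        if seg.duration > params.interpolation_latency or params.interpolation_latency == 0:
            continue
        prev, nxt = segs[k - 1], segs[k + 1]
        if prev.label != "fixation" or nxt.label != "fixation":
            continue
        cprev = _segment_centroid(trace, prev)
        cnext = _segment_centroid(trace, nxt)
        if cprev is None or cnext is None:
            continue
        dist_deg = math.hypot(cprev[0] - cnext[0], cprev[1] - cnext[1]) * params.degrees_per_pixel
        if not dist_deg < params.max_interpolation_displacement:
            continue
        i0, i1 = seg.start - 1, seg.stop  # last available before, first after
        t = trace.timestamps
        frac = (t[seg.start: seg.stop] - t[i0]) / (t[i1] - t[i0])
        out.x[seg.start: seg.stop] = trace.x[i0] + frac * (trace.x[i1] - trace.x[i0])
        out.y[seg.start: seg.stop] = trace.y[i0] + frac * (trace.y[i1] - trace.y[i0])
        out.available[seg.start: seg.stop] = True
        out.interpolated[seg.start: seg.stop] = True
        n_filled += 1
    if n_filled:
        logger.info("interpolated %d gap(s)", n_filled)
    return out, n_filled


def _segment_centroid(trace: SmoothedTrace, seg: Segment):
    sl = slice(seg.start, seg.stop)
    ok = trace.available[sl]
    if not ok.any():
        return None
    return (
        float(np.mean(trace.x[sl][ok])),
        float(np.mean(trace.y[sl][ok])),
    )


class DetectionResult(NamedTuple):
    fixations: FixationSet
    segmentation: EventSegmentation
    trace: SmoothedTrace


def _fixations_from_segmentation(
    trace: SmoothedTrace, segmentation: EventSegmentation, params: DetectionParams
) -> list:
    dpp = params.degrees_per_pixel
    out = []
    for seg in segmentation.by_label("fixation"):
        indices = np.arange(seg.start, seg.stop)
        stats = _stats_from_trace(trace, indices, dpp)
        if stats["n_samples"] == 0:
            continue
        out.append(
            Fixation(
                onset=seg.onset,
                offset=seg.offset,
                sample_indices=indices,
                **stats,
            )
        )
    return out


def detect_fixations(
    rec: GazeRecording,
    params: DetectionParams,
    smoothing: SmoothingParams | None = None,
) -> DetectionResult:
    """Full pipeline: combine eyes, smooth, interpolate gaps, segment, validate.

    Velocity is computed on the smoothed trace, recomputed from scratch after
    interpolation, and the resulting fixation candidates are passed through
    the three post-hoc criteria. Deterministic: identical inputs give
    identical results.
    """
    trace = combine_eyes(rec, include_single_eye=params.include_single_eye)
    trace = bilateral_smooth(trace, smoothing, dpp=params.degrees_per_pixel)
    v = compute_velocity(trace, params.degrees_per_pixel)
    trace, n_filled = interpolate_gaps(trace, v, params)
    v = compute_velocity(trace, params.degrees_per_pixel)
    segmentation = segment_by_velocity(trace, v, params.velocity_threshold)
    candidates = _fixations_from_segmentation(trace, segmentation, params)
    fixset = posthoc_validate(candidates, params, trace=trace)
    fixset.counts["interpolated_gaps"] = n_filled
    fixset.counts["candidates"] = len(candidates)
    return DetectionResult(fixations=fixset, segmentation=segmentation, trace=trace)
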