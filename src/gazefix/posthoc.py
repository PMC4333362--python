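"""Post-hoc validation of detected fixations.

Three criteria applied in a fixed order:

1. merge adjacent fixations that are close in time and space,
2. reject fixations whose intersample RMS exceeds a threshold,
3. reject fixations shorter than a minimum duration.

Boundary conventions (each chosen to follow the thresholds' wording
literally): merge gap strict (``gap < merge_max_gap``), merge distance
inclusive (``<= merge_max_distance``), RMS rejection strict
(``rms > max_rms_per_fixation``), duration rejection strict
(``duration < min_fixation_duration``).

Rejected fixations are kept in an audit list with a flag naming the
criterion, so a downstream manual-moderation step can review them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import DetectionParams

logger = logging.getLogger("gazefix")

__all__ = [
    "Fixation",
    "FixationSet",
    "fixation_rms",
    "merge_adjacent",
    "reject_by_rms",
    "reject_by_duration",
    "posthoc_validate",
]


@dataclass
class Fixation:
    """One detected fixation with per-event statistics.

    ``sample_indices`` (indices into the originating trace) is carried for
    statistics recomputation during merging and is not serialized.
    """

    onset: float  # ms, half-open interval [onset, offset)
    offset: float
    centroid_x: float  # px
    centroid_y: float
    centroid_x_deg: float
    centroid_y_deg: float
    rms: float  # deg
    n_samples: int
    n_interpolated: int = 0
    single_eye_fraction: float = 0.0
    pupil_mean: float | None = None
    flags: set = field(default_factory=set)
    label: str = "fixation"
    sample_indices: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"fixation duration must be positive, got {self.duration}")


@dataclass
class FixationSet:
    """Validated fixations plus the audit trail of rejected ones."""

    surviving: list
    rejected: list
    params_used: DetectionParams
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.surviving)

    def __iter__(self):
        return iter(self.surviving)


def fixation_rms(x: np.ndarray, y: np.ndarray, dpp: float) -> float:
    """RMS of intersample Euclidean distances (deg), both axes together.

    NaN coordinates are skipped; distances are taken between consecutive
    available samples. Fewer than two available samples gives 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[ok], y[ok]
    if xs.size < 2:
        return 0.0
    d2 = np.diff(xs) ** 2 + np.diff(ys) ** 2
    return float(math.sqrt(np.mean(d2)) * dpp)


def _stats_from_trace(trace, indices: np.ndarray, dpp: float) -> dict:
    """Recompute centroid / rms / pupil / counts over member samples."""
    avail = trace.available[indices]
    idx = indices[avail]
    x, y = trace.x[idx], trace.y[idx]
    cx = float(np.mean(x)) if idx.size else float("nan")
    cy = float(np.mean(y)) if idx.size else float("nan")
    pupil = None
    if trace.pupil is not None:
        pvals = trace.pupil[idx]
        pvals = pvals[np.isfinite(pvals)]
        pupil = float(np.mean(pvals)) if pvals.size else None
    return {
        "centroid_x": cx,
        "centroid_y": cy,
        "centroid_x_deg": cx * dpp,
        "centroid_y_deg": cy * dpp,
        "rms": fixation_rms(x, y, dpp),
        "n_samples": int(idx.size),
        "n_interpolated": int(trace.interpolated[idx].sum()),
        "single_eye_fraction": float(trace.single_eye[idx].mean()) if idx.size else 0.0,
        "pupil_mean": pupil,
    }


def _merge_pair(a: Fixation, b: Fixation, trace, dpp: float) -> Fixation:
    flags = (a.flags | b.flags) | {"merged"}
    if trace is not None and a.sample_indices is not None and b.sample_indices is not None:
        indices = np.concatenate([a.sample_indices, b.sample_indices])
        stats = _stats_from_trace(trace, indices, dpp)
        return Fixation(
            onset=a.onset,
            offset=b.offset,
            flags=flags,
            label=a.label,
            sample_indices=indices,
            **stats,
        )
    # Fixation-level fallback (no trace): sample-count-weighted statistics;
    # the bridging intersample pair cannot be reconstructed and is ignored.
    na, nb = max(a.n_samples, 1), max(b.n_samples, 1)
    w = na + nb
    cx = (a.centroid_x * na + b.centroid_x * nb) / w
    cy = (a.centroid_y * na + b.centroid_y * nb) / w
    pa, pb = a.pupil_mean, b.pupil_mean
    pupil = None
    if pa is not None or pb is not None:
        pupil = ((pa or 0.0) * na + (pb or 0.0) * nb) / (
            (na if pa is not None else 0) + (nb if pb is not None else 0) or 1
        )
    rms = math.sqrt(((na - 1) * a.rms**2 + (nb - 1) * b.rms**2) / max(na + nb - 2, 1))
    return Fixation(
        onset=a.onset,
        offset=b.offset,
        centroid_x=cx,
        centroid_y=cy,
        centroid_x_deg=cx * dpp,
        centroid_y_deg=cy * dpp,
        rms=rms,
        n_samples=a.n_samples + b.n_samples,
        n_interpolated=a.n_interpolated + b.n_interpolated,
        single_eye_fraction=(a.single_eye_fraction * na + b.single_eye_fraction * nb) / w,
        pupil_mean=pupil,
        flags=flags,
        label=a.label,
    )


def merge_adjacent(
    fixations: list,
    merge_max_gap: float,
    merge_max_distance: float,
    dpp: float,
    trace=None,
) -> list:
    """Greedy left-to-right chained merging, iterated to a fixpoint.

    A fixation merges with its successor iff the inter-fixation interval is
    strictly below ``merge_max_gap`` and the centroid distance is at most
    ``merge_max_distance`` (deg). The merged fixation spans first onset to
    second offset — duration includes the bridged gap — while centroid, RMS
    and pupil statistics are recomputed over member samples only.
    """
    fixations = list(fixations)
    changed = True
    while changed:
        changed = False
        out: list = []
        i = 0
        while i < len(fixations):
            cur = fixations[i]
            j = i + 1
            while j < len(fixations):
                nxt = fixations[j]
                gap = nxt.onset - cur.offset
                dist = math.hypot(
                    cur.centroid_x - nxt.centroid_x, cur.centroid_y - nxt.centroid_y
                ) * dpp
                if gap < merge_max_gap and dist <= merge_max_distance:
                    cur = _merge_pair(cur, nxt, trace, dpp)
                    changed = True
                    j += 1
                else:
                    break
            out.append(cur)
            i = j
        fixations = out
    return fixations


def reject_by_rms(fixations: list, max_rms_per_fixation: float) -> tuple[list, list]:
    """Split fixations into (surviving, rejected) on ``rms > threshold``."""
    surviving, rejected = [], []
    for f in fixations:
        if f.rms > max_rms_per_fixation:
            f.flags.add("rejected_rms")
            rejected.append(f)
        else:
            surviving.append(f)
    return surviving, rejected


def reject_by_duration(fixations: list, min_fixation_duration: float) -> tuple[list, list]:
    """Split fixations into (surviving, rejected) on ``duration < threshold``."""
    surviving, rejected = [], []
    for f in fixations:
        if f.duration < min_fixation_duration:
            f.flags.add("rejected_duration")
            rejected.append(f)
        else:
            surviving.append(f)
    return surviving, rejected


def posthoc_validate(
    fixations: list, params: DetectionParams, trace=None
) -> FixationSet:
    """Apply merge, RMS rejection, then duration rejection — in this order."""
    n_in = len(fixations)
    merged = merge_adjacent(
        fixations,
        merge_max_gap=params.merge_max_gap,
        merge_max_distance=params.merge_max_distance,
        dpp=params.degrees_per_pixel,
        trace=trace,
    )
    n_merged = n_in - len(merged)
    surviving, rej_rms = reject_by_rms(merged, params.max_rms_per_fixation)
    surviving, rej_dur = reject_by_duration(surviving, params.min_fixation_duration)
    rejected = sorted(rej_rms + rej_dur, key=lambda f: f.onset)
    counts = {
        "merged": n_merged,
        "rms_rejected": len(rej_rms),
        "duration_rejected": len(rej_dur),
    }
    logger.info(
        "posthoc: merged: %d, rms-rejected: %d, duration-rejected: %d",
        counts["merged"], counts["rms_rejected"], counts["duration_rejected"],
    )
    return FixationSet(
        surviving=surviving, rejected=rejected, params_used=params, counts=counts
    )
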