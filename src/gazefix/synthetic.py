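"""Synthetic gaze simulator with ground-truth events.

Generates alternating fixations and saccades (optionally smooth-pursuit
ramps), renders them as binocular pixel samples with calibrated Gaussian
jitter, and knocks out samples to emulate missing-data gaps and single-eye
episodes. Because the true segmentation is known exactly, every stage of the
detection pipeline can be scored without any real recording.

Noise calibration: the per-eye, per-axis jitter standard deviation is
``noise_rms / sqrt(2)`` so that the RMS of intersample distances measured on
the *combined* (two-eye-average) trace equals ``noise_rms`` in expectation —
averaging the eyes halves the variance per axis, differencing doubles it
back, and the two axes add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import GazeRecording

__all__ = [
    "SimulationParams",
    "TrueSegment",
    "GroundTruthEvents",
    "simulate_recording",
    "inject_fixation_gaps",
    "score_recovery",
    "RecoveryReport",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for one simulated recording. ``seed`` is mandatory."""

    seed: int
    sampling_rate: float = 120.0
    n_fixations: int = 10
    fixation_duration_ms: tuple = (200.0, 800.0)  # uniform range
    saccade_amplitude_deg: tuple = (5.0, 5.0)  # uniform range (or scalar)
    saccade_duration_ms: float = 30.0
    n_pursuits: int = 0
    pursuit_velocity_deg_s: float = 5.0
    pursuit_duration_ms: float = 500.0
    noise_rms: float = 0.0  # deg; measured combined-trace RMS precision
    gap_rate_hz: float = 0.0  # expected both-eye gaps per second
    gap_length_ms: tuple = (20.0, 80.0)
    single_eye_rate_hz: float = 0.0
    single_eye_duration_ms: float = 100.0
    vergence_offset_deg: float = 0.0
    degrees_per_pixel: float = 0.0177
    screen_bounds: tuple = (1920.0, 1080.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        amp = self.saccade_amplitude_deg
        if np.isscalar(amp):
            object.__setattr__(self, "saccade_amplitude_deg", (float(amp), float(amp)))
        if self.sampling_rate <= 0 or self.n_fixations < 1:
            raise ValueError("sampling_rate must be positive and n_fixations >= 1")
        if self.fixation_duration_ms[0] <= 0 or self.saccade_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if self.saccade_duration_ms >= self.fixation_duration_ms[0]:
            raise ValueError(
                "saccade_duration_ms must be shorter than the shortest fixation"
            )
        if self.noise_rms < 0 or self.gap_rate_hz < 0 or self.single_eye_rate_hz < 0:
            raise ValueError("rates and noise_rms must be non-negative")


@dataclass(frozen=True)
class TrueSegment:
    label: str  # fixation | saccade | pursuit
    onset: float  # ms, half-open
    offset: float
    start: int  # sample indices, half-open
    stop: int
    centroid_x_deg: float = float("nan")  # fixations only
    centroid_y_deg: float = float("nan")


@dataclass
class GroundTruthEvents:
    """True oculomotor segmentation plus the injected data-quality defects."""

    segments: list
    sampling_rate: float
    gaps: list = field(default_factory=list)  # (start, stop) sample ranges
    single_eye: list = field(default_factory=list)  # (start, stop, "left"|"right")

    @property
    def fixations(self) -> list:
        return [s for s in self.segments if s.label == "fixation"]

    @property
    def n_samples(self) -> int:
        return self.segments[-1].stop if self.segments else 0

    def sample_labels(self) -> np.ndarray:
        """Per-sample labels with injected gaps overlaid on the true events."""
        out = np.empty(self.n_samples, dtype=object)
        for s in self.segments:
            out[s.start: s.stop] = s.label
        for start, stop in self.gaps:
            out[start:stop] = "gap"
        return out


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _next_target(rng, pos_px, amp_px, bounds, margin=100.0):
    """Pick a saccade landing point at the given amplitude inside the screen."""
    for _ in range(200):
        theta = rng.uniform(0, 2 * math.pi)
        cand = pos_px + amp_px * np.array([math.cos(theta), math.sin(theta)])
        if (margin <= cand[0] <= bounds[0] - margin
                and margin <= cand[1] <= bounds[1] - margin):
            return cand
    # fall back: jump toward the screen centre
    centre = np.array([bounds[0] / 2, bounds[1] / 2])
    direction = centre - pos_px
    direction /= max(np.linalg.norm(direction), 1e-9)
    return pos_px + amp_px * direction


def simulate_recording(params: SimulationParams) -> tuple[GazeRecording, GroundTruthEvents]:
    """Render the event plan into a binocular recording with ground truth.

    Fixations hold a constant position, saccades follow a minimum-jerk
    displacement profile, pursuits are constant-velocity ramps. Per-eye
    i.i.d. Gaussian jitter is calibrated to ``noise_rms`` (see module
    docstring); gaps invalidate both eyes and single-eye episodes one.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    dt = 1000.0 / fs
    dpp = params.degrees_per_pixel
    bounds = params.screen_bounds

    # --- event plan in whole samples -------------------------------------
    n_sac = max(1, int(round(params.saccade_duration_ms / dt)))
    n_pur = max(1, int(round(params.pursuit_duration_ms / dt)))
    plan = []  # (label, n_samples)
    pursuit_slots = set()
    if params.n_pursuits:
        slots = rng.choice(params.n_fixations - 1, size=min(params.n_pursuits,
                           params.n_fixations - 1), replace=False) if params.n_fixations > 1 else []
        pursuit_slots = set(int(s) for s in np.atleast_1d(slots))
    for i in range(params.n_fixations):
        dur = rng.uniform(*params.fixation_duration_ms)
        plan.append(("fixation", max(2, int(round(dur / dt)))))
        if i < params.n_fixations - 1:
            plan.append(("saccade", n_sac))
            if i in pursuit_slots:
                plan.append(("pursuit", n_pur))
                plan.append(("saccade", n_sac))

    n = sum(k for _, k in plan)
    timestamps = np.arange(n) * dt
    pos = np.empty((n, 2))
    segments = []

    cur = np.array([bounds[0] / 2.0, bounds[1] / 2.0])
    idx = 0
    for label, k in plan:
        sl = slice(idx, idx + k)
        if label == "fixation":
            pos[sl] = cur
            segments.append(TrueSegment(
                label="fixation", onset=idx * dt, offset=(idx + k) * dt,
                start=idx, stop=idx + k,
                centroid_x_deg=cur[0] * dpp, centroid_y_deg=cur[1] * dpp,
            ))
        elif label == "saccade":
            amp_deg = rng.uniform(*params.saccade_amplitude_deg)
            target = _next_target(rng, cur, amp_deg / dpp, bounds)
            tau = (np.arange(k) + 1.0) / (k + 1.0)
            pos[sl] = cur + np.outer(_min_jerk(tau), target - cur)
            segments.append(TrueSegment(
                label="saccade", onset=idx * dt, offset=(idx + k) * dt,
                start=idx, stop=idx + k,
            ))
            cur = target
        else:  # pursuit
            theta = rng.uniform(0, 2 * math.pi)
            v_px = params.pursuit_velocity_deg_s / dpp / 1000.0  # px per ms
            step = v_px * dt * np.array([math.cos(theta), math.sin(theta)])
            ramp = cur + np.outer(np.arange(1, k + 1), step)
            ramp[:, 0] = np.clip(ramp[:, 0], 50, bounds[0] - 50)
            ramp[:, 1] = np.clip(ramp[:, 1], 50, bounds[1] - 50)
            pos[sl] = ramp
            segments.append(TrueSegment(
                label="pursuit", onset=idx * dt, offset=(idx + k) * dt,
                start=idx, stop=idx + k,
            ))
            cur = ramp[-1].copy()
        idx += k

    # --- render the two eyes ---------------------------------------------
    sigma_px = (params.noise_rms / math.sqrt(2.0)) / dpp
    verg_px = 0.5 * params.vergence_offset_deg / dpp
    left = pos + rng.normal(0.0, sigma_px, size=(n, 2)) if sigma_px else pos.copy()
    right = pos + rng.normal(0.0, sigma_px, size=(n, 2)) if sigma_px else pos.copy()
    left[:, 0] -= verg_px
    right[:, 0] += verg_px

    left_valid = np.ones(n, dtype=bool)
    right_valid = np.ones(n, dtype=bool)
    total_s = n * dt / 1000.0

    gaps = []
    for _ in range(rng.poisson(params.gap_rate_hz * total_s)):
        length = max(1, int(round(rng.uniform(*params.gap_length_ms) / dt)))
        start = int(rng.integers(0, max(1, n - length)))
        left_valid[start:start + length] = False
        right_valid[start:start + length] = False
        gaps.append((start, start + length))

    single_eye = []
    for _ in range(rng.poisson(params.single_eye_rate_hz * total_s)):
        length = max(1, int(round(params.single_eye_duration_ms / dt)))
        start = int(rng.integers(0, max(1, n - length)))
        eye = "left" if rng.random() < 0.5 else "right"
        (left_valid if eye == "left" else right_valid)[start:start + length] = False
        single_eye.append((start, start + length, eye))

    pupil = 3.0 + 0.3 * np.sin(2 * math.pi * timestamps / 4000.0)
    rec = GazeRecording(
        sampling_rate=fs,
        timestamps=timestamps,
        left_x=left[:, 0], left_y=left[:, 1],
        right_x=right[:, 0], right_y=right[:, 1],
        left_valid=left_valid, right_valid=right_valid,
        pupil_left=pupil.copy(), pupil_right=pupil.copy(),
    )
    truth = GroundTruthEvents(
        segments=segments, sampling_rate=fs, gaps=sorted(gaps),
        single_eye=single_eye,
    )
    return rec, truth


def inject_fixation_gaps(
    rec: GazeRecording,
    truth: GroundTruthEvents,
    fraction: float = 0.3,
    gap_ms: float = 40.0,
    seed: int = 0,
) -> tuple[GazeRecording, list]:
    """Knock out a both-eye gap centred in a random fraction of true fixations.

    Returns a modified copy of the recording and the injected sample ranges.
    Only fixations long enough to keep at least two samples on each side of
    the gap are eligible.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / rec.sampling_rate
    n_gap = max(1, int(round(gap_ms / dt)))
    eligible = [f for f in truth.fixations if f.stop - f.start >= n_gap + 4]
    k = int(round(fraction * len(truth.fixations)))
    if k > len(eligible):
        raise ValueError("not enough long fixations to inject the requested gaps")
    chosen = rng.choice(len(eligible), size=k, replace=False)
    out = rec.copy()
    ranges = []
    for i in sorted(int(c) for c in chosen):
        f = eligible[i]
        mid = (f.start + f.stop) // 2
        start = mid - n_gap // 2
        out.left_valid[start:start + n_gap] = False
        out.right_valid[start:start + n_gap] = False
        out.left_x[start:start + n_gap] = np.nan
        out.left_y[start:start + n_gap] = np.nan
        out.right_x[start:start + n_gap] = np.nan
        out.right_y[start:start + n_gap] = np.nan
        ranges.append((start, start + n_gap))
    return out, ranges


@dataclass(frozen=True)
class RecoveryReport:
    n_true: int
    n_detected: int
    n_matched: int
    hit_rate: float
    false_detection_rate: float
    mean_onset_error_ms: float
    mean_offset_error_ms: float
    duration_ratio: float  # mean detected/true duration over matched pairs

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _intervals(events) -> list:
    out = []
    for e in events:
        if hasattr(e, "onset"):
            if getattr(e, "label", "fixation") != "fixation":
                continue
            out.append((float(e.onset), float(e.offset)))
        else:
            out.append((float(e[0]), float(e[1])))
    return out


def score_recovery(detected, truth, tolerance_ms: float | None = None) -> RecoveryReport:
    """Greedy one-to-one matching of detected to true fixations by overlap.

    Candidate pairs with positive temporal overlap are matched in decreasing
    overlap order; with ``tolerance_ms`` set, a match additionally requires
    both boundary errors within the tolerance. Hit rate is matched/true,
    false-detection rate is unmatched-detected/detected.
    """
    from .posthoc import FixationSet

    if isinstance(detected, FixationSet):
        detected = detected.surviving
    det = _intervals(detected)
    tru = _intervals(truth.fixations if isinstance(truth, GroundTruthEvents) else truth)

    pairs = []
    for i, (to, tf) in enumerate(tru):
        for j, (do, df) in enumerate(det):
            overlap = min(tf, df) - max(to, do)
            if overlap > 0:
                pairs.append((overlap, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_d = set(), set()
    matches = []
    for overlap, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        onset_err = abs(det[j][0] - tru[i][0])
        offset_err = abs(det[j][1] - tru[i][1])
        if tolerance_ms is not None and (onset_err > tolerance_ms or offset_err > tolerance_ms):
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j, onset_err, offset_err))

    n_matched = len(matches)
    onset_errs = [m[2] for m in matches]
    offset_errs = [m[3] for m in matches]
    ratios = [
        (det[j][1] - det[j][0]) / (tru[i][1] - tru[i][0]) for i, j, _, _ in matches
    ]
    return RecoveryReport(
        n_true=len(tru),
        n_detected=len(det),
        n_matched=n_matched,
        hit_rate=n_matched / len(tru) if tru else 0.0,
        false_detection_rate=(len(det) - n_matched) / len(det) if det else 0.0,
        mean_onset_error_ms=float(np.mean(onset_errs)) if onset_errs else 0.0,
        mean_offset_error_ms=float(np.mean(offset_errs)) if offset_errs else 0.0,
        duration_ratio=float(np.mean(ratios)) if ratios else 0.0,
    )
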