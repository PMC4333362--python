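"""Reading and writing gaze sample tables, fixation tables, and parameter configs.

Unit conventions owned here and used throughout the package:

* time is milliseconds, positions are screen pixels;
* all thresholds are expressed in the units users know them by
  (degrees, degrees/second, milliseconds);
* pixels are converted to degrees only through the single isotropic
  ``degrees_per_pixel`` scalar;
* event intervals are half-open ``[onset, offset)`` so that
  ``duration == offset - onset`` and consecutive events tile the timeline;
* missing coordinates are NaN, never sentinel values.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gazefix")

__all__ = [
    "GazeDataError",
    "SchemaError",
    "ParamError",
    "GazeRecording",
    "DetectionParams",
    "PRESETS",
    "DEFAULT_SCHEMA",
    "read_gaze",
    "write_gaze",
    "load_params",
    "load_schema",
    "write_fixations",
    "read_fixations",
    "FIXATION_COLUMNS",
]


class GazeDataError(ValueError):
    """Raised for structurally invalid gaze data (empty table, bad timestamps...)."""


class SchemaError(GazeDataError):
    """Raised when a column mapping does not match the file being read."""


class ParamError(ValueError):
    """Raised for missing or out-of-range detection parameters."""


# --------------------------------------------------------------------------
# Raw recordings
# --------------------------------------------------------------------------

#: Default column mapping for raw sample tables. Users may override any entry
#: with a schema config; validity and pupil columns are optional.
DEFAULT_SCHEMA: dict[str, str] = {
    "timestamp": "timestamp",
    "left_x": "left_x",
    "left_y": "left_y",
    "right_x": "right_x",
    "right_y": "right_y",
    "left_valid": "left_valid",
    "right_valid": "right_valid",
    "pupil_left": "pupil_left",
    "pupil_right": "pupil_right",
}

_REQUIRED_FIELDS = ("timestamp", "left_x", "left_y", "right_x", "right_y")


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=float)


@dataclass
class GazeRecording:
    """Raw binocular gaze samples with per-eye validity and optional pupil size.

    Coordinates of samples whose validity flag is false are forced to NaN on
    construction, so downstream code only ever needs to look at the
    coordinates (``left_valid`` / ``right_valid`` stay consistent with them).
    """

    sampling_rate: float
    timestamps: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    left_valid: np.ndarray | None = None
    right_valid: np.ndarray | None = None
    pupil_left: np.ndarray | None = None
    pupil_right: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise GazeDataError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.timestamps = _as_float(self.timestamps)
        n = self.timestamps.size
        if n < 2:
            raise GazeDataError(f"recording needs at least 2 samples, got {n}")
        if not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise GazeDataError(f"timestamps not strictly increasing at row {bad}")
        for name in ("left_x", "left_y", "right_x", "right_y"):
            arr = _as_float(getattr(self, name))
            if arr.shape != (n,):
                raise GazeDataError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        for side in ("left", "right"):
            valid = getattr(self, f"{side}_valid")
            x, y = getattr(self, f"{side}_x"), getattr(self, f"{side}_y")
            finite = np.isfinite(x) & np.isfinite(y)
            if valid is None:
                valid = finite
            else:
                valid = np.asarray(valid, dtype=bool) & finite
            x[~valid] = np.nan
            y[~valid] = np.nan
            setattr(self, f"{side}_valid", valid)
        for name in ("pupil_left", "pupil_right"):
            p = getattr(self, name)
            if p is not None:
                p = _as_float(p)
                if p.shape != (n,):
                    raise GazeDataError(f"{name} has shape {p.shape}, expected ({n},)")
                setattr(self, name, p)

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration_ms(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0] + 1000.0 / self.sampling_rate)

    def copy(self) -> "GazeRecording":
        kw = {
            f.name: (None if getattr(self, f.name) is None
                     else np.array(getattr(self, f.name)))
            for f in dataclasses.fields(self)
            if f.name != "sampling_rate"
        }
        return GazeRecording(sampling_rate=self.sampling_rate, **kw)


def load_schema(source: str | Path | Mapping | None) -> dict:
    """Resolve a column-mapping config (path, mapping, or None for defaults)."""
    if source is None:
        return dict(DEFAULT_SCHEMA)
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise SchemaError(f"schema file {source} does not contain a mapping")
    schema = dict(DEFAULT_SCHEMA)
    sentinels = raw.pop("missing_values", None)
    unknown = set(raw) - set(DEFAULT_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
    schema.update({k: v for k, v in raw.items() if v is not None})
    for k, v in raw.items():
        if v is None:
            schema[k] = None
    if sentinels is not None:
        schema["missing_values"] = list(sentinels)
    return schema


def read_gaze(
    path: str | Path,
    schema: str | Path | Mapping | None = None,
    sampling_rate: float = 120.0,
) -> GazeRecording:
    """Read a delimited raw sample table into a :class:`GazeRecording`.

    ``schema`` maps logical field names (see :data:`DEFAULT_SCHEMA`) to column
    names in the file; a ``missing_values`` list in the schema declares vendor
    sentinel coordinates (e.g. ``-1``) that are mapped to missing. Rows whose
    coordinates do not parse as numbers become missing samples and are counted
    in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gaze file not found: {path}")
    schema = load_schema(schema)
    sentinels = schema.pop("missing_values", [])
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise GazeDataError(f"empty sample table: {path}")

    missing_cols = [
        schema[f] for f in _REQUIRED_FIELDS if schema.get(f) not in df.columns
    ]
    if missing_cols:
        raise SchemaError(
            f"columns missing from {path.name}: {missing_cols} "
            f"(available: {list(df.columns)})"
        )

    def numeric(fieldname: str, required: bool) -> np.ndarray | None:
        col = schema.get(fieldname)
        if col is None or col not in df.columns:
            if required:
                raise SchemaError(f"column for '{fieldname}' not found: {col}")
            return None
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        for s in sentinels:
            vals[vals == s] = np.nan
        return vals

    ts = numeric("timestamp", required=True)
    if np.isnan(ts).any():
        raise GazeDataError(f"unparseable timestamps in {path.name}")
    coords = {f: numeric(f, required=True) for f in _REQUIRED_FIELDS[1:]}
    n_unparseable = int(sum(np.isnan(c).sum() for c in coords.values()))
    if n_unparseable:
        logger.info("read_gaze: %d coordinate values unparseable or sentinel in %s",
                    n_unparseable, path.name)

    def validity(fieldname: str) -> np.ndarray | None:
        col = schema.get(fieldname)
        if col is None or col not in df.columns:
            return None
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        return np.nan_to_num(vals, nan=0.0) > 0

    return GazeRecording(
        sampling_rate=sampling_rate,
        timestamps=ts,
        left_x=coords["left_x"],
        left_y=coords["left_y"],
        right_x=coords["right_x"],
        right_y=coords["right_y"],
        left_valid=validity("left_valid"),
        right_valid=validity("right_valid"),
        pupil_left=numeric("pupil_left", required=False),
        pupil_right=numeric("pupil_right", required=False),
    )


def write_gaze(rec: GazeRecording, path: str | Path) -> None:
    """Write a recording as CSV using the default column names (round-trips
    with :func:`read_gaze` under the default schema)."""
    data = {
        "timestamp": rec.timestamps,
        "left_x": rec.left_x,
        "left_y": rec.left_y,
        "right_x": rec.right_x,
        "right_y": rec.right_y,
        "left_valid": rec.left_valid.astype(int),
        "right_valid": rec.right_valid.astype(int),
    }
    if rec.pupil_left is not None:
        data["pupil_left"] = rec.pupil_left
    if rec.pupil_right is not None:
        data["pupil_right"] = rec.pupil_right
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# Detection parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionParams:
    """All thresholds driving detection and post-hoc validation.

    ``interpolation_latency`` may be 0 to disable gap interpolation; every
    other threshold must be strictly positive. A ``merge_max_distance`` above
    0.45 deg risks merging across real short saccades and triggers a warning.
    """

    interpolation_latency: float  # ms; longest gap that may be filled
    velocity_threshold: float  # deg/s
    max_interpolation_displacement: float  # deg between flanking centroids
    degrees_per_pixel: float  # isotropic deg/pixel
    merge_max_distance: float  # deg
    merge_max_gap: float  # ms
    max_rms_per_fixation: float  # deg
    min_fixation_duration: float  # ms
    include_single_eye: bool = True

    def __post_init__(self) -> None:
        bad = []
        if self.interpolation_latency < 0:
            bad.append("interpolation_latency")
        for name in (
            "velocity_threshold",
            "max_interpolation_displacement",
            "degrees_per_pixel",
            "merge_max_distance",
            "merge_max_gap",
            "max_rms_per_fixation",
            "min_fixation_duration",
        ):
            if not getattr(self, name) > 0:
                bad.append(name)
        if bad:
            raise ParamError(f"non-positive detection parameters: {bad}")
        if self.merge_max_distance > 0.45:
            warnings.warn(
                "merge_max_distance > 0.45 deg may merge fixations across "
                "real short saccades",
                UserWarning,
                stacklevel=2,
            )

    def replace(self, **changes) -> "DetectionParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Shipped parameter presets for high- and low-spatial-precision recordings.
PRESETS: dict[str, DetectionParams] = {
    "high_precision": DetectionParams(
        interpolation_latency=60.0,
        velocity_threshold=9.0,
        max_interpolation_displacement=0.25,
        degrees_per_pixel=0.0177,
        merge_max_distance=0.24,
        merge_max_gap=50.0,
        max_rms_per_fixation=0.24,
        min_fixation_duration=99.0,
        include_single_eye=True,
    ),
    "low_precision": DetectionParams(
        interpolation_latency=60.0,
        velocity_threshold=20.0,
        max_interpolation_displacement=0.25,
        degrees_per_pixel=0.0177,
        merge_max_distance=0.35,
        merge_max_gap=50.0,
        max_rms_per_fixation=0.21,
        min_fixation_duration=120.0,
        include_single_eye=True,
    ),
}

_PARAM_KEYS = {f.name for f in dataclasses.fields(DetectionParams)}


def load_params(source: str | Path | Mapping | None) -> DetectionParams:
    """Load detection parameters from a YAML/JSON config, mapping, or preset.

    The config either names a ``preset`` (``high_precision`` /
    ``low_precision``), optionally overriding individual keys, or declares
    every threshold explicitly. ``source`` may also be a preset name directly.
    """
    if source is None:
        return PRESETS["high_precision"]
    if isinstance(source, DetectionParams):
        return source
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ParamError(f"params file {source} does not contain a mapping")
        raw = dict(raw)
    raw.pop("smoothing", None)  # handled by preprocessing.load_smoothing
    preset = raw.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ParamError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        base = PRESETS[preset].to_dict()
        base.update(raw)
        raw = base
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ParamError(f"unknown parameter keys: {sorted(unknown)}")
    missing = _PARAM_KEYS - set(raw) - {"include_single_eye"}
    if missing:
        raise ParamError(f"missing parameter keys: {sorted(missing)}")
    return DetectionParams(**raw)


# --------------------------------------------------------------------------
# Fixation tables
# --------------------------------------------------------------------------

FIXATION_COLUMNS = [
    "fixation_id",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "centroid_x_px",
    "centroid_y_px",
    "centroid_x_deg",
    "centroid_y_deg",
    "rms_deg",
    "n_samples",
    "n_interpolated",
    "merged",
    "rms_rejected",
    "duration_rejected",
    "single_eye_fraction",
    "pupil_mean",
    "label",
]


def write_fixations(fixations, path: str | Path, include_rejected: bool = False) -> None:
    """Serialize a FixationSet (or a plain fixation list) to CSV.

    Integer fields round-trip bit-exactly; reals to 6 printed decimals.
    """
    from .posthoc import FixationSet  # local import to avoid a cycle

    if isinstance(fixations, FixationSet):
        rows = list(fixations.rejected if include_rejected else fixations.surviving)
    else:
        rows = list(fixations)
    records = []
    for i, f in enumerate(rows):
        records.append(
            {
                "fixation_id": i,
                "onset_ms": f.onset,
                "offset_ms": f.offset,
                "duration_ms": f.duration,
                "centroid_x_px": f.centroid_x,
                "centroid_y_px": f.centroid_y,
                "centroid_x_deg": f.centroid_x_deg,
                "centroid_y_deg": f.centroid_y_deg,
                "rms_deg": f.rms,
                "n_samples": f.n_samples,
                "n_interpolated": f.n_interpolated,
                "merged": int("merged" in f.flags),
                "rms_rejected": int("rejected_rms" in f.flags),
                "duration_rejected": int("rejected_duration" in f.flags),
                "single_eye_fraction": f.single_eye_fraction,
                "pupil_mean": f.pupil_mean,
                "label": f.label,
            }
        )
    df = pd.DataFrame.from_records(records, columns=FIXATION_COLUMNS)
    float_cols = [
        "onset_ms", "offset_ms", "duration_ms", "centroid_x_px",
        "centroid_y_px", "centroid_x_deg", "centroid_y_deg", "rms_deg",
        "single_eye_fraction", "pupil_mean",
    ]
    df[float_cols] = df[float_cols].astype(float)
    df.to_csv(path, index=False, float_format="%.6f")


def read_fixations(path: str | Path):
    """Read a fixation CSV written by :func:`write_fixations`."""
    from .posthoc import Fixation

    df = pd.read_csv(path)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fixation table missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        flags = set()
        if r["merged"]:
            flags.add("merged")
        if r["rms_rejected"]:
            flags.add("rejected_rms")
        if r["duration_rejected"]:
            flags.add("rejected_duration")
        out.append(
            Fixation(
                onset=float(r["onset_ms"]),
                offset=float(r["offset_ms"]),
                centroid_x=float(r["centroid_x_px"]),
                centroid_y=float(r["centroid_y_px"]),
                centroid_x_deg=float(r["centroid_x_deg"]),
                centroid_y_deg=float(r["centroid_y_deg"]),
                rms=float(r["rms_deg"]),
                n_samples=int(r["n_samples"]),
                n_interpolated=int(r["n_interpolated"]),
                single_eye_fraction=float(r["single_eye_fraction"]),
                pupil_mean=float(r["pupil_mean"]) if pd.notna(r["pupil_mean"]) else None,
                flags=flags,
                label=str(r["label"]),
            )
        )
    return out
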