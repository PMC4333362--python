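import numpy as np
import pytest

from gazefix import GazeRecording, PRESETS, SmoothedTrace

DPP = 0.0177
FS = 120.0
DT = 1000.0 / FS


def make_recording(
    left_x,
    left_y,
    right_x=None,
    right_y=None,
    fs=FS,
    left_valid=None,
    right_valid=None,
    pupil=False,
):
    """Binocular recording from coordinate arrays (right defaults to left)."""
    left_x = np.asarray(left_x, dtype=float)
    left_y = np.asarray(left_y, dtype=float)
    right_x = left_x.copy() if right_x is None else np.asarray(right_x, dtype=float)
    right_y = left_y.copy() if right_y is None else np.asarray(right_y, dtype=float)
    n = left_x.size
    kw = {}
    if pupil:
        kw["pupil_left"] = np.full(n, 3.0)
        kw["pupil_right"] = np.full(n, 3.2)
    return GazeRecording(
        sampling_rate=fs,
        timestamps=np.arange(n) * (1000.0 / fs),
        left_x=left_x,
        left_y=left_y,
        right_x=right_x,
        right_y=right_y,
        left_valid=left_valid,
        right_valid=right_valid,
        **kw,
    )


def make_trace(x, y=None, fs=FS, available=None):
    """Combined trace directly (bypassing eye averaging)."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    n = x.size
    if available is None:
        available = np.isfinite(x) & np.isfinite(y)
    else:
        available = np.asarray(available, dtype=bool)
    x = np.where(available, x, np.nan)
    y = np.where(available, y, np.nan)
    return SmoothedTrace(
        timestamps=np.arange(n) * (1000.0 / fs),
        x=x,
        y=y,
        available=available,
        single_eye=np.zeros(n, dtype=bool),
        interpolated=np.zeros(n, dtype=bool),
        sampling_rate=fs,
    )


@pytest.fixture
def high_params():
    return PRESETS["high_precision"]


@pytest.fixture
def low_params():
    return PRESETS["low_precision"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
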