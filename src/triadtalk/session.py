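"""Domain types and file I/O for triadic conversation sessions.

A session is one participant conversing with two remote confederates
(the *experimenter* and the *confederate*) under a 2 (background noise)
x 4 (avatar head-movement animation) repeated-measures design.  Per
condition the raw material is: one short-term sound-level trace per
interlocutor (dB SPL), one head-motion trace for the participant
(yaw/pitch/roll in degrees, position in metres, nominally 100 Hz), and
one 10-item questionnaire response.

Coordinate conventions
----------------------
Yaw is in degrees, wrapped to (-180, 180], with 0 deg at the midline
between the two avatars and positive toward the experimenter avatar.
The avatars sit at +/-30 deg by default (three seats at equal ~1.12 m
distance form an equilateral triangle, i.e. a 60 deg subtense).
Head translation is measured as the signed displacement along
``screen_axis`` (unit vector toward the centre between the avatars,
+z by default); positive values mean leaning in toward the screen.
Time is in seconds from condition start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANIMATION_LEVELS = ("static", "automatic", "transmitted", "video")
NOISE_LEVELS = ("quiet", "noise")

#: Short labels accepted on read (paper-style abbreviations).
_ANIMATION_ALIASES = {
    "stat": "static",
    "static": "static",
    "auto": "automatic",
    "autom": "automatic",
    "automatic": "automatic",
    "trans": "transmitted",
    "transm": "transmitted",
    "transmitted": "transmitted",
    "video": "video",
}

SPEAKERS = ("participant", "experimenter", "confederate")
CONFEDERATES = ("experimenter", "confederate")


def wrap_angle(deg):
    """Wrap angles in degrees to the interval (-180, 180]."""
    deg = np.asarray(deg, dtype=float)
    wrapped = -((-deg + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 2 x 4 design (animation level x noise level)."""

    animation: str
    noise: str

    def __post_init__(self):
        anim = _ANIMATION_ALIASES.get(str(self.animation).strip().lower())
        if anim is None:
            raise ValueError(
                f"unknown animation level {self.animation!r}; "
                f"expected one of {ANIMATION_LEVELS}"
            )
        noise = str(self.noise).strip().lower()
        if noise not in NOISE_LEVELS:
            raise ValueError(
                f"unknown noise level {self.noise!r}; expected one of {NOISE_LEVELS}"
            )
        object.__setattr__(self, "animation", anim)
        object.__setattr__(self, "noise", noise)

    @property
    def label(self) -> str:
        return f"{self.animation}_{self.noise}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        anim, _, noise = str(label).strip().partition("_")
        return cls(anim, noise)


def all_conditions() -> list[Condition]:
    """The eight cells of the factorial design, in canonical order."""
    return [Condition(a, n) for n in NOISE_LEVELS for a in ANIMATION_LEVELS]


def _validate_times(times: np.ndarray, what: str) -> None:
    if times.ndim != 1:
        raise ValueError(f"{what}: times must be 1-D")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{what}: non-monotone times")


@dataclass
class LevelTrace:
    """Time-aligned short-term sound levels (dB SPL) for one interlocutor."""

    speaker_id: str
    times: np.ndarray
    levels: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        _validate_times(self.times, f"LevelTrace({self.speaker_id})")
        if len(self.times) != len(self.levels):
            raise ValueError("times and levels must have equal length")
        if not np.all(np.isfinite(self.levels)):
            bad = int(np.flatnonzero(~np.isfinite(self.levels))[0])
            raise ValueError(
                f"LevelTrace({self.speaker_id}): non-finite level at row {bad}"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Length of the covered span, counting the last sample's block."""
        return float(self.times[-1] - self.times[0] + self.dt) if len(self) else 0.0

    def replace_levels(self, levels: np.ndarray) -> "LevelTrace":
        return LevelTrace(self.speaker_id, self.times.copy(), levels, self.sample_rate)


@dataclass
class MotionTrace:
    """Participant head motion: yaw/pitch/roll (deg) and position (m)."""

    times: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self):
        for name in ("times", "yaw", "pitch", "roll", "x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        _validate_times(self.times, "MotionTrace")
        n = len(self.times)
        for name in ("yaw", "pitch", "roll", "x", "y", "z"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MotionTrace: {name} length mismatch")
        self.yaw = wrap_angle(self.yaw)
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def position(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class SceneGeometry:
    """Avatar placement as seen from the participant's seat.

    ``avatar_yaw`` holds the seat angle of each avatar; ``avatar_face_ref``
    the yaw toward the reference point on the avatar's face (between eyes
    and mouth), which coincides with the seat angle unless calibrated
    otherwise.  ``screen_axis`` is the unit direction toward the centre
    between the two avatars, used for the lean-in (translation) measure.
    """

    avatar_yaw: dict = field(
        default_factory=lambda: {"experimenter": 30.0, "confederate": -30.0}
    )
    avatar_face_ref: dict | None = None
    screen_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self):
        if self.avatar_face_ref is None:
            self.avatar_face_ref = dict(self.avatar_yaw)
        self.screen_axis = np.asarray(self.screen_axis, dtype=float)
        norm = np.linalg.norm(self.screen_axis)
        if norm == 0:
            raise ValueError("screen_axis must be non-zero")
        self.screen_axis = self.screen_axis / norm
        yaws = list(self.avatar_yaw.values())
        if len(yaws) != 2 or np.isclose(wrap_angle(yaws[0] - yaws[1]), 0.0):
            raise ValueError("the two avatar yaw angles must differ")


@dataclass
class QuestionnaireResponse:
    """One 10-item rating (7-point scale, -3..+3 in 0.5 steps)."""

    values: dict

    ITEMS = tuple(f"q{i}" for i in range(1, 11))

    def __post_init__(self):
        vals = {}
        for item in self.ITEMS:
            if item not in self.values:
                raise ValueError(f"missing questionnaire item {item}")
            v = float(self.values[item])
            if not (-3.0 <= v <= 3.0) or abs(v * 2 - round(v * 2)) > 1e-9:
                raise ValueError(
                    f"item {item}: value {v} not on the 0.5 grid within [-3, 3]"
                )
            vals[item] = v
        self.values = vals

    def as_array(self) -> np.ndarray:
        return np.array([self.values[i] for i in self.ITEMS])


@dataclass
class ConditionRecord:
    """All streams recorded for one participant x condition."""

    levels: dict = field(default_factory=dict)  # speaker -> LevelTrace
    motion: MotionTrace | None = None
    ratings: QuestionnaireResponse | None = None
    missing_reason: str | None = None

    @property
    def complete(self) -> bool:
        return (
            self.missing_reason is None
            and all(s in self.levels for s in SPEAKERS)
            and self.motion is not None
            and self.ratings is not None
        )


@dataclass
class SessionData:
    """One participant's full session: eight conditions plus their order."""

    participant_id: str
    conditions: dict = field(default_factory=dict)  # Condition -> ConditionRecord
    condition_order: list = field(default_factory=list)
    geometry: SceneGeometry = field(default_factory=SceneGeometry)

    def record(self, condition: Condition) -> ConditionRecord:
        return self.conditions.setdefault(condition, ConditionRecord())


# ---------------------------------------------------------------------------
# Measure table
# ---------------------------------------------------------------------------

MEASURE_COLUMNS = [
    "participant",
    "animation",
    "noise",
    "measure",
    "value",
    "n_used",
    "excluded",
    "reason",
]


class MeasureTable:
    """One value per participant x condition x measure, with exclusions.

    Thin wrapper around a pandas DataFrame; ``df`` is the canonical
    representation with columns ``participant, animation, noise, measure,
    value, n_used, excluded, reason``.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=MEASURE_COLUMNS)
        self.df = df.reset_index(drop=True)[MEASURE_COLUMNS]

    def add(self, participant, condition: Condition, measure, value,
            n_used=0, excluded=False, reason=""):
        row = {
            "participant": participant,
            "animation": condition.animation,
            "noise": condition.noise,
            "measure": measure,
            "value": float(value) if np.isfinite(value) else np.nan,
            "n_used": int(n_used),
            "excluded": bool(excluded) or not np.isfinite(value),
            "reason": reason,
        }
        new = pd.DataFrame([row])
        self.df = new if self.df.empty else pd.concat(
            [self.df, new], ignore_index=True)

    def slice(self, measure: str, include_excluded: bool = False) -> pd.DataFrame:
        out = self.df[self.df["measure"] == measure]
        if not include_excluded:
            out = out[~out["excluded"].astype(bool)]
        return out.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MeasureTable":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False,
                               na_values=[""], dtype={"reason": str}))

    def concat(self, other: "MeasureTable") -> "MeasureTable":
        frames = [df for df in (self.df, other.df) if not df.empty]
        if not frames:
            return MeasureTable()
        return MeasureTable(pd.concat(frames, ignore_index=True))


def subtract_participant_median(df: pd.DataFrame, value_col: str = "value"
                                ) -> pd.DataFrame:
    """Reference each value to the participant's median over all conditions.

    Mirrors the per-individual baseline used for the behavioral figures
    (values referenced to the individual median across the eight
    conditions).  Operates per participant x measure; excluded rows do not
    contribute to the median.
    """
    out = df.copy()
    med = out.groupby(["participant", "measure"])[value_col].transform("median")
    out[value_col] = out[value_col] - med
    return out


# ---------------------------------------------------------------------------
# Trace I/O (delimited text with header)
# ---------------------------------------------------------------------------

def _infer_rate(times: np.ndarray) -> float:
    if len(times) < 2:
        return 1.0
    _validate_times(times, "trace")
    return 1.0 / float(np.median(np.diff(times)))


def read_level_trace(path, speaker_id: str) -> LevelTrace:
    """Read a level trace CSV with columns ``time_s, level_db``."""
    df = pd.read_csv(path)
    for col in ("time_s", "level_db"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = df["time_s"].to_numpy(dtype=float)
    levels = df["level_db"].to_numpy(dtype=float)
    if np.isnan(levels).any():
        bad = int(np.flatnonzero(np.isnan(levels))[0])
        raise ValueError(f"{path}: NaN level at row {bad}")
    return LevelTrace(speaker_id, times, levels, _infer_rate(times))


def write_level_trace(trace: LevelTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "level_db": trace.levels}).to_csv(
        path, index=False, float_format="%.9f"
    )


_MOTION_COLS = ["time_s", "yaw_deg", "pitch_deg", "roll_deg", "x_m", "y_m", "z_m"]


def read_motion_trace(path) -> MotionTrace:
    """Read a motion trace CSV with header ``time_s, yaw_deg, ..., z_m``."""
    df = pd.read_csv(path)
    for col in _MOTION_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = df["time_s"].to_numpy(dtype=float)
    return MotionTrace(
        times,
        df["yaw_deg"].to_numpy(float),
        df["pitch_deg"].to_numpy(float),
        df["roll_deg"].to_numpy(float),
        df["x_m"].to_numpy(float),
        df["y_m"].to_numpy(float),
        df["z_m"].to_numpy(float),
        _infer_rate(times),
    )


def write_motion_trace(trace: MotionTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "yaw_deg": trace.yaw,
        "pitch_deg": trace.pitch,
        "roll_deg": trace.roll,
        "x_m": trace.x,
        "y_m": trace.y,
        "z_m": trace.z,
    }).to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Short-term levels from PCM audio
# ---------------------------------------------------------------------------

def short_term_levels(audio, sample_rate: float, block_len: float = 0.0058,
                      calibration_offset: float = 0.0,
                      silence_floor_db: float = -120.0,
                      speaker_id: str = "audio") -> LevelTrace:
    """Block-wise mean-square levels of a mono PCM stream, in dB.

    One level per non-overlapping block of ``block_len`` seconds (default
    5.8 ms, the audio block length of the telepresence renderer):
    ``10*log10(mean(x**2)) + calibration_offset``.  A fully silent block
    maps to ``silence_floor_db``.  Trailing partial blocks are dropped.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError(
            "multi-channel audio: select one channel (e.g. audio[:, 0]) "
            "before computing levels"
        )
    if block_len <= 0:
        raise ValueError("block_len must be positive")
    nblock = int(round(block_len * sample_rate))
    if nblock < 1:
        raise ValueError("block_len shorter than one sample")
    nblocks = len(audio) // nblock
    blocks = audio[: nblocks * nblock].reshape(nblocks, nblock)
    ms = np.mean(blocks ** 2, axis=1)
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(ms) + calibration_offset
    levels[ms <= 0] = silence_floor_db
    rate = sample_rate / nblock
    times = np.arange(nblocks) / rate
    return LevelTrace(speaker_id, times, levels, rate)


def read_wav_levels(path, **kwargs) -> LevelTrace:
    """Read a WAV file and compute short-term levels.

    Integer PCM is rescaled to full-scale +/-1 before the mean-square so
    that a full-scale constant signal maps to 0 dB (plus the calibration
    offset).
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: multi-channel WAV; select one channel, e.g. data[:, 0]"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return short_term_levels(data, rate, **kwargs)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_traces(traces: list, target_rate: float) -> list:
    """Resample traces onto a shared uniform grid over their common span.

    Nearest-neighbour sampling is used for every channel, which keeps
    circular quantities (yaw) on the circle: a grid point between samples
    at 179 deg and -179 deg receives one of the two, never an averaged
    ~0 deg.  Traces already on the target grid are returned unchanged in
    value; the operation is idempotent.
    """
    if not traces:
        return []
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0 = max(tr.times[0] for tr in traces)
    t1 = min(tr.times[-1] for tr in traces)
    if t1 < t0:
        raise ValueError("traces have no overlapping time span")
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate

    out = []
    for tr in traces:
        idx = np.searchsorted(tr.times, grid)
        idx = np.clip(idx, 1, len(tr.times) - 1) if len(tr.times) > 1 else idx * 0
        if len(tr.times) > 1:
            left = tr.times[idx - 1]
            right = tr.times[idx]
            idx = np.where(grid - left <= right - grid, idx - 1, idx)
        if isinstance(tr, LevelTrace):
            out.append(LevelTrace(tr.speaker_id, grid.copy(),
                                  tr.levels[idx], target_rate))
        elif isinstance(tr, MotionTrace):
            out.append(MotionTrace(grid.copy(), tr.yaw[idx], tr.pitch[idx],
                                   tr.roll[idx], tr.x[idx], tr.y[idx],
                                   tr.z[idx], target_rate))
        else:
            raise TypeError(f"cannot align object of type {type(tr).__name__}")
    return out
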