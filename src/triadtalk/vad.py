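"""Level-based speech-activity detection.

The detector reproduces a classic level-threshold pipeline used in
conversation analytics: short-term levels are smoothed (first-order
Butterworth low-pass on linear power, then a rolling 100 ms Hann window
on the dB series), a noise floor is estimated by fitting a straight line
to the lower band of the sorted level distribution, the activity
threshold is set at the 25% point of the dynamic range above that floor,
contiguous supra-threshold runs are merged across pauses shorter than
1.25 s, and merged segments shorter than 0.05 s are discarded.  The
result of the merge/discard step is called an *utterance*.

Floor and threshold are estimated for every speaker and condition
individually, so the same settings work in quiet and in loud background
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .session import LevelTrace


@dataclass
class VadParams:
    """Tunable parameters of the speech-activity detector.

    lowpass_cutoff : Hz, first-order Butterworth on linear power.
    hann_window : s, rolling Hann smoother applied to the dB series.
    threshold_fraction : position of the activity threshold within the
        estimated dynamic range above the noise floor.
    merge_pause : s, pauses shorter than this are bridged.
    min_duration : s, merged segments shorter than this are discarded.
    floor_fit_quantile_range : rank-fraction band of the sorted level
        distribution used for the noise-floor line fit.
    upper_quantile : rank fraction defining the top of the dynamic range
        (not the maximum, for outlier robustness).
    min_dynamic_range_db : a trace whose estimated dynamic range falls
        below this is flagged "no speech detectable" (a silent channel
        shows only the noise floor's own fluctuation).
    """

    lowpass_cutoff: float = 10.0
    hann_window: float = 0.1
    threshold_fraction: float = 0.25
    merge_pause: float = 1.25
    min_duration: float = 0.05
    floor_fit_quantile_range: tuple = (0.05, 0.40)
    upper_quantile: float = 0.99
    min_dynamic_range_db: float = 3.0
    butterworth_enabled: bool = True
    hann_enabled: bool = True
    hann_on_db: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if not self.merge_pause > self.min_duration:
            raise ValueError("merge_pause must exceed min_duration")
        lo, hi = self.floor_fit_quantile_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("floor_fit_quantile_range must be ordered in [0, 1]")
        if not 0.0 < self.upper_quantile <= 1.0:
            raise ValueError("upper_quantile must be in (0, 1]")


@dataclass
class NoiseFloorEstimate:
    """Noise floor, dynamic range and activity threshold for one trace."""

    floor_db: float
    upper_db: float
    dynamic_range_db: float
    threshold_db: float
    slope: float = 0.0
    residual: float = 0.0
    degenerate: bool = False  # True: "no speech detectable"

    def to_dict(self) -> dict:
        return {
            "floor_db": self.floor_db,
            "upper_db": self.upper_db,
            "dynamic_range_db": self.dynamic_range_db,
            "threshold_db": self.threshold_db,
            "slope": self.slope,
            "residual": self.residual,
            "degenerate": self.degenerate,
        }


@dataclass
class UtteranceSet:
    """Detected speech segments of one speaker: sorted, disjoint intervals."""

    speaker_id: str
    intervals: np.ndarray  # shape (n, 2), half-open [start, end)

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if len(iv):
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("empty or inverted utterance interval")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("overlapping utterances for one speaker")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def total_time(self) -> float:
        return float(self.durations.sum()) if len(self) else 0.0

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which time points fall inside an utterance."""
        times = np.asarray(times, dtype=float)
        if not len(self):
            return np.zeros(times.shape, dtype=bool)
        starts = self.intervals[:, 0]
        ends = self.intervals[:, 1]
        idx = np.searchsorted(starts, times, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(times.shape, dtype=bool)
        inside[ok] = times[ok] < ends[idx[ok]]
        return inside

    def shifted(self, dt: float) -> "UtteranceSet":
        return UtteranceSet(self.speaker_id, self.intervals + dt)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

_POWER_EPS = 1e-12


def smooth_levels(trace: LevelTrace, params: VadParams | None = None) -> LevelTrace:
    """Smooth a level trace: Butterworth on power, then Hann on dB.

    The Butterworth stage operates on linear power (10**(L/10)) with a
    causal first-order filter, matching a real-time level meter; the
    result is converted back to dB and a centred rolling Hann window with
    re-normalised truncated edges is applied to the dB series.  A constant
    trace passes through unchanged (both smoothers have unit DC gain).
    """
    params = params or VadParams()
    levels = trace.levels.astype(float)

    if params.butterworth_enabled:
        nyq = trace.sample_rate / 2.0
        if params.lowpass_cutoff >= nyq:
            raise ValueError(
                f"sample rate {trace.sample_rate:.3f} Hz too low for a "
                f"{params.lowpass_cutoff} Hz low-pass (Nyquist {nyq:.3f} Hz)"
            )
        power = 10.0 ** (levels / 10.0)
        b, a = signal.butter(1, params.lowpass_cutoff, fs=trace.sample_rate)
        # steady-state initialisation avoids a start-up transient from zero
        zi = signal.lfilter_zi(b, a) * power[0]
        power, _ = signal.lfilter(b, a, power, zi=zi)
        levels = 10.0 * np.log10(np.maximum(power, _POWER_EPS))

    if params.hann_enabled:
        nwin = int(round(params.hann_window * trace.sample_rate))
        if nwin >= 2:
            if nwin % 2 == 0:
                nwin += 1  # centred window
            win = signal.windows.hann(nwin, sym=True)
            if params.hann_on_db:
                x = levels
            else:
                x = 10.0 ** (levels / 10.0)
            num = np.convolve(x, win, mode="same")
            den = np.convolve(np.ones_like(x), win, mode="same")
            x = num / den
            levels = x if params.hann_on_db else 10.0 * np.log10(
                np.maximum(x, _POWER_EPS))

    return trace.replace_levels(levels)


# ---------------------------------------------------------------------------
# Noise floor
# ---------------------------------------------------------------------------

def estimate_noise_floor(trace: LevelTrace,
                         params: VadParams | None = None) -> NoiseFloorEstimate:
    """Estimate the noise floor from the sorted level distribution.

    An ordinary least-squares line is fitted to (rank fraction, level)
    pairs within ``floor_fit_quantile_range``; the floor is the fitted
    value at the band midpoint.  The top of the dynamic range is the
    ``upper_quantile`` level.  The activity threshold sits at
    ``floor + threshold_fraction * (upper - floor)``.

    A zero-variance trace — or one whose dynamic range stays below
    ``min_dynamic_range_db`` — is flagged ``degenerate`` ("no speech
    detectable"); for a constant trace floor, upper and threshold all
    equal the constant level.
    """
    params = params or VadParams()
    levels = np.sort(trace.levels.astype(float))
    n = len(levels)
    if n < 100:
        raise ValueError(f"need >= 100 samples to estimate a noise floor, got {n}")

    if np.ptp(levels) == 0.0:
        v = float(levels[0])
        return NoiseFloorEstimate(v, v, 0.0, v, degenerate=True)

    q = (np.arange(n) + 0.5) / n
    lo, hi = params.floor_fit_quantile_range
    band = (q >= lo) & (q <= hi)
    if band.sum() < 2:
        band = q <= max(hi, q[1])
    coef = np.polyfit(q[band], levels[band], 1)
    mid = 0.5 * (lo + hi)
    floor = float(np.polyval(coef, mid))
    resid = float(np.sqrt(np.mean(
        (levels[band] - np.polyval(coef, q[band])) ** 2)))
    upper = float(np.quantile(levels, params.upper_quantile))
    upper = max(upper, floor)
    dyn = upper - floor
    thr = floor + params.threshold_fraction * dyn
    return NoiseFloorEstimate(floor, upper, dyn, thr,
                              slope=float(coef[0]), residual=resid,
                              degenerate=dyn < params.min_dynamic_range_db)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def mask_to_sections(mask: np.ndarray, times: np.ndarray, dt: float) -> np.ndarray:
    """Contiguous True runs as half-open [start, end) intervals."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 2))
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    out = np.empty((len(starts), 2))
    for i, (s, e) in enumerate(zip(starts, ends)):
        out[i, 0] = times[s]
        out[i, 1] = times[e] if e < len(times) else times[-1] + dt
    return out


def merge_and_filter(sections: np.ndarray, merge_pause: float,
                     min_duration: float) -> np.ndarray:
    """Bridge pauses shorter than ``merge_pause``, drop short segments.

    A single left-to-right pass merges transitively (equivalent to
    iterating to convergence for this rule); the duration filter is
    applied to the merged segments.
    """
    sections = np.asarray(sections, dtype=float).reshape(-1, 2)
    if not len(sections):
        return sections
    merged = [list(sections[0])]
    for s, e in sections[1:]:
        if s - merged[-1][1] < merge_pause:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    merged = np.asarray(merged)
    keep = (merged[:, 1] - merged[:, 0]) >= min_duration
    return merged[keep]


def detect_utterances(trace: LevelTrace, params: VadParams | None = None,
                      floor: NoiseFloorEstimate | None = None,
                      smoothed: bool = True) -> UtteranceSet:
    """Detect utterances in a (smoothed) level trace.

    Activity is strictly above threshold (ties are inactive).  If
    ``smoothed`` is False the smoothing stage is applied first.  A
    degenerate noise-floor estimate yields an empty utterance set.
    """
    params = params or VadParams()
    if not smoothed:
        trace = smooth_levels(trace, params)
    if floor is None:
        floor = estimate_noise_floor(trace, params)
    if floor.degenerate:
        return UtteranceSet(trace.speaker_id, np.empty((0, 2)))
    mask = trace.levels > floor.threshold_db
    sections = mask_to_sections(mask, trace.times, trace.dt)
    segments = merge_and_filter(sections, params.merge_pause, params.min_duration)
    return UtteranceSet(trace.speaker_id, segments)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class SpeechActivityDetector(BaseEstimator):
    """Scikit-learn style facade over the level-threshold VAD.

    ``fit`` smooths the trace and estimates the per-trace noise floor and
    activity threshold; ``predict`` returns the boolean activity mask and
    ``transform`` the merged utterance intervals.  Parameters mirror
    :class:`VadParams` so the estimator works with ``get_params`` /
    ``set_params`` and sklearn model selection.
    """

    def __init__(self, lowpass_cutoff=10.0, hann_window=0.1,
                 threshold_fraction=0.25, merge_pause=1.25, min_duration=0.05,
                 floor_fit_quantile_range=(0.05, 0.40), upper_quantile=0.99,
                 min_dynamic_range_db=3.0, butterworth_enabled=True,
                 hann_enabled=True, hann_on_db=True):
        self.min_dynamic_range_db = min_dynamic_range_db
        self.lowpass_cutoff = lowpass_cutoff
        self.hann_window = hann_window
        self.threshold_fraction = threshold_fraction
        self.merge_pause = merge_pause
        self.min_duration = min_duration
        self.floor_fit_quantile_range = floor_fit_quantile_range
        self.upper_quantile = upper_quantile
        self.butterworth_enabled = butterworth_enabled
        self.hann_enabled = hann_enabled
        self.hann_on_db = hann_on_db

    def _params(self) -> VadParams:
        return VadParams(**{k: v for k, v in self.get_params().items()})

    def fit(self, trace: LevelTrace, y=None) -> "SpeechActivityDetector":
        params = self._params()
        self.smoothed_ = smooth_levels(trace, params)
        self.noise_floor_ = estimate_noise_floor(self.smoothed_, params)
        self.threshold_db_ = self.noise_floor_.threshold_db
        return self

    def predict(self, trace: LevelTrace | None = None) -> np.ndarray:
        tr = self.smoothed_ if trace is None else smooth_levels(
            trace, self._params())
        return tr.levels > self.threshold_db_

    def transform(self, trace: LevelTrace | None = None) -> UtteranceSet:
        tr = self.smoothed_ if trace is None else smooth_levels(
            trace, self._params())
        return detect_utterances(tr, self._params(), floor=self.noise_floor_)

    def fit_transform(self, trace: LevelTrace, y=None) -> UtteranceSet:
        return self.fit(trace).transform()
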