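"""Per participant x condition voice measures.

Speech level is the 95th percentile of (smoothed) levels during detected
speech activity; utterance duration is the median length of the merged
activity segments; the Lombard slope expresses the speech-level increase
per 10 dB of added background noise.
"""

from __future__ import annotations

import numpy as np

from .session import Condition, LevelTrace
from .vad import UtteranceSet


def speech_level(trace: LevelTrace, utterances: UtteranceSet) -> float:
    """95th percentile of level samples inside utterance intervals (dB SPL).

    Uses the linear-interpolation percentile definition.  Returns NaN when
    there is no detected speech activity.
    """
    if not len(utterances):
        return float("nan")
    inside = utterances.contains(trace.times)
    if not inside.any():
        return float("nan")
    return float(np.percentile(trace.levels[inside], 95))


def utterance_duration_median(utterances: UtteranceSet) -> float:
    """Median utterance duration in seconds; NaN for an empty set."""
    if not len(utterances):
        return float("nan")
    return float(np.median(utterances.durations))


def lombard_slope(levels_by_condition: dict, noise_by_condition: dict) -> float:
    """Speech-level increase per 10 dB increase of background noise.

    With two distinct noise levels (the factorial design) this is
    ``10 * (mean level in noise - mean level in quiet) / delta_noise``;
    with more noise levels an OLS slope is fitted.  Conditions present in
    only one of the two maps are ignored.
    """
    keys = [k for k in levels_by_condition if k in noise_by_condition]
    if not keys:
        raise ValueError("no overlapping conditions")
    lv = np.array([levels_by_condition[k] for k in keys], dtype=float)
    nz = np.array([noise_by_condition[k] for k in keys], dtype=float)
    ok = np.isfinite(lv) & np.isfinite(nz)
    lv, nz = lv[ok], nz[ok]
    uniq = np.unique(nz)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct background-noise levels")
    if len(uniq) == 2:
        lo, hi = uniq
        return float(10.0 * (lv[nz == hi].mean() - lv[nz == lo].mean()) / (hi - lo))
    return float(10.0 * np.polyfit(nz, lv, 1)[0])


def speech_measures(trace: LevelTrace, utterances: UtteranceSet) -> dict:
    """Bundle of voice measures for one speaker in one condition."""
    return {
        "speech_level_db": speech_level(trace, utterances),
        "utterance_duration_median_s": utterance_duration_median(utterances),
        "total_speech_time_s": utterances.total_time,
        "n_utterances": len(utterances),
    }
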