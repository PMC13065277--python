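"""Head-movement measures gated by conversational state.

Three measures per participant x condition, all computed from the head
yaw/position trace and the detected utterances:

* *angular distance to speaker* — median absolute yaw distance to the
  face of the single currently active confederate, optionally referenced
  to the per-avatar median distance over all conditions (the baseline
  removes the systematic bias toward one avatar, so referenced values
  can be negative);
* *head orientation range* — P95 - P5 of yaw, separately while the
  participant is listening and speaking; speaking-phase values are
  excluded when the total speaking time in a condition is below 15 s;
* *head translation* — median signed displacement along the axis toward
  the centre between the avatars (lean-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import CONFEDERATES, MotionTrace, SceneGeometry, wrap_angle
from .vad import UtteranceSet

# active-confederate codes
NONE, EXPERIMENTER, CONFEDERATE, BOTH = 0, 1, 2, 3
_CODE = {"experimenter": EXPERIMENTER, "confederate": CONFEDERATE}

MIN_SPEAKING_TIME_S = 15.0


@dataclass
class StateMask:
    """Per-sample conversational state on the motion-trace grid."""

    times: np.ndarray
    participant_speaking: np.ndarray  # bool
    active_confederate: np.ndarray  # codes NONE/EXPERIMENTER/CONFEDERATE/BOTH

    def single_active(self, who: str | None = None) -> np.ndarray:
        """Samples where exactly one confederate speaks and all others are silent."""
        if who is None:
            return np.isin(self.active_confederate, (EXPERIMENTER, CONFEDERATE))
        return self.active_confederate == _CODE[who]

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0

    @property
    def speaking_time_s(self) -> float:
        return float(self.participant_speaking.sum()) * self.dt


def build_state_mask(utterances: dict, times: np.ndarray,
                     require_participant_silent: bool = True) -> StateMask:
    """Sample per-speaker utterance activity onto a common time grid.

    ``active_confederate`` is a single confederate's code only where that
    confederate is active while the other confederate — and, by default,
    the participant — are silent; it is BOTH where both confederates are
    active and NONE otherwise.
    """
    times = np.asarray(times, dtype=float)
    act = {}
    for speaker in ("participant",) + CONFEDERATES:
        uset = utterances.get(speaker)
        if uset is None:
            act[speaker] = np.zeros(len(times), dtype=bool)
        elif isinstance(uset, UtteranceSet):
            act[speaker] = uset.contains(times)
        else:
            act[speaker] = UtteranceSet(speaker, np.asarray(uset)).contains(times)

    exp, conf = act["experimenter"], act["confederate"]
    part = act["participant"]
    code = np.full(len(times), NONE, dtype=np.int8)
    silent_ok = ~part if require_participant_silent else np.ones(len(times), bool)
    code[exp & ~conf & silent_ok] = EXPERIMENTER
    code[conf & ~exp & silent_ok] = CONFEDERATE
    code[exp & conf] = BOTH
    return StateMask(times, part, code)


def angular_distance_samples(motion: MotionTrace, mask: StateMask,
                             geometry: SceneGeometry) -> dict:
    """Per-avatar absolute yaw distances |wrap(yaw - face_yaw)| (degrees)."""
    out = {}
    for who in CONFEDERATES:
        sel = mask.single_active(who)
        out[who] = np.abs(wrap_angle(
            motion.yaw[sel] - geometry.avatar_face_ref[who]))
    return out


def angular_distance_to_speaker(motion: MotionTrace, mask: StateMask,
                                geometry: SceneGeometry,
                                baseline: dict | None = None) -> tuple:
    """Baseline-referenced median angular distance to the active speaker.

    Distances are pooled over samples where exactly one confederate is
    active; the per-avatar ``baseline`` (that participant's median
    distance to the same avatar over all conditions) is subtracted from
    each distance before the cumulative median, so the result can be
    negative.  Returns ``(value_deg, n_samples)``; NaN when no sample
    qualifies.
    """
    baseline = baseline or {who: 0.0 for who in CONFEDERATES}
    dists = angular_distance_samples(motion, mask, geometry)
    pooled = np.concatenate([
        dists[who] - baseline.get(who, 0.0) for who in CONFEDERATES
    ])
    if not len(pooled):
        return float("nan"), 0
    return float(np.median(pooled)), int(len(pooled))


def orientation_range(motion: MotionTrace, mask: StateMask, phase: str,
                      min_speaking_time: float = MIN_SPEAKING_TIME_S) -> tuple:
    """P95 - P5 of yaw during listening or speaking samples.

    Listening means the participant is not inside one of their own
    utterances, regardless of confederate activity.  A speaking-phase
    range with under ``min_speaking_time`` seconds of speech is excluded.
    Returns ``(value_deg, n_samples, reason)`` with ``value`` NaN and a
    reason string when excluded or empty.
    """
    if phase not in ("speaking", "listening"):
        raise ValueError("phase must be 'speaking' or 'listening'")
    sel = mask.participant_speaking if phase == "speaking" \
        else ~mask.participant_speaking
    if phase == "speaking" and mask.speaking_time_s < min_speaking_time:
        return float("nan"), int(sel.sum()), \
            f"speaking period below {min_speaking_time:g} s"
    yaw = motion.yaw[sel]
    if not len(yaw):
        return float("nan"), 0, f"no {phase} samples"
    return float(np.percentile(yaw, 95) - np.percentile(yaw, 5)), int(len(yaw)), ""


def head_translation_measure(motion: MotionTrace, geometry: SceneGeometry,
                             origin: np.ndarray | None = None) -> float:
    """Median signed projection of head position onto the screen axis (m).

    ``origin`` defaults to zero; the session pipeline passes the
    participant's overall median position so that the measure captures
    displacement relative to the individual resting posture.
    """
    pos = motion.position
    if origin is not None:
        pos = pos - np.asarray(origin, dtype=float)
    proj = pos @ geometry.screen_axis
    return float(np.median(proj))
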