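"""Synthetic triadic conversation sessions with known ground truth.

The generator emulates the sensor streams of a triadic telepresence
experiment so that every analysis stage has a recoverable target: a
semi-Markov floor-holder chain over three speakers produces utterance
intervals and signed floor-transfer offsets; per-speaker short-term
level traces are synthesised as the power sum of a condition-dependent
noise floor and Lombard-raised speech; the participant's head yaw
tracks the single active confederate with a first-order lag and an
undershoot gain, leaning in toward the screen under noise; and the
10-item ratings are driven by two latent factors ("presence" and
"conversation success"), the latter depressed in noise.

Default parameter values mirror the study conditions they emulate:
noise floors of 48.2 / 71.1 dB SPL (C) (a 22.9 dB contrast), a Lombard
slope of 4.6 dB per 10 dB of noise, quiet speech levels of 67.6 /
65.1 / 65.1 dB SPL for participant / experimenter / confederate, a
median floor-turn duration of 2.0 s, median gap 0.50 s, median overlap
1.11 s, an extra 0.72 gaps per minute in noise, a 3 cm lean-in, and a
-1.3 latent shift of conversation success under noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import signal, optimize

from .session import (CONFEDERATES, SPEAKERS, Condition, LevelTrace,
                      MotionTrace, QuestionnaireResponse, SceneGeometry,
                      SessionData, all_conditions)
from .turns import TurnEvent
from .head import build_state_mask

LN2 = float(np.log(2.0))


@dataclass
class GeneratorConfig:
    """All tunable parameters of the session generator.

    Rates are in Hz, durations in seconds, levels in dB SPL, yaw in
    degrees, translation in metres.  ``lombard_slope`` is dB of extra
    speech level per 10 dB of extra background noise.  FTO draws use
    exponential distributions parameterised by their median
    (median = ln 2 / rate); utterance durations are log-normal.
    """

    # session layout
    duration_s: float = 300.0
    n_participants: int = 16
    level_rate: float = 1.0 / 0.0058  # renderer block length 5.8 ms
    motion_rate: float = 100.0

    # speech levels
    base_speech_level: dict = field(default_factory=lambda: {
        "participant": 67.6, "experimenter": 65.1, "confederate": 65.1})
    lombard_slope: float = 4.6
    noise_floor_quiet: float = 48.2
    noise_floor_noise: float = 71.1
    modulation_depth_db: float = 3.0  # ~4 Hz syllabic level modulation
    modulation_rate_hz: float = 4.0
    utterance_level_jitter_db: float = 1.0
    sample_level_jitter_db: float = 0.5
    participant_level_sd_db: float = 2.0

    # turn-taking chain
    utterance_median_s: float = 2.0  # floor-turn length (corpus-typical)
    utterance_sigma: float = 0.6
    min_utterance_s: float = 0.15
    overlap_prob: float = 0.3
    gap_median_s: float = 0.50
    overlap_median_s: float = 1.11
    gap_median_noise_delta_s: float = 0.074
    overlap_median_noise_delta_s: float = -0.36
    gap_rate_noise_delta_per_min: float = 0.72
    overlap_max_frac: float = 0.9  # overlap clamped to this fraction of the turn

    # backchannels
    backchannel_rate_per_min: float = 2.0
    backchannel_duration_s: float = 0.3
    backchannel_clearance_s: float = 1.55  # > merge pause, keeps VAD stats clean

    # head motion
    head_lag_s: float = 0.12  # orienting-response time constant (~0.4 s settle)
    undershoot_gain: float = 0.7
    undershoot_gain_sd: float = 0.05
    yaw_jitter_deg: float = 2.0
    pitch_roll_jitter_deg: float = 0.5
    lean_in_noise_m: float = 0.03
    position_jitter_m: float = 0.003

    # ratings
    rating_loadings: dict = field(default_factory=lambda: {
        f"q{i}": 0.8 for i in range(1, 11)})
    rating_residual_sd: float = 0.6
    noise_effect_success: float = -1.3
    presence_intercept: float = 1.5
    success_intercept: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must be in [0, 1]")
        for name in ("utterance_median_s", "gap_median_s", "overlap_median_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.undershoot_gain <= 1.0:
            raise ValueError("undershoot_gain must be in [0, 1]")

    def noise_floor(self, condition: Condition) -> float:
        return self.noise_floor_noise if condition.noise == "noise" \
            else self.noise_floor_quiet

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """True utterances, floor timeline and turn events of one condition."""

    utterances: dict  # speaker -> (n, 2) interval array
    backchannel: dict  # speaker -> bool flags, aligned with utterances
    events: list  # TurnEvent with realized offsets
    floor: list  # (start, end, speaker) floor-holder timeline
    target_yaw: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def gap_offsets(self) -> np.ndarray:
        return np.array([e.offset_s for e in self.events if e.kind == "gap"])

    def overlap_offsets(self) -> np.ndarray:
        return np.array([e.offset_s for e in self.events if e.kind == "overlap"])


# ---------------------------------------------------------------------------
# Turn-chain calibration
# ---------------------------------------------------------------------------

def _expected_clamped_overlap(median_ov, utt_median, utt_sigma,
                              max_frac, nodes=40) -> float:
    """E[min(X, c min(U1, U2))] for X ~ Exp(median), U_i ~ log-normal.

    The overlap draw is clamped to ``max_frac`` of both the outgoing and
    the incoming turn; the expectation is evaluated by two-dimensional
    Gauss-Hermite quadrature over the independent turn durations.
    """
    lam = LN2 / median_ov
    x, w = hermegauss(nodes)
    w = w / w.sum()
    u = utt_median * np.exp(utt_sigma * x)
    m = np.minimum.outer(u, u)
    vals = (1.0 - np.exp(-lam * max_frac * m)) / lam
    return float(w @ vals @ w)


def _gap_rate_per_min(p_gap, gap_median, overlap_median, cfg) -> float:
    """Expected gaps/minute of the floor chain at gap probability p_gap."""
    e_utt = cfg.utterance_median_s * np.exp(cfg.utterance_sigma ** 2 / 2.0)
    e_gap = gap_median / LN2
    e_ov = _expected_clamped_overlap(overlap_median, cfg.utterance_median_s,
                                     cfg.utterance_sigma, cfg.overlap_max_frac)
    cycle = e_utt + p_gap * e_gap - (1.0 - p_gap) * e_ov
    if cycle <= 0:
        return float("inf")
    return p_gap * 60.0 / cycle


def condition_chain_params(config: GeneratorConfig, condition: Condition) -> dict:
    """Gap/overlap medians and gap probability for one condition.

    In noise the gap and overlap medians shift by their configured
    deltas, and the gap probability is solved numerically so that the
    expected gap rate exceeds the quiet rate by
    ``gap_rate_noise_delta_per_min``.
    """
    p_gap_quiet = 1.0 - config.overlap_prob
    if condition.noise == "quiet":
        return {"gap_median": config.gap_median_s,
                "overlap_median": config.overlap_median_s,
                "p_gap": p_gap_quiet}
    gm = config.gap_median_s + config.gap_median_noise_delta_s
    om = max(0.05, config.overlap_median_s + config.overlap_median_noise_delta_s)
    target = _gap_rate_per_min(p_gap_quiet, config.gap_median_s,
                               config.overlap_median_s, config) \
        + config.gap_rate_noise_delta_per_min

    def f(p):
        return _gap_rate_per_min(p, gm, om, config) - target

    try:
        p_gap = optimize.brentq(f, 1e-3, 1.0 - 1e-3, xtol=1e-6)
    except ValueError:  # target unreachable for this configuration
        p_gap = p_gap_quiet
    return {"gap_median": gm, "overlap_median": om, "p_gap": p_gap}


# ---------------------------------------------------------------------------
# Turn sequence
# ---------------------------------------------------------------------------

def sample_turn_sequence(config: GeneratorConfig, duration: float,
                         rng: np.random.Generator,
                         condition: Condition | None = None) -> GroundTruth:
    """Sample the floor-holder chain and backchannels for one condition.

    The chain picks the next speaker uniformly among the other two; each
    transition draws a gap (probability ``p_gap``, exponential with the
    configured median) or an overlap (negative offset, exponential,
    clamped to ``overlap_max_frac`` of the outgoing turn and to the
    incoming speaker's availability).  Backchannels are inserted as true
    short utterances inside other speakers' turns, flagged in the ground
    truth, and never generate turn events.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    condition = condition or Condition("static", "quiet")
    chain = condition_chain_params(config, condition)
    empty = {s: np.empty((0, 2)) for s in SPEAKERS}
    if duration == 0:
        return GroundTruth({k: v.copy() for k, v in empty.items()},
                           {s: np.empty(0, bool) for s in SPEAKERS}, [], [],
                           params=chain)

    def draw_duration():
        d = config.utterance_median_s * np.exp(
            config.utterance_sigma * rng.standard_normal())
        return max(d, config.min_utterance_s)

    utter = {s: [] for s in SPEAKERS}
    flags = {s: [] for s in SPEAKERS}
    events: list[TurnEvent] = []
    floor_timeline = []
    last_end = {s: -np.inf for s in SPEAKERS}

    cur = SPEAKERS[rng.integers(3)]
    t = 0.0
    d = draw_duration()
    while t < duration:
        utter[cur].append((t, t + d))
        flags[cur].append(False)
        floor_timeline.append((t, t + d, cur))
        last_end[cur] = t + d
        t_e = t + d

        others = [s for s in SPEAKERS if s != cur]
        nxt = others[rng.integers(2)]
        d_next = draw_duration()
        if rng.random() < chain["p_gap"]:
            off = rng.exponential(chain["gap_median"] / LN2)
        else:
            # clamping to both turns keeps the incomer outlasting the
            # floor holder and the expected cycle length analytic
            ov = rng.exponential(chain["overlap_median"] / LN2)
            ov = min(ov, config.overlap_max_frac * d,
                     config.overlap_max_frac * d_next,
                     t_e - last_end[nxt] - 0.01)
            if ov <= 0:  # incomer not available early: degrade to a gap
                off = rng.exponential(chain["gap_median"] / LN2)
            else:
                off = -ov
        events.append(TurnEvent("overlap" if off < 0 else "gap",
                                cur, nxt, off, t_e))
        t = t_e + off
        cur = nxt
        d = d_next

    # drop the final provisional event if the incoming turn never started
    if events and events[-1].at_time_s + events[-1].offset_s >= duration:
        events.pop()

    _insert_backchannels(config, duration, rng, utter, flags,
                         floor_timeline, last_end)

    gt_utts, gt_flags = {}, {}
    for s in SPEAKERS:
        iv = np.array(utter[s]).reshape(-1, 2)
        fl = np.array(flags[s], dtype=bool)
        order = np.argsort(iv[:, 0]) if len(iv) else np.empty(0, int)
        gt_utts[s] = iv[order]
        gt_flags[s] = fl[order]
    return GroundTruth(gt_utts, gt_flags, events, floor_timeline, params=chain)


def _insert_backchannels(config, duration, rng, utter, flags,
                         floor_timeline, last_end):
    """Poisson backchannels inside others' turns (failed interjections).

    Placement keeps a clearance larger than the VAD merge pause to the
    backchanneler's own utterances so the detector's merge rule does not
    fuse them with real turns, and the backchannel ends before the floor
    segment does so it can never register as a floor transfer.
    """
    if config.backchannel_rate_per_min <= 0:
        return
    n_bc = rng.poisson(config.backchannel_rate_per_min * duration / 60.0)
    times = np.sort(rng.uniform(0, duration, size=n_bc))
    clear = config.backchannel_clearance_s
    for t0 in times:
        host = next((seg for seg in floor_timeline
                     if seg[0] <= t0 < seg[1]), None)
        if host is None:
            continue
        d_bc = config.backchannel_duration_s * np.exp(
            0.3 * rng.standard_normal())
        d_bc = max(d_bc, 0.1)
        if t0 + d_bc > host[1] - 0.1 or t0 < host[0] + 0.05:
            continue
        cands = [s for s in SPEAKERS if s != host[2]]
        who = cands[rng.integers(2)]
        iv = np.array(utter[who]).reshape(-1, 2)
        if len(iv) and np.any((t0 - clear < iv[:, 1]) & (iv[:, 0] < t0 + d_bc + clear)):
            continue
        utter[who].append((t0, t0 + d_bc))
        flags[who].append(True)


# ---------------------------------------------------------------------------
# Level synthesis
# ---------------------------------------------------------------------------

def synthesize_levels(gt: GroundTruth, config: GeneratorConfig,
                      condition: Condition,
                      rng: np.random.Generator) -> dict:
    """Per-speaker short-term level traces as floor + speech power sums.

    During a speaker's utterances the speech component sits at the base
    level plus the Lombard gain for the condition's noise floor,
    amplitude-modulated at ~4 Hz (in dB) with per-utterance and
    per-sample level jitter; outside utterances only the noise floor
    remains.  Powers add linearly before conversion to dB.
    """
    floor_db = config.noise_floor(condition)
    lombard = config.lombard_slope * (
        floor_db - config.noise_floor_quiet) / 10.0
    duration = max((iv[-1, 1] for iv in gt.utterances.values() if len(iv)),
                   default=0.0)
    n = max(1, int(np.ceil(duration * config.level_rate)))
    times = np.arange(n) / config.level_rate
    out = {}
    for speaker in SPEAKERS:
        iv = gt.utterances[speaker]
        base = config.base_speech_level.get(speaker, 65.0) + lombard
        speech_db = np.full(n, -np.inf)
        mod = config.modulation_depth_db * np.sin(
            2.0 * np.pi * config.modulation_rate_hz * times)
        for k, (s, e) in enumerate(iv):
            sel = (times >= s) & (times < e)
            lvl = base + rng.normal(0.0, config.utterance_level_jitter_db)
            speech_db[sel] = lvl + mod[sel]
        if config.sample_level_jitter_db > 0:
            speech_db = speech_db + rng.normal(
                0.0, config.sample_level_jitter_db, size=n)
        power = 10.0 ** (floor_db / 10.0) + np.where(
            np.isfinite(speech_db), 10.0 ** (speech_db / 10.0), 0.0)
        out[speaker] = LevelTrace(speaker, times, 10.0 * np.log10(power),
                                  config.level_rate)
    return out


# ---------------------------------------------------------------------------
# Head-motion synthesis
# ---------------------------------------------------------------------------

def synthesize_head_motion(gt: GroundTruth, geometry: SceneGeometry,
                           config: GeneratorConfig, condition: Condition,
                           rng: np.random.Generator,
                           undershoot_gain: float | None = None
                           ) -> MotionTrace:
    """Participant head motion tracking the single active confederate.

    The target yaw is ``gain * avatar_yaw`` of the currently single
    active confederate and 0 (centre) while the participant speaks or
    both/neither confederate is active; the head follows with a
    first-order lag plus Gaussian jitter.  In noise conditions the head
    shifts toward the screen by the configured lean-in.
    """
    g = config.undershoot_gain if undershoot_gain is None else undershoot_gain
    duration = max((iv[-1, 1] for iv in gt.utterances.values() if len(iv)),
                   default=1.0)
    n = max(2, int(np.ceil(duration * config.motion_rate)))
    times = np.arange(n) / config.motion_rate
    mask = build_state_mask(
        {s: gt.utterances[s] for s in SPEAKERS}, times)

    target = np.zeros(n)
    for who in CONFEDERATES:
        target[mask.single_active(who)] = g * geometry.avatar_yaw[who]
    gt.target_yaw = target

    alpha = min(1.0, (1.0 / config.motion_rate) / max(config.head_lag_s, 1e-6))
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    yaw = signal.lfilter(b, a, target, zi=[target[0] * (1.0 - alpha)])[0]
    yaw = yaw + rng.normal(0.0, config.yaw_jitter_deg, size=n)

    pitch = rng.normal(0.0, config.pitch_roll_jitter_deg, size=n)
    roll = rng.normal(0.0, config.pitch_roll_jitter_deg, size=n)
    lean = config.lean_in_noise_m if condition.noise == "noise" else 0.0
    pos_noise = rng.normal(0.0, config.position_jitter_m, size=(n, 3))
    axis = geometry.screen_axis
    pos = pos_noise + lean * axis
    return MotionTrace(times, yaw, pitch, roll,
                       pos[:, 0], pos[:, 1], pos[:, 2], config.motion_rate)


# ---------------------------------------------------------------------------
# Ratings synthesis
# ---------------------------------------------------------------------------

def synthesize_ratings(config: GeneratorConfig, condition: Condition,
                       rng: np.random.Generator) -> QuestionnaireResponse:
    """Draw one questionnaire response from the two-factor rating model.

    Presence items load on a latent presence factor, success items on a
    latent success factor that is shifted by ``noise_effect_success``
    under noise.  Q10 is generated on a reversed scale (effort: high in
    noise).  Values snap to the 0.5 grid and clip to [-3, 3].
    """
    presence = rng.standard_normal()
    success = rng.standard_normal() + (
        config.noise_effect_success if condition.noise == "noise" else 0.0)
    vals = {}
    from .stats import PRESENCE_ITEMS, SUCCESS_ITEMS

    for item in PRESENCE_ITEMS:
        lam = config.rating_loadings[item]
        v = config.presence_intercept + lam * presence \
            + rng.normal(0.0, config.rating_residual_sd)
        vals[item] = v
    for item in SUCCESS_ITEMS:
        lam = config.rating_loadings[item]
        core = lam * success + rng.normal(0.0, config.rating_residual_sd)
        if item == "q10":  # reversed scale: high effort = poor success
            vals[item] = -config.success_intercept - core
        else:
            vals[item] = config.success_intercept + core
    snapped = {k: float(np.clip(np.round(v * 2.0) / 2.0, -3.0, 3.0))
               for k, v in vals.items()}
    return QuestionnaireResponse(snapped)


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    session: SessionData
    truths: dict  # Condition -> GroundTruth
    traits: dict


def generate_session(config: GeneratorConfig, participant_id: str,
                     seed) -> SessionBundle:
    """Generate all eight conditions of one participant, deterministically.

    Every condition draws from an independent sub-stream derived from
    ``seed``, so the same seed reproduces the session bit-for-bit.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    trait_stream, order_stream, cond_parent = root.spawn(3)
    trait_rng = np.random.default_rng(trait_stream)
    traits = {
        "level_offset_db": float(trait_rng.normal(
            0.0, config.participant_level_sd_db)),
        "undershoot_gain": float(np.clip(trait_rng.normal(
            config.undershoot_gain, config.undershoot_gain_sd), 0.0, 1.0)),
    }
    geometry = SceneGeometry()
    session = SessionData(participant_id, geometry=geometry)
    conds = all_conditions()
    order_rng = np.random.default_rng(order_stream)
    session.condition_order = [conds[i] for i in
                               order_rng.permutation(len(conds))]
    truths = {}

    cond_streams = cond_parent.spawn(len(conds))
    base = dict(config.base_speech_level)
    base["participant"] = base.get("participant", 65.0) + traits["level_offset_db"]
    cfg = GeneratorConfig(**{**config.to_dict(), "base_speech_level": base})

    for condition, stream in zip(conds, cond_streams):
        rng = np.random.default_rng(stream)
        gt = sample_turn_sequence(cfg, cfg.duration_s, rng, condition)
        rec = session.record(condition)
        rec.levels = synthesize_levels(gt, cfg, condition, rng)
        rec.motion = synthesize_head_motion(
            gt, geometry, cfg, condition, rng,
            undershoot_gain=traits["undershoot_gain"])
        rec.ratings = synthesize_ratings(cfg, condition, rng)
        truths[condition] = gt
    return SessionBundle(session, truths, traits)


def generate_study(config: GeneratorConfig, seed,
                   n_participants: int | None = None) -> list:
    """Generate a full study cohort (default 16 participants)."""
    n = config.n_participants if n_participants is None else n_participants
    return [generate_session(config, f"P{i + 1:02d}",
                             np.random.SeedSequence([int(seed), i]))
            for i in range(n)]
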