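"""End-to-end analysis: sessions in, measure table and statistics out.

Per participant and condition the pipeline (i) smooths each
interlocutor's level trace and detects utterances, (ii) derives voice
measures and the gap/overlap structure of floor transfers, (iii) gates
the head-motion trace by conversational state and computes the movement
measures, and (iv) collects the questionnaire response.  Study-level
helpers then run the factorial statistics and the one-factor rating
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import head as head_mod
from . import speech, stats, turns, vad
from .session import (CONFEDERATES, SPEAKERS, Condition, MeasureTable,
                      SceneGeometry, SessionData)

BEHAVIORAL_MEASURES = [
    "speech_level",
    "utterance_duration",
    "gap_duration",
    "overlap_duration",
    "angular_distance",
    "orientation_range_listening",
    "orientation_range_speaking",
    "head_translation",
]


def detect_condition_utterances(record, params: vad.VadParams) -> dict:
    """Smoothed traces and detected utterances for every interlocutor."""
    out = {"smoothed": {}, "utterances": {}, "floor": {}}
    for speaker in SPEAKERS:
        trace = record.levels[speaker]
        sm = vad.smooth_levels(trace, params)
        fl = vad.estimate_noise_floor(sm, params)
        out["smoothed"][speaker] = sm
        out["floor"][speaker] = fl
        out["utterances"][speaker] = vad.detect_utterances(sm, params, floor=fl)
    return out


def session_measures(session: SessionData,
                     params: vad.VadParams | None = None,
                     geometry: SceneGeometry | None = None) -> MeasureTable:
    """All behavioral measures of one session, one row per measure x condition.

    The angular-distance baseline (per-avatar median distance over all
    conditions) and the translation origin (overall median head
    position) are computed across the session before the per-condition
    values, as both reference the individual's overall behavior.
    """
    params = params or vad.VadParams()
    geometry = geometry or session.geometry
    table = MeasureTable()

    interm = {}
    for condition, record in session.conditions.items():
        if not record.complete:
            for m in BEHAVIORAL_MEASURES:
                table.add(session.participant_id, condition, m, np.nan,
                          excluded=True,
                          reason=record.missing_reason or "incomplete streams")
            continue
        det = detect_condition_utterances(record, params)
        motion = record.motion
        mask = head_mod.build_state_mask(det["utterances"], motion.times)
        dists = head_mod.angular_distance_samples(motion, mask, geometry)
        proj = (motion.position @ geometry.screen_axis)
        interm[condition] = {
            "det": det, "motion": motion, "mask": mask,
            "dists": dists, "proj": proj,
        }

    if not interm:
        return table

    baseline = {}
    for who in CONFEDERATES:
        pooled = np.concatenate([c["dists"][who] for c in interm.values()])
        baseline[who] = float(np.median(pooled)) if len(pooled) else 0.0
    all_proj = np.concatenate([c["proj"] for c in interm.values()])
    origin_proj = float(np.median(all_proj))

    for condition, c in interm.items():
        pid = session.participant_id
        det, motion, mask = c["det"], c["motion"], c["mask"]
        utts = det["utterances"]

        sm = det["smoothed"]["participant"]
        own = utts["participant"]
        lvl = speech.speech_level(sm, own)
        table.add(pid, condition, "speech_level", lvl,
                  n_used=int(own.contains(sm.times).sum()),
                  reason="" if np.isfinite(lvl) else "no detected speech")
        for who in CONFEDERATES:
            lvl_o = speech.speech_level(det["smoothed"][who], utts[who])
            table.add(pid, condition, f"speech_level_{who}", lvl_o,
                      n_used=len(utts[who]))
        dur = speech.utterance_duration_median(own)
        table.add(pid, condition, "utterance_duration", dur, n_used=len(own),
                  reason="" if np.isfinite(dur) else "no detected speech")

        events = turns.find_floor_transfers(utts)
        duration_s = sm.duration
        summ = turns.fto_summary(events, duration_s)
        table.add(pid, condition, "gap_duration", summ.median_gap_s,
                  n_used=sum(e.kind == "gap" for e in events))
        table.add(pid, condition, "overlap_duration", summ.median_overlap_s,
                  n_used=sum(e.kind == "overlap" for e in events))
        table.add(pid, condition, "gap_rate", summ.gap_rate_per_min,
                  n_used=summ.n_transfers)
        table.add(pid, condition, "overlap_rate", summ.overlap_rate_per_min,
                  n_used=summ.n_transfers)

        ang, n_ang = head_mod.angular_distance_to_speaker(
            motion, mask, geometry, baseline)
        table.add(pid, condition, "angular_distance", ang, n_used=n_ang,
                  reason="" if np.isfinite(ang) else "no single-speaker samples")
        ang_raw, _ = head_mod.angular_distance_to_speaker(motion, mask, geometry)
        table.add(pid, condition, "angular_distance_raw", ang_raw, n_used=n_ang)

        for phase in ("listening", "speaking"):
            val, n_used, reason = head_mod.orientation_range(motion, mask, phase)
            table.add(pid, condition, f"orientation_range_{phase}", val,
                      n_used=n_used, reason=reason)

        proj = c["proj"] - origin_proj
        table.add(pid, condition, "head_translation", float(np.median(proj)),
                  n_used=len(proj))
    return table


def session_ratings(session: SessionData) -> pd.DataFrame:
    """Long-format questionnaire responses: one row per condition."""
    rows = []
    for condition, record in session.conditions.items():
        if record.ratings is None:
            continue
        row = {"participant": session.participant_id,
               "animation": condition.animation, "noise": condition.noise}
        row.update(record.ratings.values)
        rows.append(row)
    return pd.DataFrame(rows)


def study_measures(sessions: list, params: vad.VadParams | None = None
                   ) -> tuple[MeasureTable, pd.DataFrame]:
    """Measure table and pooled ratings for a list of sessions."""
    table = MeasureTable()
    ratings = []
    for s in sessions:
        table = table.concat(session_measures(s, params))
        ratings.append(session_ratings(s))
    return table, pd.concat(ratings, ignore_index=True) if ratings \
        else pd.DataFrame()


def study_turn_events(sessions: list, params: vad.VadParams | None = None
                      ) -> dict:
    """Detected floor-transfer events pooled across sessions, per condition."""
    params = params or vad.VadParams()
    events = {}
    for session in sessions:
        for condition, record in session.conditions.items():
            if not record.complete:
                continue
            det = detect_condition_utterances(record, params)
            events.setdefault(condition, []).extend(
                turns.find_floor_transfers(det["utterances"]))
    return events


def lombard_slopes(table: MeasureTable,
                   noise_levels: dict | None = None) -> pd.DataFrame:
    """Per-participant Lombard slope from the speech-level measures."""
    noise_levels = noise_levels or {"quiet": 48.2, "noise": 71.1}
    df = table.slice("speech_level")
    rows = []
    for pid, grp in df.groupby("participant"):
        lv = {Condition(r.animation, r.noise): r.value
              for r in grp.itertuples()}
        nz = {c: noise_levels[c.noise] for c in lv}
        rows.append({"participant": pid,
                     "slope_db_per_10db": speech.lombard_slope(lv, nz)})
    return pd.DataFrame(rows)


def pooled_fto(sessions_events: dict) -> dict:
    """Pool turn events across participants, per condition."""
    out = {}
    for condition, events in sessions_events.items():
        offs = np.array([e.offset_s for e in events])
        out[condition] = {
            "n": len(offs),
            "median_fto_s": float(np.median(offs)) if len(offs) else np.nan,
        }
    return out


def behavioral_statistics(table: MeasureTable,
                          measures: list | None = None) -> dict:
    """RM-ANOVA report per behavioral measure (Table-4 style)."""
    out = {}
    for measure in measures or BEHAVIORAL_MEASURES:
        df = table.slice(measure)
        if df.empty:
            continue
        try:
            out[measure] = stats.rm_anova_2x4(df)
        except ValueError as exc:
            out[measure] = {"error": str(exc)}
    return out


def rating_statistics(ratings: pd.DataFrame) -> dict:
    """Kruskal-Wallis + Dunn per item and per latent construct (Table-5 style).

    Items are tested on the raw scale for both factors; the construct
    factor scores come from the pooled one-factor models with Q10
    reversed beforehand.
    """
    out = {"items": {}, "constructs": {}}
    items = [c for c in ratings.columns if c.startswith("q")]
    for item in items:
        out["items"][item] = {
            factor: stats.kruskal_wallis_with_dunn(
                ratings[item], ratings[factor], name=f"{item}~{factor}")
            for factor in ("animation", "noise")
        }
    scored = stats.score_questionnaire(ratings)
    for construct in ("presence", "success"):
        try:
            fr = stats.one_factor_analysis(scored, construct)
        except ValueError as exc:  # e.g. too few pooled responses
            out["constructs"][construct] = {"error": str(exc)}
            continue
        tests = {
            factor: stats.kruskal_wallis_with_dunn(
                fr.scores, ratings[factor], name=f"{construct}~{factor}")
            for factor in ("animation", "noise")
        }
        quiet = fr.scores[(ratings["noise"] == "quiet").to_numpy()]
        noise = fr.scores[(ratings["noise"] == "noise").to_numpy()]
        out["constructs"][construct] = {
            "factor": fr, "tests": tests,
            "noise_delta": float(np.mean(noise) - np.mean(quiet))
            if len(quiet) and len(noise) else np.nan,
        }
    return out
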