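"""Synthetic session generator: ground truth, levels, motion, ratings."""

import numpy as np
import pytest

import triadtalk as tt
from triadtalk.session import Condition, SceneGeometry
from triadtalk.synth import (GeneratorConfig, sample_turn_sequence,
                             synthesize_head_motion, synthesize_levels,
                             synthesize_ratings)


@pytest.fixture
def cfg():
    return GeneratorConfig(duration_s=60.0)


class TestTurnSequence:
    def test_zero_duration_yields_empty_truth(self, cfg):
        gt = sample_turn_sequence(cfg, 0.0, np.random.default_rng(0))
        assert all(len(iv) == 0 for iv in gt.utterances.values())
        assert gt.events == []

    def test_no_overlap_config_gives_nonnegative_offsets(self):
        c = GeneratorConfig(overlap_prob=0.0, backchannel_rate_per_min=0.0)
        gt = sample_turn_sequence(c, 300.0, np.random.default_rng(1))
        assert all(e.offset_s >= 0 for e in gt.events)

    def test_speaker_utterances_disjoint_and_min_duration(self, cfg):
        gt = sample_turn_sequence(cfg, 300.0, np.random.default_rng(2))
        for iv in gt.utterances.values():
            if len(iv) > 1:
                assert np.all(iv[1:, 0] >= iv[:-1, 1])
            assert np.all(iv[:, 1] - iv[:, 0] >= cfg.min_utterance_s - 1e-9)

    def test_event_signs_match_kind(self, cfg):
        gt = sample_turn_sequence(cfg, 300.0, np.random.default_rng(3))
        for e in gt.events:
            assert (e.offset_s >= 0) == (e.kind == "gap")
            assert e.from_speaker != e.to_speaker

    def test_monte_carlo_gap_median(self):
        # ~10,000 transitions pooled over repeated 20-min draws
        c = GeneratorConfig(backchannel_rate_per_min=0.0)
        gaps = []
        rng = np.random.default_rng(4)
        while len(gaps) < 10000:
            gt = sample_turn_sequence(c, 1200.0, rng)
            gaps.extend(gt.gap_offsets().tolist())
        med = np.median(gaps)
        assert 0.47 <= med <= 0.53

    def test_backchannels_marked_and_never_floor_transfers(self, cfg):
        from triadtalk.turns import find_floor_transfers
        gt = sample_turn_sequence(cfg, 600.0, np.random.default_rng(5))
        n_bc = sum(int(f.sum()) for f in gt.backchannel.values())
        assert n_bc > 0
        ev = find_floor_transfers(gt.utterances)
        assert len(ev) == len(gt.events)


class TestLevels:
    def test_silent_speaker_sits_on_noise_floor(self, cfg):
        gt = sample_turn_sequence(cfg, 60.0, np.random.default_rng(6))
        gt.utterances["confederate"] = np.empty((0, 2))
        gt.backchannel["confederate"] = np.empty(0, bool)
        traces = synthesize_levels(gt, cfg, Condition("static", "quiet"),
                                   np.random.default_rng(7))
        assert np.all(np.abs(traces["confederate"].levels
                             - cfg.noise_floor_quiet) < 0.1)

    def test_high_snr_plateau_matches_speech_level(self):
        c = GeneratorConfig(base_speech_level={"participant": 78.2},
                            noise_floor_quiet=48.2, modulation_depth_db=0.0,
                            utterance_level_jitter_db=0.0,
                            sample_level_jitter_db=0.0)
        gt = tt.GroundTruth(
            {"participant": np.array([[1.0, 5.0]]),
             "experimenter": np.empty((0, 2)),
             "confederate": np.empty((0, 2))},
            {"participant": np.zeros(1, bool),
             "experimenter": np.empty(0, bool),
             "confederate": np.empty(0, bool)}, [], [])
        tr = synthesize_levels(gt, c, Condition("static", "quiet"),
                               np.random.default_rng(8))["participant"]
        inside = (tr.times >= 1.0) & (tr.times < 5.0)
        # 30 dB SNR: power sum adds only ~0.004 dB
        assert np.all(np.abs(tr.levels[inside] - 78.2) < 0.01)

    def test_lombard_gain_is_slope_times_noise_delta(self):
        c = GeneratorConfig(modulation_depth_db=0.0,
                            utterance_level_jitter_db=0.0,
                            sample_level_jitter_db=0.0)
        gt = tt.GroundTruth(
            {"participant": np.array([[1.0, 5.0]]),
             "experimenter": np.empty((0, 2)),
             "confederate": np.empty((0, 2))},
            {"participant": np.zeros(1, bool),
             "experimenter": np.empty(0, bool),
             "confederate": np.empty(0, bool)}, [], [])
        out = {}
        for noise in ("quiet", "noise"):
            tr = synthesize_levels(gt, c, Condition("static", noise),
                                   np.random.default_rng(9))["participant"]
            inside = (tr.times >= 2.0) & (tr.times < 4.0)
            # subtract the condition noise floor power to isolate speech
            p = 10 ** (tr.levels[inside] / 10) - 10 ** (c.noise_floor(
                Condition("static", noise)) / 10)
            out[noise] = 10 * np.log10(p.mean())
        # 4.6 dB per 10 dB over a 22.9 dB contrast -> 10.53 dB
        assert out["noise"] - out["quiet"] == pytest.approx(10.534, abs=0.01)


class TestHeadMotion:
    def _single_speaker_gt(self, who, span):
        utts = {s: np.empty((0, 2)) for s in
                ("participant", "experimenter", "confederate")}
        utts[who] = np.array([span])
        flags = {k: np.zeros(len(v), bool) for k, v in utts.items()}
        return tt.GroundTruth(utts, flags, [], [])

    def test_steady_state_reaches_scaled_avatar_yaw(self):
        c = GeneratorConfig(yaw_jitter_deg=0.0, undershoot_gain=1.0,
                            lean_in_noise_m=0.0)
        gt = self._single_speaker_gt("experimenter", [0.0, 30.0])
        mo = synthesize_head_motion(gt, SceneGeometry(), c,
                                    Condition("static", "quiet"),
                                    np.random.default_rng(10))
        assert mo.yaw[-1] == pytest.approx(30.0, abs=0.1)

    def test_undershoot_scales_dwell_yaw(self):
        c = GeneratorConfig(yaw_jitter_deg=0.0, undershoot_gain=0.7)
        gt = self._single_speaker_gt("confederate", [0.0, 30.0])
        mo = synthesize_head_motion(gt, SceneGeometry(), c,
                                    Condition("static", "quiet"),
                                    np.random.default_rng(11))
        assert mo.yaw[-1] == pytest.approx(-21.0, abs=0.1)

    def test_lean_in_shifts_z_by_configured_amount(self):
        c = GeneratorConfig(lean_in_noise_m=0.03)
        gt = self._single_speaker_gt("experimenter", [0.0, 10.0])
        zq = synthesize_head_motion(gt, SceneGeometry(), c,
                                    Condition("static", "quiet"),
                                    np.random.default_rng(12)).z
        zn = synthesize_head_motion(gt, SceneGeometry(), c,
                                    Condition("static", "noise"),
                                    np.random.default_rng(12)).z
        assert np.median(zn) - np.median(zq) == pytest.approx(0.03, abs=0.002)


class TestRatings:
    def test_values_on_grid_and_clipped(self):
        c = GeneratorConfig()
        rng = np.random.default_rng(13)
        for _ in range(50):
            r = synthesize_ratings(c, Condition("video", "noise"), rng)
            arr = r.as_array()
            assert np.all(arr >= -3.0) and np.all(arr <= 3.0)
            assert np.allclose(arr * 2, np.round(arr * 2))

    def test_noise_shifts_success_items_by_loading_times_effect(self):
        c = GeneratorConfig(rating_residual_sd=0.0)
        rng = np.random.default_rng(14)
        q9 = {"quiet": [], "noise": []}
        for _ in range(800):
            for nz in ("quiet", "noise"):
                q9[nz].append(synthesize_ratings(
                    c, Condition("static", nz), rng).values["q9"])
        shift = np.mean(q9["noise"]) - np.mean(q9["quiet"])
        assert shift == pytest.approx(-1.3 * 0.8, abs=0.12)

    def test_extreme_latents_clip_at_bounds(self):
        c = GeneratorConfig(success_intercept=10.0, rating_residual_sd=0.0)
        r = synthesize_ratings(c, Condition("static", "quiet"),
                               np.random.default_rng(15))
        assert r.values["q9"] == 3.0
        assert r.values["q10"] == -3.0


class TestSessionAssembly:
    def test_same_seed_is_bit_identical(self):
        c = GeneratorConfig(duration_s=30.0)
        b1 = tt.generate_session(c, "P01", 777)
        b2 = tt.generate_session(c, "P01", 777)
        for cond in b1.session.conditions:
            r1 = b1.session.conditions[cond]
            r2 = b2.session.conditions[cond]
            for spk in r1.levels:
                assert np.array_equal(r1.levels[spk].levels,
                                      r2.levels[spk].levels)
            assert np.array_equal(r1.motion.yaw, r2.motion.yaw)
            assert r1.ratings.values == r2.ratings.values
        assert b1.session.condition_order == b2.session.condition_order

    def test_different_seeds_differ(self):
        c = GeneratorConfig(duration_s=30.0)
        b1 = tt.generate_session(c, "P01", 1)
        b2 = tt.generate_session(c, "P01", 2)
        cond = next(iter(b1.session.conditions))
        assert not np.array_equal(
            b1.session.conditions[cond].levels["participant"].levels,
            b2.session.conditions[cond].levels["participant"].levels)

    def test_session_covers_all_eight_conditions(self, cfg):
        b = tt.generate_session(cfg, "P01", 3)
        assert len(b.session.conditions) == 8
        assert sorted(b.session.condition_order) == \
            sorted(b.session.conditions)

    def test_default_cohort_is_sixteen(self):
        assert GeneratorConfig().n_participants == 16
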