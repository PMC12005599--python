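"""Generator contracts: determinism, schedules, grids, and ground truth."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from ema_context import synthetic_data as sd
from ema_context.ema_core import normalize_likert, read_event_logs, read_manifests


def _tiny_config(**response_overrides):
    studies = (
        sd.StudyDesign("a", 3, "older", "intervention", 8, 7, 1, 5),
        sd.StudyDesign("b", 3, "younger", "observational", 12, 7, 0, 10),
    )
    resp = dataclasses.replace(sd.ResponseModelConfig(), **response_overrides)
    return sd.GeneratorConfig(studies=studies, response=resp)


class TestDeterminism:
    def test_same_seed_reproduces_sessions_and_streams(self):
        cfg = _tiny_config()
        d1 = sd.generate_dataset(cfg, 5)
        d2 = sd.generate_dataset(cfg, 5)
        for p1, p2 in zip(d1.participants, d2.participants):
            assert p1.participant_id == p2.participant_id
            assert np.array_equal(p1.accel_mag, p2.accel_mag)
            assert np.array_equal(p1.fix_lat, p2.fix_lat)
            s1 = [(s.prompt.scheduled_time, s.compliance) for s in p1.sessions]
            s2 = [(s.prompt.scheduled_time, s.compliance) for s in p2.sessions]
            assert s1 == s2

    def test_different_seed_differs(self):
        cfg = _tiny_config()
        d1 = sd.generate_dataset(cfg, 5)
        d2 = sd.generate_dataset(cfg, 6)
        assert not np.array_equal(d1.participants[0].accel_mag, d2.participants[0].accel_mag)

    def test_written_logs_are_byte_identical(self, tmp_path):
        cfg = _tiny_config()
        p1 = sd.write_dataset(sd.generate_dataset(cfg, 3), tmp_path / "r1",
                              include_streams=False)
        p2 = sd.write_dataset(sd.generate_dataset(cfg, 3), tmp_path / "r2",
                              include_streams=False)
        assert p1["prompts"].read_bytes() == p2["prompts"].read_bytes()
        assert p1["manifest"].read_bytes() == p2["manifest"].read_bytes()


class TestSchedule:
    def test_one_prompt_per_block_per_day(self):
        study = sd.StudyDesign("a", 1, "older", "observational", 8, 14, 1, 5)
        rng = np.random.default_rng(0)
        start = dt.datetime(2023, 3, 6)
        prompts = sd.schedule_prompts(study, start, rng)
        assert len(prompts) == 14 * len(study.time_blocks)

    def test_prompts_fall_inside_their_blocks(self):
        study = sd.StudyDesign("a", 1, "older", "observational", 8, 60, 1, 5)
        rng = np.random.default_rng(1)
        prompts = sd.schedule_prompts(study, dt.datetime(2023, 3, 6), rng)
        blocks = study.time_blocks
        for p in prompts:
            assert any(s <= p.time() < e for s, e in blocks)

    def test_never_responding_participant_logs_max_attempts(self):
        cfg = _tiny_config(base_rr=1e-9, beta_home=0, beta_cp=0,
                           beta_activity=0, intercept_sd=0.0,
                           beta_questions=0.0)
        ds = sd.generate_dataset(cfg, 2)
        for p in ds.participants:
            study = next(s for s in cfg.studies if s.study_id == p.study_id)
            for s in p.sessions:
                assert not s.responded
                assert s.prompt.attempt_count == study.max_reissues


class TestAnswerModel:
    def test_raw_values_on_declared_grid_and_normalizable(self, mini_dataset):
        for p in mini_dataset.participants:
            for s in p.sessions:
                for a in s.answers:
                    assert a.raw_min <= a.raw_value <= a.raw_max
                    assert float(a.raw_value).is_integer()
                    norm = normalize_likert(a.raw_value, a.raw_min, a.raw_max, a.inverted)
                    assert 1.0 <= norm <= 5.0
                    assert norm == a.norm_value

    def test_base_rate_recovered_with_effects_zeroed(self):
        """With all effects off, the response rate is the configured base rate."""
        studies = (
            sd.StudyDesign("a", 30, "older", "observational", 8, 14, 1, 5),
            sd.StudyDesign("b", 30, "younger", "observational", 12, 14, 1, 5),
        )
        resp = sd.ResponseModelConfig(
            base_rr=0.8,
            beta_questions=0.0,
            beta_home=0.0,
            beta_cp=0.0,
            beta_activity=0.0,
            intercept_sd=0.0,
            tod_offsets={
                "older": {"morning": 0, "afternoon": 0, "evening": 0},
                "younger": {"morning": 0, "afternoon": 0, "evening": 0},
            },
        )
        ds = sd.generate_dataset(sd.GeneratorConfig(studies=studies, response=resp), 9)
        sessions = ds.all_sessions()
        assert len(sessions) >= 3000
        rr = 100.0 * np.mean([s.responded for s in sessions])
        assert rr == pytest.approx(80.0, abs=2.0)

    def test_truth_probabilities_match_configured_base(self):
        cfg = _tiny_config(beta_questions=0.0, beta_home=0.0, beta_cp=0.0,
                           beta_activity=0.0, intercept_sd=0.0,
                           tod_offsets={
                               "older": {"morning": 0, "afternoon": 0, "evening": 0},
                               "younger": {"morning": 0, "afternoon": 0, "evening": 0},
                           })
        ds = sd.generate_dataset(cfg, 4)
        for p in ds.participants:
            assert np.allclose(p.truth.p_respond, 0.8)

    def test_no_careless_drift_means_flat_careless(self):
        cfg = _tiny_config(careless_drift_per_day=0.0)
        ds = sd.generate_dataset(cfg, 3)
        for p in ds.participants:
            assert np.ptp(p.truth.careless_by_prompt) == 0.0


class TestBehavior:
    def test_zero_away_bouts_keeps_fixes_at_home(self):
        studies = (sd.StudyDesign("a", 2, "older", "observational", 8, 7, 1, 5),)
        behavior = dataclasses.replace(sd.BehaviorConfig(), away_bouts_per_day=0.0)
        ds = sd.generate_dataset(
            sd.GeneratorConfig(studies=studies, behavior=behavior), 8
        )
        from ema_context.sensor_markers import distance_bearing

        for p in ds.participants:
            assert p.truth.away_intervals == []
            d, _ = distance_bearing(
                p.fix_lat, p.fix_lon, p.truth.home_lat, p.truth.home_lon
            )
            assert np.max(d) < 60.0  # GPS jitter only

    def test_transitions_are_state_boundaries(self, mini_dataset):
        for p in mini_dataset.participants:
            trans = set(p.truth.transitions)
            for a, b in p.truth.away_intervals:
                # bout boundaries fall on the true transition grid
                assert any(abs(t - a) <= 60 for t in trans)
                assert any(abs(t - b) <= 60 for t in trans)


class TestRoundTrip:
    def test_written_logs_reload_into_identical_sessions(self, tmp_path):
        cfg = _tiny_config()
        ds = sd.generate_dataset(cfg, 13)
        paths = sd.write_dataset(ds, tmp_path, include_streams=False)
        manifests = read_manifests(paths["manifest"])
        data = read_event_logs(paths["prompts"], manifests)
        assert not data.issues
        orig = sorted(
            (
                (s.prompt.participant_id, s.prompt.scheduled_time, s.responded,
                 round(s.compliance, 9), s.prompt.attempt_count)
                for s in ds.all_sessions()
            )
        )
        loaded = sorted(
            (
                (s.prompt.participant_id, s.prompt.scheduled_time, s.responded,
                 round(s.compliance, 9), s.prompt.attempt_count)
                for s in data.sessions
            )
        )
        assert loaded == orig

    def test_ambient_streams_round_trip(self, tmp_path, ambient_dataset):
        from ema_context.sensor_markers import read_ambient_stream

        paths = sd.write_dataset(ambient_dataset, tmp_path, include_streams=True)
        p = ambient_dataset.participants[0]
        loaded = read_ambient_stream(paths["streams"] / f"{p.participant_id}_ambient.csv")
        assert len(loaded.times) == len(p.ambient.times)
        assert list(loaded.kinds) == list(p.ambient.kinds)
        assert list(loaded.states) == list(p.ambient.states)
        # ISO timestamps round to the second
        assert np.allclose(loaded.times, p.ambient.times, atol=1.0)

    def test_reloaded_answers_preserve_normalized_values(self, tmp_path):
        cfg = _tiny_config()
        ds = sd.generate_dataset(cfg, 13)
        paths = sd.write_dataset(ds, tmp_path, include_streams=False)
        data = read_event_logs(paths["prompts"], read_manifests(paths["manifest"]))
        by_key = {
            (s.prompt.participant_id, s.prompt.scheduled_time): s
            for s in data.sessions
        }
        for s in ds.all_sessions():
            loaded = by_key[(s.prompt.participant_id, s.prompt.scheduled_time)]
            assert sorted(a.norm_value for a in loaded.answers) == pytest.approx(
                sorted(a.norm_value for a in s.answers)
            )
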