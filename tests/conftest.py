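import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ema_context import synthetic_data as sd
from ema_context.ema_core import PromptEvent, LikertResponse, ResponseSession


@pytest.fixture(scope="session")
def mini_dataset():
    """A small deterministic two-study dataset shared across tests."""
    return sd.generate_dataset(sd.small_config(n_participants=6, duration_days=10), seed=7)


@pytest.fixture(scope="session")
def ambient_dataset():
    """A small dataset whose participants use the ambient (smart-home) protocol."""
    study = sd.StudyDesign(
        "sh-test", 4, "older", "observational", 7, 10, 1, 5, modality="ambient"
    )
    cfg = sd.GeneratorConfig(studies=(study,))
    return sd.generate_dataset(cfg, seed=11)


@pytest.fixture
def make_session():
    """Factory for hand-built response sessions."""

    def _make(
        n_answered: int,
        n_questions: int = 4,
        when: dt.datetime = dt.datetime(2023, 3, 7, 9, 30),
        participant_id: str = "p1",
        study_id: str = "s1",
        values=None,
        category: str = "sharp",
        elapsed_day: int = 0,
    ) -> ResponseSession:
        answers = tuple(
            LikertResponse(
                question_id=f"q{i + 1}",
                category=category,
                raw_value=(values[i] if values is not None else 3),
                raw_min=1,
                raw_max=5,
                inverted=False,
            )
            for i in range(n_answered)
        )
        prompt = PromptEvent(
            participant_id=participant_id,
            study_id=study_id,
            scheduled_time=when,
            elapsed_day=elapsed_day,
        )
        return ResponseSession(prompt=prompt, answers=answers, n_questions_asked=n_questions)

    return _make
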