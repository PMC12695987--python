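import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vwmdyn import Event, TrialLog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_worked_example_log() -> TrialLog:
    """The narrative example trial: four views, two placements.

    A viewing session opens at t=15.0 s (items A-D viewed for 0.3, 0.5,
    1.2, 0.6 s), then a building session in which B is placed 4.5 s and
    C 5.3 s after their views ended, closing at t=24.0 s.
    """
    events = [
        Event("session_start", "viewing", 15.0),
        Event("view_start", "A", 15.2),
        Event("view_end", "A", 15.5),
        Event("view_start", "B", 15.8),
        Event("view_end", "B", 16.3),
        Event("view_start", "C", 16.6),
        Event("view_end", "C", 17.8),
        Event("view_start", "D", 18.1),
        Event("view_end", "D", 18.7),
        Event("session_end", "viewing", 18.7),
        Event("session_start", "building", 18.7),
        Event("place", "B", 20.8),
        Event("place", "C", 23.1),
        Event("session_end", "building", 24.0),
    ]
    return TrialLog("p001", 1, events)


@pytest.fixture
def worked_example_log() -> TrialLog:
    return make_worked_example_log()


@pytest.fixture
def worked_example_text(worked_example_log) -> str:
    lines = ["participant\ttrial\tkind\titem\ttime_s"]
    for e in worked_example_log.events:
        lines.append(f"p001\t1\t{e.kind}\t{e.item_id}\t{e.time_s:.3f}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
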