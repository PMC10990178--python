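import numpy as np
import pandas as pd
import pytest

from springgait import (
    Anthropometrics,
    ParticipantProfile,
    SimulationConfig,
    StepTiming,
    TrialRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return SimulationConfig()


def make_profile(pid: str, mass=70.0, height=1.78, sn="S", **axes) -> ParticipantProfile:
    labels = {"axis_ei": "E", "axis_sn": sn, "axis_tf": "T", "axis_jp": "J"}
    labels.update(axes)
    return ParticipantProfile(
        participant_id=pid,
        sex="M",
        age=30.0,
        anthropometrics=Anthropometrics(mass=mass, height=height),
        axes=labels,
        weekly_hours=6.0,
    )


def make_trial(pid: str, speed: float, tc: float, tf: float, n_steps: int = 4,
               measured: float | None = None) -> TrialRecord:
    return TrialRecord(
        participant_id=pid,
        requested_speed=speed,
        measured_speed=speed if measured is None else measured,
        steps=tuple(StepTiming(tc, tf) for _ in range(n_steps)),
    )


@pytest.fixture
def two_participant_inputs():
    """2 participants x 3 speeds, all trials valid."""
    profiles = [make_profile("P1"), make_profile("P2", sn="N")]
    trials = []
    for pid, base in (("P1", 0.26), ("P2", 0.24)):
        for speed, shift in ((3.3, 0.0), (4.2, -0.02), (5.0, -0.04)):
            trials.append(make_trial(pid, speed, base + shift, 0.11))
    return profiles, trials


@pytest.fixture
def toy_mixed_df():
    """4 subjects (2 per group) x 3 within-levels, fixed values."""
    values = {
        "s1": [10.0, 12.0, 15.0],
        "s2": [11.0, 13.5, 15.5],
        "s3": [12.5, 15.0, 18.0],
        "s4": [13.0, 16.5, 19.5],
    }
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    rows = [
        {"subject": s, "grp": groups[s], "speed": lvl, "y": v}
        for s, vals in values.items()
        for lvl, v in zip([3.3, 4.2, 5.0], vals)
    ]
    return pd.DataFrame(rows)
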