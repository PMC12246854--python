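import numpy as np
import pytest

from stresskit.io_formats import (
    Channel,
    EDASeries,
    Montage,
    StageSchedule,
    default_montage,
)
from stresskit.synthetic import scaled_config


@pytest.fixture(scope="session")
def montage() -> Montage:
    return default_montage()


@pytest.fixture
def tiny_montage() -> Montage:
    return Montage(
        channels=(
            Channel("Tx1-Rx1", "right", 10),
            Channel("Tx6-Rx5", "left", 10),
        ),
        pairs=(("Tx1-Rx1", "Tx6-Rx5"),),
    )


@pytest.fixture
def short_schedule() -> StageSchedule:
    """Seven 60-s stages, same labels as the full design."""
    labels = ("baseline", "anticipation", "stress", "intermediate", "sound",
              "rest1", "rest2")
    return StageSchedule(tuple(
        (lab, 60.0 * i, 60.0 * (i + 1)) for i, lab in enumerate(labels)))


@pytest.fixture
def small_study_config():
    """Reduced-size study configuration for simulation-backed tests."""
    return scaled_config()


def make_eda(values, fs=4.0, pid="p01", start=0.0, marks=()):
    return EDASeries(participant_id=pid, start_time=start, sample_rate=fs,
                     values=np.asarray(values, dtype=float),
                     event_marks=list(marks))
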