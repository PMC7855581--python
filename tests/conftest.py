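import numpy as np
import pandas as pd
import pytest

from phenocage.core import (
    EntryStream,
    TaskSchedule,
    dlb_arena,
    phenotyper_arena,
    ymaze_arena,
)


@pytest.fixture(scope="session")
def schedule():
    return TaskSchedule()


@pytest.fixture(scope="session")
def ymaze():
    return ymaze_arena()


@pytest.fixture(scope="session")
def dlb():
    return dlb_arena()


@pytest.fixture(scope="session")
def cage():
    return phenotyper_arena()


def stream_from_labels(labels, schedule=None, subject_id="s1", dt=60.0, t0=0.0):
    """EntryStream with the given entrance labels at regular spacing."""
    sched = schedule if schedule is not None else TaskSchedule()
    t = t0 + dt * np.arange(len(labels))
    return EntryStream(subject_id, pd.DataFrame({"t": t, "entrance": list(labels)}),
                       sched)


@pytest.fixture(scope="session")
def make_stream():
    return stream_from_labels
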