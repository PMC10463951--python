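import numpy as np
import pandas as pd
import pytest

from elptools.icage import SECONDS_PER_DAY, TaskSchedule


def make_visits(rows, group="g"):
    """Visit frame from compact (animal, corner, start_s, end_s, np, licks) rows."""
    recs = []
    for r in rows:
        animal, corner, start, end = r[:4]
        np_count = r[4] if len(r) > 4 else 1
        licks = r[5] if len(r) > 5 else 0
        recs.append(
            {
                "animal_id": animal,
                "group": group,
                "corner": corner,
                "start_s": float(start),
                "end_s": float(end),
                "task": "FA",
                "np_count": np_count,
                "np_correct_count": np_count,
                "door_opened": True,
                "lick_count": licks,
                "lick_duration_s": licks * 0.12,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def simple_schedule():
    """Four-task schedule (2 days each) with two animals on corners 1 and 2."""
    seg = pd.DataFrame(
        {
            "task": ["FA", "NP3c", "PPL", "PPLrev"],
            "start_s": [i * 2 * SECONDS_PER_DAY for i in range(4)],
            "end_s": [(i + 1) * 2 * SECONDS_PER_DAY for i in range(4)],
        }
    )
    return TaskSchedule(segments=seg, ppl_corner={"a1": 1, "a2": 2})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
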