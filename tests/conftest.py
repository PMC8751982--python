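import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ethoseq as e

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20211208)


@pytest.fixture
def ethogram_csv(tmp_path):
    """Factory writing an ethogram CSV from a label list."""

    def _write(labels, name="etho.csv", animal_id=None, feed_state=None, header=True):
        p = tmp_path / name
        lines = ["frame,behavior"] if header else []
        if animal_id is not None:
            lines = ["frame,behavior,animal_id,feed_state"]
            lines += [f"{i},{c},{animal_id},{feed_state}" for i, c in enumerate(labels)]
        else:
            lines += [f"{i},{c}" for i, c in enumerate(labels)]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write


def make_sequence(labels, animal_id="a1", feed_state=0, fps=e.DEFAULT_FPS):
    return e.FrameSequence(
        animal_id=animal_id,
        feed_state=feed_state,
        labels=np.array(labels, dtype=object),
        fps=fps,
    )


def make_subsequence(labels, **kw):
    """Single timeout-terminated subsequence from raw labels."""
    seq = make_sequence(labels, **kw)
    subs = e.segment_subsequences(seq)
    assert len(subs) == 1
    return subs[0]


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study shared by read-only tests."""
    return e.simulate_dataset(n_animals=2, seed=11, trial_duration_s=90.0)


@pytest.fixture(scope="session")
def small_subsequences(small_dataset):
    return small_dataset.subsequences()
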