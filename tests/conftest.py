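import numpy as np
import pytest

from stembond.forcecurve import Segment
from stembond.tethering import EventSet, RuptureEvent


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_segment():
    """100-sample approach segment at a constant +3 pN offset."""
    z = np.linspace(0.0, 99.0, 100)
    return Segment(label="approach", piezo_height_nm=z, force_pN=np.full(100, 3.0))


def make_event_set(forces, lengths, probe="anti_FN", sample_id="s1", substrate="soft"):
    events = tuple(
        RuptureEvent(rupture_force_pN=f, rupture_length_nm=length, curve_id=f"c{i}")
        for i, (f, length) in enumerate(zip(forces, lengths))
    )
    return EventSet(
        events=events,
        sample_id=sample_id,
        probe=probe,
        substrate=substrate,
        n_curves_total=len(events),
    )


@pytest.fixture
def lognormal_events(rng):
    """Sample/control event sets drawn from the same broad population."""

    def draw(n, probe, sample_id="s1"):
        f = rng.lognormal(np.log(30), 0.8, n)
        lengths = rng.lognormal(np.log(15), 0.8, n)
        return make_event_set(f, lengths, probe=probe, sample_id=sample_id)

    return draw
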