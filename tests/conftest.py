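import numpy as np
import pytest
from hypothesis import settings

from afterimage import synthetic
from afterimage.session import RecordingSession, TrialRecord, WindowSpec

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

ON_W = WindowSpec("ON", 0.0, 4.0, "odor_onset")
OFF_W = WindowSpec("OFF", 0.0, 4.0, "odor_offset")
ITI_W = WindowSpec("ITI", 0.0, 20.0, "odor_offset")


@pytest.fixture(scope="session")
def locust_session():
    """Locust-like solitary-block spike session, ITI trimmed for speed."""
    cfg = synthetic.locust_like(odors=("bza", "vny", "oct", "nen"),
                                iti_s=24.0, seed=101)
    sess, truth = synthetic.generate_session(cfg)
    return sess, truth


@pytest.fixture(scope="session")
def mouse_session():
    """Mouse-like solitary-block calcium session (raw fluorescence)."""
    cfg = synthetic.mouse_like(n_units=120, iti_s=57.0, seed=202)
    sess, truth = synthetic.generate_session(cfg)
    return sess, truth


@pytest.fixture()
def tiny_spike_session():
    """Hand-written 2-unit, 2-trial spike session."""
    def trial(tid, odor, t0):
        return TrialRecord(
            trial_id=tid, odor=odor, t_start_s=t0, t_end_s=t0 + 10.0,
            odor_sequence=[(odor, t0 + 2.0, t0 + 6.0)],
            activity={
                "pn1": np.array([t0 + 2.01, t0 + 2.04, t0 + 2.06, t0 + 7.0]),
                "pn2": np.array([t0 + 0.5, t0 + 3.0]),
            },
            block_id=0, trial_index_in_block=int(tid[-1]))
    return RecordingSession(
        modality="spikes", units=["pn1", "pn2"],
        trials=[trial("t0", "hex", 0.0), trial("t1", "hex", 20.0)],
        meta={"species": "locust"})
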