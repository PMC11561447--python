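import json

import numpy as np
import pytest

from kdscreen import keystroke_features as kf
from kdscreen import synthetic_data as sd


def ev(t, action, key="A"):
    return kf.RawKeyEvent(timestamp=t, action=action, key_id=key)


def make_session(keystrokes, session_id="s0", participant_id="p0", n_presses=None):
    ks = [kf.Keystroke(p, r, k) for p, r, k in keystrokes]
    ks.sort(key=lambda s: s.press_time)
    return kf.TypingSession(
        session_id=session_id,
        participant_id=participant_id,
        keystrokes=ks,
        n_presses=len(ks) if n_presses is None else n_presses,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_config():
    return sd.CohortConfig(
        hc=sd.default_hc_params(8),
        mci=sd.default_mci_params(6),
        stream=sd.StreamConfig(sessions_mean=4, presses_mean=60),
        seed=11,
    )


@pytest.fixture
def event_log_file(tmp_path):
    """Writer for event-log JSON files built from session dicts."""

    def _write(sessions, name="events.json", ndjson=False):
        path = tmp_path / name
        if ndjson:
            path.write_text("\n".join(json.dumps(s) for s in sessions) + "\n")
        else:
            path.write_text(json.dumps(sessions))
        return path

    return _write
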