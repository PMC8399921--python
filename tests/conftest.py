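import numpy as np
import pytest

import fieldfatigue as ff
from fieldfatigue.labelling import build_timeline


@pytest.fixture(scope="session")
def session1():
    """One-lap synthetic session with aligned streams and a sensor-derived timeline."""
    cfg = ff.ProtocolConfig(n_laps=1, seed=3)
    session = ff.generate_session(cfg)
    streams = ff.align_session(session)
    timeline = build_timeline(
        session.accel[:, 0], session.accel_rate_hz, session.gps,
        cfg.sections, cfg.n_laps,
    )
    return cfg, session, streams, timeline


@pytest.fixture(scope="session")
def walkup128():
    """Default four-lap session windowed on walk_up at W=128 with the LTLF label."""
    cfg = ff.ProtocolConfig(n_laps=4, seed=1)
    session = ff.generate_session(cfg)
    streams = ff.align_session(session)
    timeline = build_timeline(
        session.accel[:, 0], session.accel_rate_hz, session.gps,
        cfg.sections, cfg.n_laps,
    )
    span = streams.length_n / streams.rate_hz
    label = ff.label_from_scores(session.test_scores, span, "LTLF")
    ds = ff.window_activity(streams, timeline, "walk_up", 128, label)
    return session, streams, timeline, label, ds
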