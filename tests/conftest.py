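import numpy as np
import pytest

import sleepderiv as sd


@pytest.fixture(scope="session")
def wake_only_config() -> sd.SimConfig:
    """A single 3-h wake block: no naps, no drift, no dropouts."""
    return sd.SimConfig(
        duration_h=3.0,
        wake_block_min=180.0,
        drift_amplitude_ms=0.0,
        missing_fraction=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def wake_only_beats(wake_only_config) -> sd.BeatSeries:
    _, states = sd.generate_protocol(wake_only_config)
    return sd.generate_rri(states, wake_only_config)


@pytest.fixture(scope="session")
def short_recording() -> sd.SimRecording:
    """A 6-h default-physiology recording shared across tests."""
    cfg = sd.profile_config("S10", duration_h=6.0, seed=42)
    return sd.simulate_recording(cfg)


@pytest.fixture(scope="session")
def short_features(short_recording):
    rec = short_recording
    labels = sd.label_epochs(rec.events, rec.states.span)
    beats, beat_labels = sd.attach_labels(rec.beats, labels)
    fm = sd.build_features(
        beats, beat_labels, {"rc", "rri", "drri", "d2rri"}, resp=rec.resp
    )
    return fm
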