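import numpy as np
import pandas as pd
import pytest

from cuephys.io import SessionBundle, UnitRecord
from cuephys.psth import AlignedTensor, BinGrid
from cuephys.simulate import preset_config, simulate_session


def make_trials(cue_onsets, cue_types):
    onsets = np.asarray(cue_onsets, float)
    return pd.DataFrame(
        {
            "trial_id": np.arange(onsets.size),
            "cue_type": np.asarray(cue_types, dtype=object),
            "cue_onset_s": onsets,
            "lever_onset_s": onsets + 3.0,
            "press_time_s": [np.nan] * onsets.size,
            "omission": [True] * onsets.size,
        }
    )


def make_tensor(counts, cue_types, unit_id="u0"):
    return AlignedTensor(
        unit_id=unit_id,
        counts=np.asarray(counts, dtype=np.int64),
        cue_types=np.asarray(cue_types, dtype=object),
        grid=BinGrid(),
    )


@pytest.fixture
def tiny_bundle():
    """Two hand-written units, four trials (2 DS+ / 2 DS−)."""
    trials = make_trials([10.0, 50.0, 90.0, 130.0], ["DS+", "DS-", "DS+", "DS-"])
    u1 = UnitRecord(
        "u1", "ratA", "control", "day1", "dmPFC",
        spike_times=np.array([9.5, 10.0, 10.2, 50.5, 91.0, 133.2]),
    )
    u2 = UnitRecord(
        "u2", "ratA", "control", "day1", "VTA",
        spike_times=np.array([10.1, 13.05, 52.9, 93.4]),
        waveform_ms=1.4,
    )
    return SessionBundle(
        units=[u1, u2], trials=trials,
        animal_id="ratA", group="control", session="day1",
    )


@pytest.fixture(scope="session")
def control_session():
    """One simulated control session at study-scale trial structure."""
    return simulate_session(
        preset_config("control"), "ratS", "control", "day1", seed=20240
    )
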