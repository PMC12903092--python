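"""Shared fixtures: a hand-built two-electrode well with hand-made detections."""

import numpy as np
import pytest

from meaburst.electrode_bursts import ElectrodeBurst
from meaburst.network_bursts import NetworkBurst
from meaburst.spike_io import SpikeRecording


@pytest.fixture
def hand_recording():
    """Two-electrode, 300 s recording with every spike placed by hand.

    Electrode R1C1: a 5-spike burst at 10 s (ISI 0.05), a 6-spike burst at
    20 s (ISI 0.1), and tonic spikes at 100 and 200 s (13 spikes).
    Electrode R1C2: a 5-spike burst at 10 s (ISI 0.1) and tonic spikes at
    50, 150 and 250 s (8 spikes).
    """
    e1 = np.array([10.0, 10.05, 10.10, 10.15, 10.20,
                   20.0, 20.1, 20.2, 20.3, 20.4, 20.5,
                   100.0, 200.0])
    e2 = np.array([10.0, 10.1, 10.2, 10.3, 10.4,
                   50.0, 150.0, 250.0])
    return SpikeRecording(
        well_id="A1",
        spike_times={"R1C1": e1, "R1C2": e2},
        duration=300.0,
        sampling_rate=1000.0,
        metadata={"group": "ctrl", "DIV": 35},
    )


@pytest.fixture
def hand_ebursts():
    """Electrode bursts consistent with hand_recording, placed by hand."""
    return {
        "R1C1": [
            ElectrodeBurst("R1C1", 10.0, 10.2, 5),
            ElectrodeBurst("R1C1", 20.0, 20.5, 6),
        ],
        "R1C2": [ElectrodeBurst("R1C2", 10.0, 10.4, 5)],
    }


@pytest.fixture
def hand_nbursts():
    """Classified network bursts consistent with hand_recording.

    Two main bursts covering the synchronous firing, plus one fragment
    trailing the second main burst by 0.45 s.
    """
    return [
        NetworkBurst(9.95, 10.55, frozenset({"R1C1", "R1C2"}), "main", None),
        NetworkBurst(19.95, 20.55, frozenset({"R1C1"}), "main", None),
        NetworkBurst(21.0, 21.2, frozenset(), "fragment", 1),
    ]
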