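import numpy as np
import pytest

from cortiwave import GridGeometry, NoiseSpec, WaveSpec
from cortiwave.events import SpikeEvent
from cortiwave.synth import gen_plane_wave_event, gen_spiral_wave_event


@pytest.fixture
def grid8() -> GridGeometry:
    return GridGeometry()


@pytest.fixture
def grid_bad5() -> GridGeometry:
    """8x8 grid with three high-impedance channels flagged bad."""
    return GridGeometry(bad_channels=frozenset({5, 17, 60}))


def recording_as_event(rec, event_id=0, context="interictal"):
    """Wrap a standalone generated event recording as a SpikeEvent."""
    return SpikeEvent(event_id=event_id, window=(rec.t0, rec.t0 + rec.duration),
                      segment=rec.data, context=context, peak_channel=0,
                      peak_time=rec.t0, fs=rec.fs, geometry=rec.geometry)


def make_wave_events(geometry, n_each=10, noise_sd=200.0, fs=1000.0, seed0=100):
    """Interleaved right-to-left / left-to-right / spiral events with labels.

    noise_sd=200 uV against 2000 uV spikes is an amplitude SNR of 10.
    """
    events, labels = [], []
    for i in range(3 * n_each):
        kind = i % 3
        noise = NoiseSpec(white_sd=noise_sd, common_mode_amplitude=0.0,
                          seed=seed0 + i)
        if kind == 0:
            rec, _ = gen_plane_wave_event(geometry, fs,
                                          WaveSpec.plane(direction=(-1, 0)), noise)
            labels.append("right_to_left")
        elif kind == 1:
            rec, _ = gen_plane_wave_event(geometry, fs,
                                          WaveSpec.plane(direction=(1, 0)), noise)
            labels.append("left_to_right")
        else:
            rec, _ = gen_spiral_wave_event(geometry, fs, WaveSpec.spiral(), noise)
            labels.append("spiral")
        events.append(recording_as_event(rec, event_id=i))
    return events, labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
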