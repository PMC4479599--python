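import numpy as np
import pytest

from lombardlab import acoustics, call_synth


@pytest.fixture(scope="session")
def clc_spec():
    return call_synth.default_clc_spec()


@pytest.fixture(scope="session")
def chirp_spec():
    return call_synth.default_chirp_spec()


@pytest.fixture(scope="session")
def rendered_clc(clc_spec):
    """Rendered baseline long call with its annotation and measurements."""
    clip, ann = call_synth.synth_call(clc_spec)
    meas = acoustics.measure_call(clip, ann, acoustics.NoiseStats.silent())
    return clip, ann, meas


@pytest.fixture(scope="session")
def rendered_chirp(chirp_spec):
    clip, ann = call_synth.synth_call(chirp_spec)
    meas = acoustics.measure_call(clip, ann, acoustics.NoiseStats.silent())
    return clip, ann, meas


@pytest.fixture(scope="session")
def truth_summaries():
    """Trial summaries of one seeded parameter-level experiment (3 x 12)."""
    from lombardlab import stats

    cfg = call_synth.make_default_config(3, seed=42)
    return stats.aggregate(call_synth.simulate_truth(cfg))


def measured_band_edges(psd, low_hz, high_hz):
    """-3 dB (half of in-band median density) edge frequencies of a PSD."""
    inband = (psd.freqs >= low_hz) & (psd.freqs <= high_hz)
    ref = np.median(psd.power[inband])
    above = np.flatnonzero(psd.power >= ref / 2)
    return float(psd.freqs[above[0]]), float(psd.freqs[above[-1]])
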