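import numpy as np
import pytest

from cardioema import signals, synthdata


@pytest.fixture(scope="session")
def steady_recording():
    """60 s noise-free recording: IBI 1000 ms, PEP 100 ms, LVET 300 ms."""
    return synthdata.generate_raw_recording(np.full(60, 1000.0), seed=0)


@pytest.fixture(scope="session")
def steady_beats(steady_recording):
    rec = steady_recording
    ecg = signals.filter_ecg(rec.ecg, rec.fs)
    return signals.qc_ibi(signals.detect_r_peaks(ecg, rec.fs))


def make_beats(ibi_ms, start_s=0.0):
    """BeatSeries from an IBI trajectory, all beats accepted."""
    return signals.BeatSeries.from_ibi(np.asarray(ibi_ms, float), start_s)
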