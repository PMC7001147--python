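"""Reading audio and exporting waveforms, traces and analysis tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .characterize import AutocorrResult, CorrelationMap, SpectrumEstimate
from .envelope import StimulationWaveform, Waveform
from .staircase import StaircaseTrace

__all__ = [
    "read_wav",
    "write_wav",
    "current_to_csv",
    "spectrum_to_csv",
    "autocorr_to_csv",
    "correlation_map_to_csv",
    "trace_to_csv",
]


def read_wav(path) -> Waveform:
    """Read a mono PCM or float WAV file; integer formats are scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path} has {data.shape[1]} channels; only mono audio is supported — "
            "mix down or extract one channel first"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(samples=data, rate=float(rate))


def write_wav(path, wave: Waveform) -> None:
    wavfile.write(path, int(wave.rate), wave.samples.astype(np.float32))


def current_to_csv(path, current: StimulationWaveform) -> None:
    pd.DataFrame(
        {"time_s": current.times_s, "current_mA": current.samples}
    ).to_csv(path, index=False)


def spectrum_to_csv(path, spectrum: SpectrumEstimate) -> None:
    pd.DataFrame(
        {"freq_hz": spectrum.frequencies, "amplitude": spectrum.amplitudes}
    ).to_csv(path, index=False)


def autocorr_to_csv(path, result: AutocorrResult) -> None:
    pd.DataFrame({"lag_ms": result.lags_ms, "r": result.r}).to_csv(path, index=False)


def correlation_map_to_csv(path, cmap: CorrelationMap) -> None:
    phases, lags = np.meshgrid(cmap.phases_deg, cmap.lags_ms, indexing="ij")
    pd.DataFrame(
        {
            "phase_deg": phases.ravel(),
            "lag_ms": lags.ravel(),
            "r": cmap.corr.ravel(),
        }
    ).to_csv(path, index=False)


def trace_to_csv(path, trace: StaircaseTrace) -> None:
    pd.DataFrame(
        {
            "trial": [t.index for t in trace.trials],
            "snr_db": [t.snr_db for t in trace.trials],
            "n_correct": [t.n_correct for t in trace.trials],
            "passed": [t.passed for t in trace.trials],
            "is_reversal": [t.is_reversal for t in trace.trials],
        }
    ).to_csv(path, index=False)
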