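"""Stimulation-waveform construction from speech envelopes.

The stimulation current used for envelope-tACS is a phase- and latency-shifted
copy of the slow (< 12 Hz) amplitude envelope of the target speech.  The phase
shift is defined through the analytic signal: writing the zero-mean envelope as
y(t) and its Hilbert transform as H[y](t), the complexification
z(t) = y(t) + iH[y](t) rotates under multiplication by exp(i*phi), and the
phase-shifted envelope is Re[exp(i*phi) z(t)].  A shift of 180 deg is therefore
exactly the inversion of the (zero-mean) envelope, and a shift of 360 deg the
identity — unlike a time delay, which decorrelates a broadband envelope.

This module provides the envelope extraction, the phase and latency shift, and
the conditioning of the final current (mean removal, half-sine onset/offset
ramps, amplitude normalisation) together with the sixteen-condition battery
used in the experiment (sham burst, DC anodal/cathodal, unrelated envelope,
and envelope-tACS at 6 phases x 2 latencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import firwin, hilbert

__all__ = [
    "Waveform",
    "Envelope",
    "AnalyticEnvelope",
    "StimulationWaveform",
    "StimulationCondition",
    "ENV_TACS_PHASES_DEG",
    "ENV_TACS_LATENCIES_MS",
    "all_conditions",
    "extract_envelope",
    "analytic_envelope",
    "phase_shift_envelope",
    "delay_envelope",
    "condition_current",
    "make_condition_current",
]

#: Phase shifts (degrees) probed in the envelope-tACS conditions.
ENV_TACS_PHASES_DEG = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)

#: Stimulation latencies (ms) of the current relative to the audio.
ENV_TACS_LATENCIES_MS = (100.0, 250.0)


def _as_float_array(samples: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"{name} must contain at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite samples")
    return arr


@dataclass(frozen=True)
class Waveform:
    """A sampled real signal (e.g. the speech audio), in arbitrary units."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", _as_float_array(self.samples, "samples"))
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n) / self.rate


@dataclass(frozen=True)
class Envelope(Waveform):
    """A (speech) envelope.  ``is_raw`` marks a nonnegative, unconditioned one."""

    is_raw: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.is_raw and np.any(self.samples < 0):
            raise ValueError("raw envelopes must be nonnegative")


@dataclass(frozen=True)
class AnalyticEnvelope:
    """Complex analytic representation z = y + iH[y] of a zero-mean envelope."""

    samples: np.ndarray
    rate: float

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StimulationWaveform(Waveform):
    """A conditioned stimulation current in mA.

    Starts and ends at exactly 0 mA and never exceeds ``max_abs_mA`` in
    magnitude.  ``is_zero`` flags the degenerate case of a constant input
    envelope, which conditions to the all-zero current.
    """

    max_abs_mA: float = 1.0
    is_zero: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.max_abs_mA > 0:
            raise ValueError("max_abs_mA must be positive")
        if self.samples[0] != 0.0 or self.samples[-1] != 0.0:
            raise ValueError("stimulation currents must begin and end at 0 mA")
        if np.max(np.abs(self.samples)) > self.max_abs_mA * (1 + 1e-12):
            raise ValueError("stimulation current exceeds max_abs_mA")


_KINDS = ("sham", "dc_plus", "dc_minus", "unrelated_env", "env_tacs")


@dataclass(frozen=True)
class StimulationCondition:
    """One of the 16 stimulation conditions of the battery.

    ``phase_deg`` and ``latency_ms`` are present if and only if
    ``kind == "env_tacs"``.
    """

    kind: str
    phase_deg: float | None = None
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "env_tacs":
            if self.phase_deg is None or self.latency_ms is None:
                raise ValueError("env_tacs conditions require phase_deg and latency_ms")
            if self.phase_deg not in ENV_TACS_PHASES_DEG:
                raise ValueError(f"phase_deg must be one of {ENV_TACS_PHASES_DEG}")
            if self.latency_ms not in ENV_TACS_LATENCIES_MS:
                raise ValueError(f"latency_ms must be one of {ENV_TACS_LATENCIES_MS}")
        elif self.phase_deg is not None or self.latency_ms is not None:
            raise ValueError("phase/latency are only defined for env_tacs conditions")

    @property
    def label(self) -> str:
        if self.kind == "env_tacs":
            return f"env_tacs_p{int(self.phase_deg)}_l{int(self.latency_ms)}"
        return self.kind


def all_conditions() -> list[StimulationCondition]:
    """Enumerate the 16-condition battery: 4 controls + 6 phases x 2 latencies."""
    conds = [
        StimulationCondition("sham"),
        StimulationCondition("dc_plus"),
        StimulationCondition("dc_minus"),
        StimulationCondition("unrelated_env"),
    ]
    for tau in ENV_TACS_LATENCIES_MS:
        for phi in ENV_TACS_PHASES_DEG:
            conds.append(StimulationCondition("env_tacs", phase_deg=phi, latency_ms=tau))
    return conds


# --------------------------------------------------------------------------
# envelope extraction


def extract_envelope(audio: Waveform, cutoff_hz: float = 12.0) -> Envelope:
    """Extract the slow amplitude envelope of an audio signal.

    The envelope is the magnitude of the analytic signal, low-pass filtered
    with a linear-phase FIR filter (Hamming-windowed sinc) whose group delay
    is compensated so the envelope stays time-aligned with the audio.

    Parameters
    ----------
    audio : Waveform
        Mono audio signal.
    cutoff_hz : float
        Low-pass cut-off; must lie below the Nyquist frequency.
    """
    if not cutoff_hz < audio.rate / 2:
        raise ValueError(
            f"cutoff_hz={cutoff_hz} must be below the Nyquist frequency {audio.rate / 2}"
        )
    numtaps = int(round(6 * audio.rate / cutoff_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    if audio.n <= numtaps:
        raise ValueError(
            f"audio too short for envelope extraction: need more than {numtaps} "
            f"samples (6 / cutoff seconds), got {audio.n}"
        )
    magnitude = np.abs(hilbert(audio.samples))
    taps = firwin(numtaps, cutoff_hz, window="hamming", fs=audio.rate)
    # 'same'-mode convolution with a symmetric FIR centres the filter, which
    # compensates the (numtaps-1)/2 group delay.
    smoothed = np.convolve(magnitude, taps, mode="same")
    # Rectify tiny filter undershoots so the raw envelope stays nonnegative.
    np.maximum(smoothed, 0.0, out=smoothed)
    return Envelope(samples=smoothed, rate=audio.rate, is_raw=True)


# --------------------------------------------------------------------------
# analytic signal and phase shift


def analytic_envelope(env: Envelope, pad: int | None = 0) -> AnalyticEnvelope:
    """Analytic representation z = y0 + iH[y0] of the mean-removed envelope.

    The mean is removed before complexification: rotating the analytic signal
    of an envelope with a DC offset would mix that offset into every phase,
    whereas the zero-mean convention makes a 180 deg shift an exact inversion.

    ``pad`` controls reflect-padding (samples on each side) applied before the
    FFT-based Hilbert transform.  The default of 0 keeps the transform a pure
    spectral rotation, so repeated phase shifts compose exactly and the
    amplitude spectrum is preserved bit-for-bit; padding (``None`` selects
    half a second, about one low-pass filter length) trades those exact
    algebraic properties for smaller transient errors at the signal edges.
    """
    y0 = env.samples - env.samples.mean()
    n = y0.size
    if pad is None:
        pad = min(n - 1, int(round(env.rate / 2)))
    if pad > 0:
        padded = np.concatenate([y0[pad:0:-1], y0, y0[-2 : -2 - pad : -1]])
        z = hilbert(padded)[pad : pad + n]
        # keep the real part exactly equal to the zero-mean source
        z = y0 + 1j * z.imag
    else:
        z = hilbert(y0)
    return AnalyticEnvelope(samples=z, rate=env.rate)


def _cos_sin_deg(phi_deg: float) -> tuple[float, float]:
    phi = float(phi_deg) % 360.0
    exact = {0.0: (1.0, 0.0), 90.0: (0.0, 1.0), 180.0: (-1.0, 0.0), 270.0: (0.0, -1.0)}
    if phi in exact:
        return exact[phi]
    rad = np.deg2rad(phi)
    return float(np.cos(rad)), float(np.sin(rad))


def phase_shift_envelope(env: Envelope, phi_deg: float, pad: int | None = 0) -> Envelope:
    """Shift every spectral component of the envelope by ``phi_deg`` degrees.

    Returns Re[exp(i*phi) z(t)] where z is the analytic signal of the
    zero-mean envelope.  The output is zero-mean; its amplitude spectrum is
    identical to the input's at every nonzero frequency.  Positive phi maps
    cos(w t) to cos(w t + phi) (a phase advance).  phi is wrapped to
    [0, 360).
    """
    z = analytic_envelope(env, pad=pad)
    c, s = _cos_sin_deg(phi_deg)
    # Re[e^{i phi}(y0 + i h)] = cos(phi) y0 - sin(phi) h
    out = c * z.samples.real - s * z.samples.imag
    return Envelope(samples=out, rate=env.rate, is_raw=False)


# --------------------------------------------------------------------------
# latency shift


def delay_envelope(env: Envelope, tau_ms: float) -> Envelope:
    """Delay the envelope by ``tau_ms`` milliseconds (nearest-sample quantised).

    The output at time t equals the input at t - tau; the leading gap is
    zero-filled and the length is preserved.  A negative ``tau_ms`` advances
    the signal (trailing gap zero-filled); this extension is used when
    scanning correlation maps over negative lags.
    """
    shift = int(round(tau_ms / 1000.0 * env.rate))
    if abs(shift) >= env.n:
        raise ValueError(
            f"delay of {tau_ms} ms ({abs(shift)} samples) exceeds the signal "
            f"duration ({env.n} samples)"
        )
    if shift == 0:
        return Envelope(samples=env.samples.copy(), rate=env.rate, is_raw=env.is_raw)
    out = np.zeros_like(env.samples)
    if shift > 0:
        out[shift:] = env.samples[:-shift]
    else:
        out[:shift] = env.samples[-shift:]
    return Envelope(samples=out, rate=env.rate, is_raw=env.is_raw)


# --------------------------------------------------------------------------
# current conditioning


def _half_sine_ramps(n: int, n_ramp: int) -> np.ndarray:
    """Unit taper: half-sine 0->1 over the first and 1->0 over the last n_ramp."""
    taper = np.ones(n)
    if n_ramp > 1:
        ramp = np.sin(np.pi / 2 * np.arange(n_ramp) / (n_ramp - 1))
        taper[:n_ramp] = ramp
        taper[-n_ramp:] = ramp[::-1]
    else:
        taper[0] = 0.0
        taper[-1] = 0.0
    return taper


def condition_current(
    env: Envelope, max_abs_mA: float, ramp_ms: float = 250.0
) -> StimulationWaveform:
    """Turn an envelope into a safe stimulation current.

    Subtracts the mean (so the current alternates around zero), applies
    half-sine onset/offset ramps of ``ramp_ms`` so the current begins and ends
    at exactly 0 mA, and rescales so the peak magnitude equals ``max_abs_mA``.

    A constant input has nothing left after mean subtraction; it conditions to
    the all-zero current, flagged with ``is_zero`` instead of dividing by zero.
    """
    if not max_abs_mA > 0:
        raise ValueError("max_abs_mA must be positive")
    n_ramp = int(round(ramp_ms / 1000.0 * env.rate))
    if 2 * n_ramp >= env.n:
        raise ValueError(
            f"2*ramp_ms={2 * ramp_ms} ms does not fit in the {env.duration_s * 1000:.0f} ms signal"
        )
    x = env.samples - env.samples.mean()
    tapered = x * _half_sine_ramps(env.n, max(n_ramp, 1))
    peak = np.max(np.abs(tapered))
    if peak == 0.0:
        return StimulationWaveform(
            samples=np.zeros(env.n), rate=env.rate, max_abs_mA=max_abs_mA, is_zero=True
        )
    out = tapered / peak * max_abs_mA
    return StimulationWaveform(samples=out, rate=env.rate, max_abs_mA=max_abs_mA)


def _dc_current(
    n: int, rate: float, max_abs_mA: float, sign: float, ramp_ms: float
) -> StimulationWaveform:
    n_ramp = int(round(ramp_ms / 1000.0 * rate))
    out = sign * max_abs_mA * _half_sine_ramps(n, max(n_ramp, 1))
    return StimulationWaveform(samples=out, rate=rate, max_abs_mA=max_abs_mA)


def make_condition_current(
    target_env: Envelope,
    unrelated_env: Envelope | None,
    cond: StimulationCondition,
    max_abs_mA: float,
    ramp_ms: float = 250.0,
    sham_duration_ms: float = 500.0,
    sham_ramp_ms: float = 100.0,
) -> StimulationWaveform:
    """Build the stimulation current for any of the 16 conditions.

    env_tacs applies phase shift, then latency shift, then conditioning to the
    target envelope; unrelated_env conditions the unrelated envelope without
    shifts; dc_plus/dc_minus are constant +/- max_abs_mA plateaus between
    onset/offset ramps; sham is a tapered burst confined to the first
    ``sham_duration_ms`` (the burst shape is the conditioned opening of the
    target envelope), zero everywhere else.
    """
    n, rate = target_env.n, target_env.rate
    if cond.kind == "env_tacs":
        shifted = phase_shift_envelope(target_env, cond.phase_deg)
        delayed = delay_envelope(shifted, cond.latency_ms)
        return condition_current(delayed, max_abs_mA, ramp_ms=ramp_ms)
    if cond.kind == "unrelated_env":
        if unrelated_env is None:
            raise ValueError("unrelated_env condition requires an unrelated envelope")
        if unrelated_env.rate != rate:
            raise ValueError("target and unrelated envelopes must share the sampling rate")
        return condition_current(unrelated_env, max_abs_mA, ramp_ms=ramp_ms)
    if cond.kind in ("dc_plus", "dc_minus"):
        sign = 1.0 if cond.kind == "dc_plus" else -1.0
        return _dc_current(n, rate, max_abs_mA, sign, ramp_ms)
    if cond.kind == "sham":
        n_burst = int(round(sham_duration_ms / 1000.0 * rate))
        if n_burst < 4 or n_burst > n:
            raise ValueError("sham burst duration must fit within the stimulus")
        burst_env = Envelope(samples=target_env.samples[:n_burst], rate=rate)
        burst = condition_current(burst_env, max_abs_mA, ramp_ms=sham_ramp_ms)
        out = np.zeros(n)
        out[:n_burst] = burst.samples
        return StimulationWaveform(samples=out, rate=rate, max_abs_mA=max_abs_mA)
    raise ValueError(f"unknown condition kind {cond.kind!r}")
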