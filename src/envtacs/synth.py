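"""Synthetic study data with known ground truth.

No behavioural data accompany the study design this package implements, so
every pipeline stage is exercised on simulated inputs: speech-like envelopes
whose spectra peak near 2 Hz and stay below 12 Hz, and per-subject SRT
records for the full 16-condition battery in which the phase effect follows
the multiperiodic cosine model with known amplitudes and offsets.  Recovery
of those known parameters is the package's primary correctness surface.

All default effect sizes are generator choices (the study never published its
fitted amplitudes); they are loosely scaled to the fitted-curve extrema the
study reports (about -1 to +2 dB around sham) and to the 2 dB penalty of the
unrelated-envelope control.

Randomness is organised as one independent stream per (seed, subject,
condition) via ``numpy``'s ``SeedSequence`` spawning, so enlarging the
subject pool never perturbs existing records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .envelope import (
    ENV_TACS_LATENCIES_MS,
    ENV_TACS_PHASES_DEG,
    Envelope,
    StimulationCondition,
    all_conditions,
    delay_envelope,
)
from .multiperiodic import LinearResponseModel, PhaseProfile, linear_response_profile
from .staircase import PsychometricListener, StaircaseParams, StaircaseTrace, run_staircase

__all__ = [
    "GroundTruth",
    "SubjectDataset",
    "gen_speech_like_envelope",
    "gen_dataset",
    "gen_linear_listener",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = ("subject", "kind", "phase_deg", "latency_ms", "srt_db")


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters against which recovery is scored.

    The phase effect of env-tACS at latency tau is
    sum_k a_k cos(k phi - psi_k) (dB around the subject's baseline), with
    separate amplitudes/offsets per latency.  Controls get constant offsets.
    """

    amp_100: tuple[float, float, float] = (0.9, 0.7, 0.4)
    psi_100: tuple[float, float, float] = (74.0, 30.0, 180.0)
    amp_250: tuple[float, float, float] = (1.0, 0.8, 0.6)
    psi_250: tuple[float, float, float] = (244.0, 90.0, 0.0)
    unrelated_env_penalty_db: float = 2.0
    dc_effect_db: float = 0.0
    sham_effect_db: float = 0.0
    subject_sd_db: float = 1.0
    residual_sd_db: float = 0.5
    slope_db: float = 1.0
    lapse: float = 0.0
    n_subjects: int = 17
    baseline_srt_db: float = -6.0
    #: Optional explicit phase effects {latency_ms: {phase_deg: dB}} that
    #: override the cosine model (used by the linear-response listener).
    phase_effect_overrides: Mapping[float, Mapping[float, float]] | None = None

    def __post_init__(self) -> None:
        for amps in (self.amp_100, self.amp_250):
            if any(a < 0 for a in amps):
                raise ValueError("amplitudes must be nonnegative")
        if self.subject_sd_db < 0 or self.residual_sd_db < 0:
            raise ValueError("standard deviations must be nonnegative")

    def phase_effect(self, phase_deg: float, latency_ms: float) -> float:
        """Programmed env-tACS effect (dB) at one phase and latency."""
        if self.phase_effect_overrides is not None:
            return float(self.phase_effect_overrides[latency_ms][phase_deg])
        amps, psis = (
            (self.amp_100, self.psi_100)
            if latency_ms == 100.0
            else (self.amp_250, self.psi_250)
        )
        phi = np.deg2rad(phase_deg)
        return float(
            sum(
                a * np.cos(k * phi - np.deg2rad(psi))
                for k, (a, psi) in enumerate(zip(amps, psis), start=1)
            )
        )

    def condition_effect(self, cond: StimulationCondition) -> float:
        if cond.kind == "sham":
            return self.sham_effect_db
        if cond.kind in ("dc_plus", "dc_minus"):
            return self.dc_effect_db
        if cond.kind == "unrelated_env":
            return self.unrelated_env_penalty_db
        return self.phase_effect(cond.phase_deg, cond.latency_ms)


@dataclass(frozen=True)
class SubjectDataset:
    """SRT records for all 16 conditions x n_subjects, plus provenance."""

    df: pd.DataFrame
    seed: int
    truth: GroundTruth | None = None
    mode: str = "direct"
    traces: Mapping[tuple[str, str], StaircaseTrace] | None = None

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        counts = self.df.groupby("subject").size()
        if not (counts == 16).all():
            bad = counts[counts != 16]
            raise ValueError(f"every subject needs 16 conditions; offending: {dict(bad)}")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject"].unique())

    def sham_normalized(self) -> pd.DataFrame:
        """SRTs with each subject's sham SRT subtracted (sham maps to 0 dB)."""
        df = self.df.copy()
        sham = df[df["kind"] == "sham"].set_index("subject")["srt_db"]
        df["srt_db"] = df["srt_db"] - df["subject"].map(sham).to_numpy()
        return df

    def phase_profiles(
        self, latency_ms: float, normalized: bool = True
    ) -> list[PhaseProfile]:
        """One six-point profile per subject at the given latency."""
        df = self.sham_normalized() if normalized else self.df
        rows = df[(df["kind"] == "env_tacs") & (df["latency_ms"] == latency_ms)]
        profiles = []
        for subject, grp in rows.groupby("subject"):
            grp = grp.sort_values("phase_deg")
            profiles.append(
                PhaseProfile(
                    phases_deg=grp["phase_deg"].to_numpy(float),
                    srt_db=grp["srt_db"].to_numpy(float),
                    latency_ms=latency_ms,
                    subject=str(subject),
                )
            )
        return profiles

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=list(DATASET_COLUMNS))

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "SubjectDataset":
        return cls(df=pd.read_csv(path), seed=seed)


# --------------------------------------------------------------------------
# speech-like envelopes


def gen_speech_like_envelope(
    duration_s: float, rate: float = 100.0, seed: int = 0
) -> Envelope:
    """Nonnegative broadband envelope emulating natural speech dynamics.

    Complex Gaussian spectral noise is shaped by an amplitude profile made of
    a Gaussian bump centred at 2 Hz (sigma 2.5 Hz, amplitude 1.5) on top of a
    unit broadband floor, rolled off smoothly between 9.5 and 12 Hz and zero above; the
    inverse transform is shifted to nonnegativity (leaving the spectrum
    untouched at every nonzero frequency).  The floor is what keeps the
    autocorrelation localised near lag zero — a narrow 2 Hz peak alone would
    ring at 500 ms — while the bump fixes the spectral peak near 2 Hz, the two
    features the target speech material exhibits.
    """
    if duration_s < 4.0:
        raise ValueError("envelopes must be at least 4 s long")
    n = int(round(duration_s * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    profile = 1.5 * np.exp(-((freqs - 2.0) ** 2) / (2 * 2.5**2)) + 1.0
    rolloff = np.clip((12.0 - freqs) / 2.5, 0.0, 1.0)
    profile = profile * np.sin(np.pi / 2 * rolloff) ** 2
    profile[freqs > 12.0] = 0.0
    rng = np.random.default_rng(seed)
    spec = profile * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    y = x - x.min()
    return Envelope(samples=y, rate=rate, is_raw=True)


# --------------------------------------------------------------------------
# full datasets


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def gen_dataset(
    truth: GroundTruth,
    seed: int = 0,
    mode: str = "direct",
    staircase_params: StaircaseParams | None = None,
    keep_traces: bool = False,
) -> SubjectDataset:
    """Simulate SRTs for every subject and condition.

    mode='direct' draws srt = baseline + b_s + effect + Normal(0, residual_sd)
    with the subject offset b_s ~ Normal(0, subject_sd); mode='staircase'
    instead equips a psychometric listener with that true threshold and runs
    the full closed-loop adaptive procedure, so staircase estimation noise
    replaces the residual term.
    """
    if mode not in ("direct", "staircase"):
        raise ValueError(f"unknown mode {mode!r}; expected 'direct' or 'staircase'")
    params = staircase_params or StaircaseParams()
    conds = all_conditions()
    rows = []
    traces: dict[tuple[str, str], StaircaseTrace] = {}
    for s in range(truth.n_subjects):
        subject = f"S{s:02d}"
        b_s = truth.subject_sd_db * _stream(seed, s, 10_000).standard_normal()
        for ci, cond in enumerate(conds):
            rng = _stream(seed, s, ci)
            srt_true = truth.baseline_srt_db + b_s + truth.condition_effect(cond)
            if mode == "direct":
                srt = srt_true + truth.residual_sd_db * rng.standard_normal()
            else:
                listener = PsychometricListener(
                    srt_true_db=srt_true, slope_db=truth.slope_db, lapse=truth.lapse
                )
                trace = run_staircase(listener, params, rng)
                srt = trace.srt_db
                if keep_traces:
                    traces[(subject, cond.label)] = trace
            rows.append(
                {
                    "subject": subject,
                    "kind": cond.kind,
                    "phase_deg": cond.phase_deg if cond.phase_deg is not None else np.nan,
                    "latency_ms": cond.latency_ms if cond.latency_ms is not None else np.nan,
                    "srt_db": srt,
                }
            )
    df = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    return SubjectDataset(
        df=df, seed=seed, truth=truth, mode=mode, traces=traces if keep_traces else None
    )


# --------------------------------------------------------------------------
# linear-response listener


def gen_linear_listener(
    kernel_spec: str = "random",
    seed: int = 0,
    rate: float = 100.0,
    env_duration_s: float = 8.0,
    kernel_duration_s: float = 0.5,
    effect_scale_db: float = 1.0,
) -> tuple[LinearResponseModel, GroundTruth]:
    """A virtual subject whose phase effects obey linear-response theory.

    The susceptibility kernel is either a smooth random kernel, a unit
    impulse at lag zero, or identically zero.  Phase effects are computed by
    convolving the kernel with phase- and latency-shifted copies of one
    speech-like envelope and rescaling the strongest latency profile to peak
    at ``effect_scale_db``; a linear rescale preserves the forced
    sinusoidality, so downstream analysis must classify such data as linear
    (or as no modulation when the kernel vanishes).
    """
    if kernel_spec not in ("random", "impulse", "zero"):
        raise ValueError("kernel_spec must be 'random', 'impulse' or 'zero'")
    n_k = max(int(round(kernel_duration_s * rate)), 1)
    rng = np.random.default_rng(seed)
    if kernel_spec == "random":
        raw = rng.standard_normal(n_k)
        width = max(n_k // 10, 1)
        smooth = np.convolve(raw, np.hanning(width + 2), mode="same")
        kernel = smooth
    elif kernel_spec == "impulse":
        kernel = np.zeros(n_k)
        kernel[0] = 1.0
    else:
        kernel = np.zeros(n_k)

    env = gen_speech_like_envelope(env_duration_s, rate=rate, seed=seed + 1)
    model = LinearResponseModel(
        kernel=kernel, rate=rate, t_a=1.0, t_b=env_duration_s - 1.0
    )
    overrides: dict[float, dict[float, float]] = {}
    peak = 0.0
    for tau in ENV_TACS_LATENCIES_MS:
        delayed = delay_envelope(env, tau)
        prof = linear_response_profile(model, delayed, ENV_TACS_PHASES_DEG)
        overrides[tau] = dict(zip(ENV_TACS_PHASES_DEG, prof.srt_db))
        peak = max(peak, float(np.max(np.abs(prof.srt_db))))
    if peak > 0:
        scale = effect_scale_db / peak
        overrides = {
            tau: {phi: v * scale for phi, v in d.items()} for tau, d in overrides.items()
        }
    truth = GroundTruth(
        phase_effect_overrides=overrides,
        residual_sd_db=0.2,
    )
    return model, truth
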