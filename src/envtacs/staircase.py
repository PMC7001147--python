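"""Adaptive up-down estimation of the sentence reception threshold (SRT).

Each trial presents a five-keyword sentence at some signal-to-noise ratio
(SNR).  If the listener repeats at least half of the keywords, the next
sentence is presented at a lower SNR; otherwise at a higher one.  The SNR
starts at 10 dB and moves in 3 dB steps until four reversals (changes of
direction) have occurred, then in 1 dB steps.  The SRT — the SNR at which the
listener gets 50% of keywords right — is the mean SNR of the last ten of the
(around 25) presentations.

With symmetric steps this rule converges to the level where the probability
of passing a sentence is 1/2; for a five-keyword binomial listener with
per-keyword probability p, P(at least 3 of 5) = 1/2 exactly when p = 1/2, so
the procedure targets the per-keyword 50% point.

A simulated listener with a logistic psychometric function closes the loop so
the procedure can be exercised, calibrated, and fed into dataset generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "StaircaseParams",
    "TrialRecord",
    "StaircaseTrace",
    "PsychometricListener",
    "keyword_pass",
    "staircase_update",
    "simulate_trial",
    "run_staircase",
]


@dataclass(frozen=True)
class StaircaseParams:
    """Step schedule of the adaptive procedure (all levels in dB SNR)."""

    initial_snr_db: float = 10.0
    big_step_db: float = 3.0
    small_step_db: float = 1.0
    reversals_before_small: int = 4
    n_trials: int = 25
    n_tail: int = 10
    pass_fraction: float = 0.5
    #: Up/down step-size ratio; 1.0 is the symmetric rule targeting 50%.
    up_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.big_step_db <= 0 or self.small_step_db <= 0:
            raise ValueError("step sizes must be positive")
        if not 0 < self.pass_fraction < 1:
            raise ValueError("pass_fraction must lie in (0, 1)")
        if self.n_tail > self.n_trials:
            raise ValueError("n_tail cannot exceed n_trials")
        if self.up_weight <= 0:
            raise ValueError("up_weight must be positive")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    snr_db: float
    n_keywords: int
    n_correct: int
    passed: bool
    is_reversal: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_keywords:
            raise ValueError("n_correct must lie in [0, n_keywords]")


@dataclass(frozen=True)
class StaircaseTrace:
    """A completed staircase run with its derived threshold."""

    trials: tuple[TrialRecord, ...]
    reversal_indices: tuple[int, ...]
    srt_db: float

    @property
    def snrs_db(self) -> np.ndarray:
        return np.array([t.snr_db for t in self.trials])


@dataclass(frozen=True)
class PsychometricListener:
    """Virtual subject: per-keyword logistic psychometric function.

    The probability of reporting one keyword correctly at a given SNR is
    (1 - lapse) * logistic((snr - srt_true_db) / slope_db); ``srt_true_db``
    is the 50% point (for lapse = 0) and ``slope_db`` the spread.
    """

    srt_true_db: float
    slope_db: float = 1.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_db <= 0:
            raise ValueError("slope_db must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")

    def p_keyword(self, snr_db: float) -> float:
        x = (snr_db - self.srt_true_db) / self.slope_db
        return float((1.0 - self.lapse) * expit(x))


def keyword_pass(n_correct: int, n_keywords: int, pass_fraction: float = 0.5) -> bool:
    """True iff the keyword score reaches the pass fraction (SNR goes down)."""
    if n_keywords <= 0:
        raise ValueError("n_keywords must be positive")
    if not 0 <= n_correct <= n_keywords:
        raise ValueError("n_correct must lie in [0, n_keywords]")
    return n_correct / n_keywords >= pass_fraction


def staircase_update(
    current_snr: float,
    passed: bool,
    n_reversals_so_far: int,
    params: StaircaseParams = StaircaseParams(),
) -> float:
    """Next SNR: down by one step after a pass, up after a fail.

    The step is the big one while fewer than ``reversals_before_small``
    reversals have been logged, the small one afterwards.  ``up_weight``
    scales the upward step only (1.0 gives the symmetric rule).
    """
    step = (
        params.big_step_db
        if n_reversals_so_far < params.reversals_before_small
        else params.small_step_db
    )
    return current_snr - step if passed else current_snr + step * params.up_weight


def simulate_trial(
    listener: PsychometricListener,
    snr_db: float,
    n_keywords: int = 5,
    rng: np.random.Generator | None = None,
    index: int = 0,
    pass_fraction: float = 0.5,
) -> TrialRecord:
    """One sentence presentation: keywords are independent Bernoulli draws."""
    if rng is None:
        rng = np.random.default_rng()
    p = listener.p_keyword(snr_db)
    n_correct = int(rng.binomial(n_keywords, p))
    return TrialRecord(
        index=index,
        snr_db=snr_db,
        n_keywords=n_keywords,
        n_correct=n_correct,
        passed=keyword_pass(n_correct, n_keywords, pass_fraction),
    )


def run_staircase(
    listener: PsychometricListener,
    params: StaircaseParams = StaircaseParams(),
    rng: np.random.Generator | None = None,
    n_keywords: int = 5,
) -> StaircaseTrace:
    """Run the full closed-loop adaptive procedure against a virtual listener.

    A trial is a reversal when the direction of the SNR change it triggers
    differs from the previous nonzero change; the first trial cannot be one.
    The SRT is the mean SNR of the last ``n_tail`` presentations.
    """
    if rng is None:
        rng = np.random.default_rng()
    snr = params.initial_snr_db
    trials: list[TrialRecord] = []
    reversal_indices: list[int] = []
    prev_direction: int | None = None
    n_reversals = 0
    for k in range(params.n_trials):
        rec = simulate_trial(
            listener, snr, n_keywords, rng, index=k, pass_fraction=params.pass_fraction
        )
        direction = -1 if rec.passed else 1
        is_reversal = prev_direction is not None and direction != prev_direction
        rec = TrialRecord(
            index=rec.index,
            snr_db=rec.snr_db,
            n_keywords=rec.n_keywords,
            n_correct=rec.n_correct,
            passed=rec.passed,
            is_reversal=is_reversal,
        )
        trials.append(rec)
        # Step size uses the reversal count before this trial's reversal is
        # logged, so the change at the fourth reversal is still the big step.
        snr = staircase_update(snr, rec.passed, n_reversals, params)
        if is_reversal:
            n_reversals += 1
            reversal_indices.append(k)
        prev_direction = direction
    srt = float(np.mean([t.snr_db for t in trials[-params.n_tail :]]))
    return StaircaseTrace(
        trials=tuple(trials), reversal_indices=tuple(reversal_indices), srt_db=srt
    )
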