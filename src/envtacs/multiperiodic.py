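"""Multiperiodic modelling of the SRT's dependence on stimulation phase.

Six equally spaced phases support exactly three periods of variation —
360, 180 and 120 deg — so the phase profile decomposes as

    SRT(phi) = A0 + A1 cos(phi - psi1) + A2 cos(2 phi - psi2)
                  + A3 cos(3 phi - psi3),

a discrete cosine transform with nonnegative amplitudes A_k and phase
offsets psi_k.  On the 60-deg grid sin(3 phi) vanishes at every sample, so
only the cosine component of the 120-deg term is estimable and psi3 is
restricted to {0, 180} (a sign).

Which amplitudes are genuinely present is decided by LASSO regression on the
trigonometric design {cos phi, sin phi, cos 2phi, sin 2phi, cos 3phi} with
the penalty chosen by 10-fold cross-validation along the LARS path, and the
significance of each term entering the path assessed with the covariance
test of Lockhart, Taylor, Tibshirani & Tibshirani (2014): the drop in
covariance at each entry step is compared against its exponential null.

Linear-response theory ties into this: if the threshold depends linearly on
the stimulation waveform, SRT(phi) is the convolution of a susceptibility
kernel with the phase-shifted envelope, which forces a purely sinusoidal
(360-deg) phase dependence.  Any significant 180- or 120-deg component is
therefore evidence of a nonlinear response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import lars_path

from .circular import rayleigh_test
from .envelope import ENV_TACS_PHASES_DEG, Envelope, phase_shift_envelope

__all__ = [
    "PhaseProfile",
    "MultiperiodicFit",
    "SelectionResult",
    "LinearResponseModel",
    "DESIGN_TERMS",
    "dct_fit",
    "reconstruct",
    "extrema",
    "trig_design",
    "lasso_select",
    "classify_linearity",
    "linear_response_srt",
    "best_phase_align",
]

#: Design columns; sin(3 phi) is identically zero on the 60-deg grid.
DESIGN_TERMS = ("cos1", "sin1", "cos2", "sin2", "cos3")

#: Columns carrying each amplitude.
_AMPLITUDE_TERMS = {1: ("cos1", "sin1"), 2: ("cos2", "sin2"), 3: ("cos3",)}


@dataclass(frozen=True)
class PhaseProfile:
    """SRT (dB) sampled at stimulation phases for one subject and latency."""

    phases_deg: np.ndarray
    srt_db: np.ndarray
    latency_ms: float = 250.0
    subject: str = "pooled"

    def __post_init__(self) -> None:
        p = np.asarray(self.phases_deg, float)
        s = np.asarray(self.srt_db, float)
        if p.size != s.size:
            raise ValueError("phases and SRTs differ in length")
        object.__setattr__(self, "phases_deg", p)
        object.__setattr__(self, "srt_db", s)

    @property
    def n(self) -> int:
        return self.phases_deg.size


@dataclass(frozen=True)
class MultiperiodicFit:
    """Amplitudes (dB) and phase offsets (deg) at periods 360/180/120 deg."""

    A0: float
    A1: float
    A2: float
    A3: float
    psi1: float
    psi2: float
    psi3: float

    def __post_init__(self) -> None:
        for k, a in enumerate((self.A1, self.A2, self.A3), start=1):
            if a < 0:
                raise ValueError(f"A{k} must be nonnegative")
        if self.psi3 not in (0.0, 180.0):
            raise ValueError("psi3 is identifiable only up to sign: must be 0 or 180")

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.A1, self.A2, self.A3)


@dataclass(frozen=True)
class SelectionResult:
    """LASSO path selection with covariance-test significance.

    ``entry_order`` lists design terms in the order they entered the LARS
    path; ``entry_p`` is the covariance-test p-value at each term's entry
    (exponential null); ``amplitude_p`` maps k in {1,2,3} to the smaller of
    the entry p-values of the columns carrying A_k.  ``selected`` holds the
    terms with nonzero coefficients at the cross-validated penalty.
    """

    entry_order: tuple[str, ...]
    entry_p: dict[str, float]
    amplitude_p: dict[int, float]
    selected: tuple[str, ...]
    alpha_chosen: float
    coef: dict[str, float]
    intercept: float
    n_obs: int

    def fit_at_penalty(self) -> MultiperiodicFit:
        """Express the penalised coefficients as amplitudes and offsets."""
        return _coef_to_fit(self.intercept, self.coef)

    def significant_amplitudes(self, alpha: float = 0.05) -> set[int]:
        return {k for k, p in self.amplitude_p.items() if p < alpha}


@dataclass(frozen=True)
class LinearResponseModel:
    """Susceptibility kernel chi sampled at the envelope rate.

    ``kernel`` holds chi at lags 0, dt, 2 dt, ...; ``t_a``/``t_b`` delimit
    the stimulus window (seconds) over which the response integral runs.
    """

    kernel: np.ndarray
    rate: float
    t_a: float
    t_b: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, float)
        if not np.all(np.isfinite(k)):
            raise ValueError("kernel must be finite")
        if not self.t_a < self.t_b:
            raise ValueError("t_a must precede t_b")
        object.__setattr__(self, "kernel", k)


# --------------------------------------------------------------------------
# DCT decomposition


def _check_six_point_grid(profile: PhaseProfile) -> np.ndarray:
    order = np.argsort(profile.phases_deg)
    phases = profile.phases_deg[order]
    expected = np.asarray(ENV_TACS_PHASES_DEG)
    if phases.size != 6 or not np.allclose(phases, expected):
        raise ValueError(
            "DCT decomposition requires the six equally spaced phases "
            f"{tuple(expected)}, got {tuple(profile.phases_deg)}"
        )
    return order


def dct_fit(profile: PhaseProfile) -> MultiperiodicFit:
    """Exact DCT decomposition of a six-point phase profile.

    A0 is the mean; for k = 1, 2 the amplitude and offset come from the
    cosine/sine moments C_k = (1/3) sum srt cos(k phi), S_k analogously;
    for k = 3 only the cosine moment exists on this grid (alias limit), so
    A3 = |(1/6) sum srt cos(3 phi)| with psi3 carrying the sign.  The
    reconstruction reproduces the six samples exactly.
    """
    order = _check_six_point_grid(profile)
    phi = np.deg2rad(profile.phases_deg[order])
    srt = profile.srt_db[order]
    a0 = float(np.mean(srt))
    amps, psis = [], []
    for k in (1, 2):
        c = float(np.sum(srt * np.cos(k * phi)) / 3.0)
        s = float(np.sum(srt * np.sin(k * phi)) / 3.0)
        amps.append(float(np.hypot(c, s)))
        psis.append(float(np.rad2deg(np.arctan2(s, c)) % 360.0))
    c3 = float(np.sum(srt * np.cos(3 * phi)) / 6.0)
    amps.append(abs(c3))
    psis.append(0.0 if c3 >= 0 else 180.0)
    return MultiperiodicFit(
        A0=a0, A1=amps[0], A2=amps[1], A3=amps[2],
        psi1=psis[0], psi2=psis[1], psi3=psis[2],
    )


def reconstruct(fit: MultiperiodicFit, phi_deg: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the four-term cosine sum at the given phase(s)."""
    phi = np.deg2rad(np.asarray(phi_deg, float))
    out = (
        fit.A0
        + fit.A1 * np.cos(phi - np.deg2rad(fit.psi1))
        + fit.A2 * np.cos(2 * phi - np.deg2rad(fit.psi2))
        + fit.A3 * np.cos(3 * phi - np.deg2rad(fit.psi3))
    )
    return float(out) if np.isscalar(phi_deg) else out


def extrema(
    fit: MultiperiodicFit, grid_deg: float = 1.0
) -> tuple[float, float, float, float]:
    """Grid search for the extrema of the reconstruction on [0, 360).

    Returns (phi_min, srt_min, phi_max, srt_max); ties resolve to the
    smallest phase.
    """
    if not (360.0 / grid_deg).is_integer():
        raise ValueError("grid_deg must divide 360")
    grid = np.arange(0.0, 360.0, grid_deg)
    values = reconstruct(fit, grid)
    i_min, i_max = int(np.argmin(values)), int(np.argmax(values))
    return float(grid[i_min]), float(values[i_min]), float(grid[i_max]), float(values[i_max])


# --------------------------------------------------------------------------
# LASSO / LARS selection with the covariance test


def trig_design(phases_deg: np.ndarray) -> np.ndarray:
    """Trigonometric design matrix with columns ``DESIGN_TERMS``."""
    phi = np.deg2rad(np.asarray(phases_deg, float))
    return np.column_stack(
        [np.cos(phi), np.sin(phi), np.cos(2 * phi), np.sin(2 * phi), np.cos(3 * phi)]
    )


def _interp_coefs(alphas: np.ndarray, coefs: np.ndarray, alpha: float) -> np.ndarray:
    """Piecewise-linear interpolation of the LASSO path at ``alpha``."""
    # alphas decrease along the path; np.interp needs increasing x
    rev = alphas[::-1]
    return np.array([np.interp(alpha, rev, row[::-1]) for row in coefs])


def _coef_to_fit(intercept: float, coef: dict[str, float]) -> MultiperiodicFit:
    amps, psis = [], []
    for k in (1, 2):
        c = coef.get(f"cos{k}", 0.0)
        s = coef.get(f"sin{k}", 0.0)
        amps.append(float(np.hypot(c, s)))
        psis.append(float(np.rad2deg(np.arctan2(s, c)) % 360.0) if (c, s) != (0.0, 0.0) else 0.0)
    c3 = coef.get("cos3", 0.0)
    amps.append(abs(c3))
    psis.append(0.0 if c3 >= 0 else 180.0)
    return MultiperiodicFit(
        A0=intercept, A1=amps[0], A2=amps[1], A3=amps[2],
        psi1=psis[0], psi2=psis[1], psi3=psis[2],
    )


def _stack_profiles(
    profiles: Sequence[PhaseProfile],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    phases = [tuple(np.sort(p.phases_deg)) for p in profiles]
    if len(set(phases)) != 1:
        raise ValueError("all profiles must share a common phase grid")
    X = np.vstack([trig_design(p.phases_deg) for p in profiles])
    y = np.concatenate([p.srt_db for p in profiles])
    groups = np.concatenate(
        [np.full(p.n, i) for i, p in enumerate(profiles)]
    )
    return X, y, groups


def _group_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fold assignment keeping all observations of a subject in one fold."""
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    folds = [perm[i::n_folds] for i in range(min(n_folds, uniq.size))]
    return [np.isin(groups, f) for f in folds]


def lasso_select(
    profiles: Sequence[PhaseProfile],
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """LASSO on the trigonometric design with LARS, CV, and covariance test.

    The per-subject profiles are stacked; the intercept is unpenalised
    (handled by centring) and columns are scaled to unit variance for the
    path.  The penalty is chosen by ``folds``-fold cross-validation with
    subjects kept whole within folds (seeded assignment).  Each term's entry
    into the LARS path is assigned a covariance-test p-value against the
    Exp(1) null, with the residual variance taken from the full
    least-squares fit; the p-value of amplitude A_k is the smaller entry
    p-value of its cosine/sine pair.
    """
    if len(profiles) < 2:
        raise ValueError("lasso_select requires at least 2 subjects")
    X, y, groups = _stack_profiles(profiles)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("fewer observations than design columns plus intercept")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    if np.any(x_scale == 0):
        raise ValueError("design contains a constant column on this phase grid")
    y_mean = y.mean()
    Xs = (X - x_mean) / x_scale
    yc = y - y_mean

    alphas, _, coefs = lars_path(Xs, yc, method="lasso")

    # --- residual variance from the full least-squares fit.  Per-subject
    # intercepts are included: sham-normalised SRTs share the subject's sham
    # noise across all their phases, which is orthogonal to the trigonometric
    # columns (it never perturbs the path) but would otherwise double the
    # residual-variance estimate and halve every covariance statistic.
    uniq = np.unique(groups)
    dummies = (groups[:, None] == uniq[None, :]).astype(float)
    beta_ls, *_ = np.linalg.lstsq(np.hstack([Xs, dummies]), yc, rcond=None)
    rss = float(np.sum((yc - np.hstack([Xs, dummies]) @ beta_ls) ** 2))
    dof = n - p - uniq.size
    if dof <= 0:
        raise ValueError("not enough observations to estimate the residual variance")
    sigma2 = rss / dof

    # --- covariance test at each entry step
    nonzero = coefs != 0
    entry_knot = {}
    for j in range(p):
        hits = np.flatnonzero(nonzero[j])
        if hits.size:
            entry_knot[j] = int(hits[0])
    entry_order = tuple(
        DESIGN_TERMS[j] for j in sorted(entry_knot, key=entry_knot.get)
    )
    entry_p: dict[str, float] = {t: 1.0 for t in DESIGN_TERMS}
    for j, k in entry_knot.items():
        # coefs[:, k] is the solution at alphas[k], the knot where the NEXT
        # variable enters (its coefficient there is still exactly zero) —
        # the lambda_{k+1} of the covariance-test definition.
        a_next = alphas[k]
        cov_full = float(yc @ (Xs @ coefs[:, k]))
        prev_active = np.flatnonzero(nonzero[:, k - 1]) if k > 0 else np.array([], int)
        if prev_active.size:
            sub_alphas, _, sub_coefs = lars_path(
                Xs[:, prev_active], yc, method="lasso"
            )
            beta_prev = _interp_coefs(sub_alphas, sub_coefs, a_next)
            cov_prev = float(yc @ (Xs[:, prev_active] @ beta_prev))
        else:
            cov_prev = 0.0
        t_stat = max((cov_full - cov_prev) / sigma2, 0.0)
        entry_p[DESIGN_TERMS[j]] = float(np.exp(-t_stat))

    amplitude_p = {
        k: min(entry_p[t] for t in terms) for k, terms in _AMPLITUDE_TERMS.items()
    }

    # --- cross-validated choice of the penalty
    rng = np.random.default_rng(seed)
    masks = _group_folds(groups, folds, rng)
    grid = alphas
    sse = np.zeros(grid.size)
    count = np.zeros(grid.size)
    for test_mask in masks:
        train = ~test_mask
        if train.sum() <= p or test_mask.sum() == 0:
            continue
        tr_alphas, _, tr_coefs = lars_path(Xs[train], yc[train], method="lasso")
        for gi, a in enumerate(grid):
            beta = _interp_coefs(tr_alphas, tr_coefs, a)
            resid = yc[test_mask] - Xs[test_mask] @ beta
            sse[gi] += float(resid @ resid)
            count[gi] += test_mask.sum()
    cv_mse = sse / np.maximum(count, 1)
    alpha_chosen = float(grid[int(np.argmin(cv_mse))])

    beta_chosen = _interp_coefs(alphas, coefs, alpha_chosen)
    beta_orig = beta_chosen / x_scale
    coef_map = {t: float(b) for t, b in zip(DESIGN_TERMS, beta_orig)}
    intercept = float(y_mean - x_mean @ beta_orig)
    selected = tuple(t for t in DESIGN_TERMS if coef_map[t] != 0.0)
    return SelectionResult(
        entry_order=entry_order,
        entry_p=entry_p,
        amplitude_p=amplitude_p,
        selected=selected,
        alpha_chosen=alpha_chosen,
        coef=coef_map,
        intercept=intercept,
        n_obs=n,
    )


def classify_linearity(selection: SelectionResult, alpha: float = 0.05) -> str:
    """Classify the phase response: 'linear', 'nonlinear' or 'no_modulation'.

    A linear (convolutional) dependence of the SRT on the stimulation
    waveform permits only the 360-deg component, so any significant A2 or A3
    is evidence of nonlinearity.
    """
    sig = selection.significant_amplitudes(alpha)
    if 2 in sig or 3 in sig:
        return "nonlinear"
    if sig == {1}:
        return "linear"
    return "no_modulation"


# --------------------------------------------------------------------------
# linear-response machinery


def linear_response_srt(
    model: LinearResponseModel, env: Envelope, phi_deg: float
) -> float:
    """SRT predicted by the linear-response convolution for one phase.

    Evaluates dt * sum_{t' in [t_a, t_b]} chi(t_b - t') y_phi(t'), a discrete
    convolution of the susceptibility kernel with the phase-shifted envelope
    over the stimulus window.
    """
    if model.rate != env.rate:
        raise ValueError("kernel and envelope must share the sampling rate")
    dt = 1.0 / env.rate
    ia = int(round(model.t_a * env.rate))
    ib = int(round(model.t_b * env.rate))
    if ia < 0 or ib > env.n or ia >= ib:
        raise ValueError("response window falls outside the envelope support")
    y_phi = phase_shift_envelope(env, phi_deg).samples[ia:ib]
    lags = (ib - 1) - np.arange(ia, ib)  # lag of each t' from the evaluation time
    valid = lags < model.kernel.size
    return float(np.dot(model.kernel[lags[valid]], y_phi[valid]) * dt)


def linear_response_profile(
    model: LinearResponseModel, env: Envelope,
    phases_deg: Sequence[float] = ENV_TACS_PHASES_DEG,
) -> PhaseProfile:
    """Evaluate the linear-response SRT at several phases."""
    srts = [linear_response_srt(model, env, phi) for phi in phases_deg]
    return PhaseProfile(phases_deg=np.asarray(phases_deg, float), srt_db=np.asarray(srts))


# --------------------------------------------------------------------------
# best-phase alignment


def best_phase_align(
    profiles: Sequence[PhaseProfile],
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, list[PhaseProfile], SelectionResult, float]:
    """Align each subject's profile to their best (lowest-SRT) phase.

    The best phase becomes the new 0 deg; because choosing the minimum and
    then analysing it would bias the fit, the relabelled 0-deg datum is
    dropped and the LASSO selection is rerun on the remaining five points per
    subject.  Returns (best_phases, aligned_profiles, refit,
    rayleigh_p_best_phases); the Rayleigh p-value asks whether the best
    phases cluster across subjects.
    """
    best_phases = []
    aligned: list[PhaseProfile] = []
    for prof in profiles:
        order = np.argsort(prof.phases_deg)
        phases = prof.phases_deg[order]
        srt = prof.srt_db[order]
        best = float(phases[int(np.argmin(srt))])  # argmin; ties -> smallest phase
        best_phases.append(best)
        new_phases = (phases - best) % 360.0
        keep = new_phases != 0.0
        aligned.append(
            PhaseProfile(
                phases_deg=new_phases[keep],
                srt_db=srt[keep],
                latency_ms=prof.latency_ms,
                subject=prof.subject,
            )
        )
    refit = lasso_select(aligned, folds=folds, seed=seed)
    p_rayleigh = rayleigh_test(np.asarray(best_phases))
    return np.asarray(best_phases), aligned, refit, p_rayleigh
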