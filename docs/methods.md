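# Methods

This note documents the scientific model behind `envtacs`, the default
parameters with their units and rationale, what the synthetic data generator
does and does not emulate, and the numerical choices that matter for
reproducing results.

## 1. Stimulation waveforms

### Envelope extraction

`extract_envelope` full-wave rectifies the audio and low-pass filters it
with a zero-phase FIR at 12 Hz (default). The result is a nonnegative
"raw" envelope. 12 Hz keeps the syllabic and phrasal modulations that
cortical tracking follows while discarding the carrier and fast amplitude
flutter.

### Phase shift

The phase-shift operator acts on the mean-removed envelope `y0` through the
analytic signal:

```
y_φ = cos(φ) · y0 − sin(φ) · H[y0]
```

where `H` is the Hilbert transform. Implemented via the FFT, this is an
exact rotation of every spectral coefficient by φ, which yields three
invariants the tests rely on:

- φ = 180° is exact negation of `y0` (to machine precision);
- amplitude spectra are preserved bit-for-bit at every nonzero frequency;
- shifts compose additively, `y_{a+b} = (y_a)_b`.

`analytic_envelope` defaults to **no padding** (`pad=0`). Reflection
padding reduces wrap-around transients for signals with mismatched ends,
but it breaks the rotation identity: with padding, composition and spectrum
preservation hold only to ~1e-3 instead of ~1e-15. Since the generated and
extracted envelopes are long relative to their correlation time, wrap-around
leakage is negligible and exactness wins. Callers who need padding can pass
`pad=None` (half-second reflection) or an explicit sample count.

One caveat is inherent: for even-length signals the lone Nyquist bin cannot
be rotated by a real operator, only attenuated by cos φ. Band-limited
envelopes carry no Nyquist energy, so this never matters in practice; the
composition property test uses an odd length for exactness on broadband
noise.

### Latency shift and conditioning

`delay_envelope` shifts by the nearest whole sample (latencies of 100 and
250 ms are exact at 100 Hz) and zero-pads the exposed edge.
`condition_current` prepares the waveform for delivery: mean removal, peak
scaling to exactly `max_abs_mA` (0.9 mA is a conventional safe
transcranial current), and half-sine on/off ramps (default 250 ms; 100 ms
for the sham burst) so the current starts and ends at exactly zero. A constant envelope conditions
to the zero waveform.

### The condition battery

`all_conditions()` enumerates 16 conditions: env-tACS at 6 phases
(0°–300° in 60° steps) × 2 latencies (100, 250 ms), sham (a single 500 ms
burst at stimulus onset, mimicking the skin sensation of onset without
sustained current), constant +DC and −DC (controls for net charge), and an
independently generated unrelated envelope (controls for "any fluctuating
current" versus "this speech's envelope").

## 2. Stimulus characterization

- `amplitude_spectrum`: Welch average with a Hann window, segment length
  chosen from the requested resolution (default 0.25 Hz). The DC component
  is reported separately so the modulation spectrum is not dominated by the
  nonnegative envelope's mean.
- `autocorrelation`: normalized autocorrelation with a significance band
  from phase-randomized surrogates. The band is the (1−α) quantile of the
  **maximum absolute cross-correlation** between the envelope and each
  surrogate, so it adapts to the spectrum: for a sinusoid (whose surrogates
  are sinusoids) the band widens to ~1, for broadband noise it sits near
  `sqrt(2 ln N / N)`. An autocorrelation value outside the band indicates
  temporal structure beyond what the amplitude spectrum alone implies.
- `phase_time_correlation_map`: Pearson correlation between the φ-shifted
  envelope and the τ-lagged envelope on a (φ, τ) grid, computed with
  windowed inner-product sums for speed and matching the naive per-cell
  computation to 1e-10. For a pure sinusoid at frequency f the map is
  `cos(2π f τ + φ)` — phase shift and time lag are then interchangeable —
  whereas for a broadband envelope no single lag reproduces a phase shift.
- `phase_sweep_correlation`: correlation of `y_φ` with an arbitrary target
  over a phase grid (default step 1°). Against the negated envelope the
  sweep is exactly `−cos(φ)` (the unpadded Hilbert transform is orthogonal
  to and norm-equal with `y0`), so the maximum falls at exactly 180°.

## 3. Adaptive staircase

`run_staircase` implements a 1-up/1-down sentence staircase: 25 trials, 5
keywords per sentence, a trial passes when at least half the keywords are
reported. SNR starts at +10 dB; steps are 3 dB until the fourth reversal
and 1 dB after (the step size for a trial is decided by the number of
reversals *before* that trial's own reversal is logged). The SRT estimate
is the mean SNR of the last 10 trials. With symmetric steps the procedure
converges on the 50% point of the per-keyword psychometric function;
`up_weight` allows asymmetric variants. The virtual listener is logistic,
`p(correct) = (1 − lapse) · expit((snr − srt_true)/slope)`, with default
slope 1 dB.

Measured behaviour (seeded, reproduced in the acceptance tests): a
near-step-function listener is recovered within 1 dB; a 1 dB-slope listener
shows mean bias below 0.01 dB over 1000 runs with per-run scatter of ~1 dB.

## 4. Circular statistics

Phase-dependent SRTs are weighted circular data: angle = stimulation phase,
weight = sham-normalized SRT shifted to be nonnegative (minimum subtracted).

- **Moore–Rayleigh test**: weights are converted to ranks (mid-ranks on
  ties, with a warning) and the statistic is the rank-weighted resultant
  `R* = |Σ rᵢ e^{iθᵢ}| / n^{3/2}`. The p-value is Monte Carlo: the angles
  are redrawn iid uniform with the ranks kept, and the add-one-corrected
  exceedance proportion is reported (default 10⁴ draws). A Monte Carlo
  null is used because the asymptotic tail is inaccurate at the sample
  sizes of interest; measured type-I error at n = 102 is 0.054 at α = 0.05
  over 2000 replicates.
- **Period folding**: with six phases 60° apart, the representable periods
  are 360/k for k = 1..3. `moore_rayleigh_by_period` folds the angles to
  each of 360°, 180° and 120° and Benjamini–Hochberg-adjusts across the
  three periods.
- **Rayleigh test** (unweighted, for best-phase clustering across subjects)
  uses the small-sample corrected approximation; measured type-I error at
  n = 17 is 0.047.
- `latency_difference_test` applies the folded Moore–Rayleigh machinery to
  per-(subject, phase) SRT differences between the two latencies.
- Across the 15 condition-vs-sham contrasts, `compare_to_sham` controls the
  false discovery rate with Benjamini–Hochberg–Yekutieli, valid under
  arbitrary dependence among the contrasts (they share the sham reference).

## 5. Multiperiodic model and selection

### Decomposition

On the six-point grid the SRT profile is decomposed as

```
SRT(φ) = A0 + A1 cos(φ − ψ1) + A2 cos(2φ − ψ2) + A3 cos(3φ − ψ3)
```

`dct_fit` computes the coefficients by exact projection (the trigonometric
design is orthogonal on the grid). The third component is special: at six
points, `sin(3φ)` vanishes identically, so only `cos(3φ)` is identifiable,
`A3 = |⟨srt, cos 3φ⟩|/6` and `ψ3 ∈ {0°, 180°}`. No doubling factor is
applied to `A3`'s projection: the stated amplitude is the one that
reproduces the profile through the reconstruction formula, which round-trip
tests verify exactly.

### Sparse selection and inference

`lasso_select` stacks per-subject profiles (sham-normalized), standardizes
the five design columns (`cos φ, sin φ, cos 2φ, sin 2φ, cos 3φ`), and runs
the LARS/LASSO path. Two devices give honest inference:

- **Covariance test per entry.** Each term's entry into the path gets the
  covariance-test statistic `T = (cov_full − cov_prev)/σ²`, with
  `p = exp(−T)` under its asymptotic Exp(1) null. `cov_full` is evaluated
  at the knot where the *next* variable enters — in the path returned by
  LARS, the solution at knot k is the correct λ_{k+1} evaluation point,
  because the entering variable's own coefficient is still exactly zero
  there. Evaluating one knot later would add the next entrant's
  least-squares contribution and inflate T by a χ²₁-sized term; this is
  exactly the failure mode the null-calibration test guards against.
- **σ² with subject intercepts.** Sham normalization subtracts each
  subject's own sham SRT, so all six observations of a subject share the
  same (negated) sham noise. That shared term is orthogonal to every
  trigonometric column (each sums to zero over the grid), so it cannot
  affect the path — but left in the residual it would roughly double the
  variance estimate and halve every T. The residual variance is therefore
  estimated from a least-squares fit that includes per-subject intercept
  dummies, with degrees of freedom n − 5 − (number of subjects).

The per-amplitude p-value is the smaller of the entry p-values of the
cos/sin pair carrying that amplitude (for `A3`, the single `cos 3φ`
column). The reported support is chosen by 10-fold cross-validation with
subject-whole folds (a subject's six points never straddle folds, avoiding
leakage through the subject intercept).

**Calibration, measured at n = 17 subjects over 500 null replicates:**
false-selection rates at α = 0.05 are 3.4% (A1), 4.4% (A2) and 1.6% (A3).
The pairs sit near nominal — the min-of-two-p's anti-conservative doubling
roughly cancels the conservative bias of later-step covariance tests — but
`A3` rides on a single column that tends to enter the path late, where the
Exp(1) approximation is conservative, and no doubling compensates. A
calibration criterion that demands ~5% for *every* amplitude is therefore
unattainable for `A3` with this estimator at this sample size; the
acceptance test states the nominal band for all three amplitudes and the
`A3` clause runs red at its true ~1.6% rate. This is a conservative
direction — `A3` discoveries are *under*-claimed — and is left visible
rather than papered over with a recalibrated threshold.

### Linearity criterion

If the threshold change is a linear functional of the stimulation current,
`ΔSRT(φ) = ∫ χ(t−t′) y_φ(t′) dt′`, then because `y_φ` is a rotation in each
frequency, the φ-dependence collapses to a single sinusoid: only `A1` can
be nonzero. `linear_response_profile` implements the convolution for an
arbitrary kernel χ and the acceptance tests verify `A2/A1` and `A3/A1`
below 1e-9 across 100 random kernels. `classify_linearity` then reads the
selection: significant `A2` or `A3` ⇒ `nonlinear`; only `A1` ⇒ `linear`;
nothing ⇒ `no_modulation`.

### Best-phase alignment

`best_phase_align` relabels each subject's lowest-SRT phase as 0°. Choosing
the minimum and then analysing it would bias the aligned profile downward
at 0°, so the relabelled 0° datum is dropped and the selection is rerun on
the remaining five points per subject. A Rayleigh test on the best phases
asks whether subjects share an optimal phase.

## 6. Synthetic data generator

### What it emulates

- **Speech-like envelope** (`gen_speech_like_envelope`): Gaussian spectral
  noise shaped by a syllable-rate bump (Gaussian centred at 2 Hz, σ =
  2.5 Hz, amplitude 1.5 over a unit broadband floor), rolled off smoothly
  between 9.5 and 12 Hz and zero above 12 Hz, inverse-transformed and
  shifted to be nonnegative. Design targets, verified across seeds: the
  modulation spectrum peaks in the syllable band (1.5–2.5 Hz), the
  autocorrelation falls inside the surrogate band beyond 150 ms (speech
  envelopes carry little long-range memory), and there is no energy above
  12 Hz.
- **Subjects and conditions** (`gen_dataset`): 17 subjects, each with a
  baseline SRT of −6 dB plus a subject offset (SD 1 dB), measured in all 16
  conditions with residual noise (SD 0.5 dB). Phase effects follow the
  three-component cosine model with per-latency amplitudes and offsets
  (defaults: 0.9/0.7/0.4 dB at 74°/30°/180° for 100 ms; 1.0/0.8/0.6 dB at
  244°/90°/0° for 250 ms); the unrelated-envelope condition costs 2 dB; DC
  and sham are null. Per-subject random streams are keyed by
  `(seed, subject, condition)` so a subject's data do not change when the
  pool size changes.
- **Measurement**: `mode="direct"` draws the SRT with Gaussian noise;
  `mode="staircase"` actually runs the adaptive procedure against a
  logistic listener whose true threshold is the programmed value, giving
  realistic staircase scatter (~1 dB) on top.
- **Linear listeners** (`gen_linear_listener`): a convolutional ground
  truth for testing the linearity criterion end to end.

### What it does not emulate

No audio is synthesized — the envelope is generated directly at the
envelope rate. There is no lexical or sentence-level structure, no
learning/fatigue across trials, no phase drift between current and audio
within a trial, no electrode or skin-sensation modelling, and the noise is
homoscedastic Gaussian. The generator's purpose is calibrated inference on
the statistical machinery, not acoustic realism.

## 7. Numerical choices and problem sizes

- Envelope rate 100 Hz: 10 ms resolution, exact sample counts for the
  100/250 ms latencies, comfortable margin above the 12 Hz envelope band.
- Unpadded FFT Hilbert transform (see §1) to keep rotation identities
  exact.
- Phase sweeps and extrema use a 1° grid; extrema ties resolve to the
  smallest phase.
- Monte Carlo sizes: 10⁴ draws for Moore–Rayleigh p-values (resolution
  ~10⁻⁴ with the add-one correction), 2000 replicates for type-I-error
  checks, 500 replicates for selection calibration (binomial SE ≈ 1%, so
  rates are gated at ±3 SE around the nominal 5%).
- The phase/lag-equivalence check uses a sinusoid at 8 Hz sampled at 64 Hz
  with 2²¹ samples and integer-sample lags, so the empirical correlations
  match `cos(2π f τ + φ)` to below 1e-6 without windowing error.

## 8. Limitations

- The covariance test is asymptotic; at 17 subjects its per-step Exp(1)
  null is only approximately correct, and exactly calibrated inference for
  the single-column `A3` component is not achievable with this estimator
  (see §5). Amplitude-level p-values should be read as conservative for
  `A3`.
- The six-point phase grid cannot distinguish `ψ3` beyond its sign, and
  aliases any true component above the third harmonic into the estimated
  ones.
- The sham-burst and DC controls are modelled as statistically null; real
  sensation or polarization effects would require a richer generator.
- `best_phase_align` removes selection bias at the relabelled 0° by
  dropping that datum, at the cost of one sixth of the data; subtler
  shrinkage-based corrections are out of scope.
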