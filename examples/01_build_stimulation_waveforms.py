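"""Build the stimulation current for every condition of the battery.

The envelope-tACS current is the speech envelope phase-shifted via its
analytic signal, delayed by the stimulation latency, and conditioned for
delivery (mean-removed, peak-scaled, ramped to zero at both ends).
"""

import numpy as np

from envtacs import (
    all_conditions,
    condition_current,
    delay_envelope,
    gen_speech_like_envelope,
    make_condition_current,
    phase_shift_envelope,
)

env = gen_speech_like_envelope(duration_s=10.0, rate=100.0, seed=0)
unrelated = gen_speech_like_envelope(duration_s=10.0, rate=100.0, seed=99)
print(f"envelope: {env.n} samples at {env.rate:g} Hz, "
      f"mean {env.samples.mean():.3f} (nonnegative raw envelope)")

# a 180-degree shift is an exact inversion of the mean-removed envelope
y0 = env.samples - env.samples.mean()
inv = phase_shift_envelope(env, 180.0)
print(f"max |shift(180) + y0| = {np.max(np.abs(inv.samples + y0)):.2e} "
      "(180 deg inverts exactly)")

# latency shift moves the current later in time by whole samples
delayed = delay_envelope(phase_shift_envelope(env, 0.0), 250.0)
print(f"250 ms delay at 100 Hz: first {np.count_nonzero(delayed.samples[:25] == 0)} "
      "samples are zero-padded")

# conditioning: zero endpoints, exact peak current
cur = condition_current(delayed, max_abs_mA=0.9)
print(f"conditioned current: endpoints ({cur.samples[0]:g}, {cur.samples[-1]:g}), "
      f"peak {np.max(np.abs(cur.samples)):.3f} mA")

# the full 16-condition battery
print("\ncondition battery:")
for cond in all_conditions():
    cur = make_condition_current(env, unrelated, cond, max_abs_mA=0.9)
    rms = float(np.sqrt(np.mean(cur.samples**2)))
    print(f"  {cond.label:<28s} rms {rms:.3f} mA")
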