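"""Estimate a speech reception threshold with the adaptive up-down staircase.

A virtual listener with a known 50%-keyword threshold answers 25 sentences of
5 keywords each; the SNR moves down on a pass and up on a fail, with the step
shrinking from 3 to 1 dB after the fourth reversal.  The SRT estimate is the
mean SNR of the last 10 sentences.
"""

import numpy as np

from envtacs import PsychometricListener, run_staircase

listener = PsychometricListener(srt_true_db=-6.3, slope_db=1.0)
trace = run_staircase(listener, rng=np.random.default_rng(0))

print("trial  SNR(dB)  correct/5  reversal")
for t in trace.trials:
    print(f"{t.index + 1:>5d}  {t.snr_db:>7.1f}  {t.n_correct:>9d}  "
          f"{'*' if t.is_reversal else ''}")

print(f"\ntrue SRT  : {listener.srt_true_db:+.2f} dB")
print(f"estimate  : {trace.srt_db:+.2f} dB (mean of last 10 SNRs)")
print(f"error     : {trace.srt_db - listener.srt_true_db:+.2f} dB")
print("The staircase homes in with coarse 3 dB steps, then refines at 1 dB.")
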