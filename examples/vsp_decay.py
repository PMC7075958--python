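"""Current decay under voltage-sensitive phosphatase activation.

During a 10 s depolarizing step the phosphatase depletes membrane PIP2 and
the K+ current collapses toward a plateau; the ratio I(10 s)/I_peak indexes
how sensitive the channel is to PIP2 depletion (smaller ratio = stronger
decay). This example builds analytic decay traces with known plateaus and
verifies the measured ratios against the closed form.
"""

import numpy as np

from mhf import StepRecording, vsp_decay

t = np.arange(0.0, 10_001.0, 10.0)  # ms
voltages = np.array([40.0, 60.0, 80.0, 100.0])
plateaus = np.array([0.85, 0.70, 0.55, 0.47])  # stronger decay at higher V
tau_ms = 2_500.0
currents = np.stack(
    [500.0 * (p + (1 - p) * np.exp(-t / tau_ms)) for p in plateaus]
)
rec = StepRecording(voltages=voltages, time_ms=t, currents=currents)

result = vsp_decay(rec)
print(result.as_frame().to_string(index=False))
closed = plateaus + (1 - plateaus) * np.exp(-10_000.0 / tau_ms)
print("\nmax |measured - closed form| =", np.max(np.abs(result.ratio - closed)))
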