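"""Per-cycle frequency-rate coupling under noisy working-memory drive.

Slow Ornstein-Uhlenbeck fluctuations of the uniform WM current push the
network deeper into or out of its oscillatory regime.  Cycles riding a
stronger drive are both faster and more active, so per-cycle oscillation
frequency and mean excitatory rate are strongly positively correlated.
"""

import numpy as np

from phasecode.field_model import FieldParams, InputSpec, simulate_field
from phasecode.model_coding import extract_cycles, freq_rate_correlation

trace = simulate_field(FieldParams(), InputSpec(), duration=30000.0,
                       seed=1).after_transient()
cycles = extract_cycles(trace)
r, p = freq_rate_correlation(cycles)
print(f"{len(cycles)} oscillation cycles; "
      f"frequency {cycles.freq.mean():.1f} +/- {cycles.freq.std():.1f} Hz")
print(f"Pearson r(frequency, mean rate) = {r:.3f}  (slope test p = {p:.2g})")
hist, edges = np.histogram(cycles.freq, bins=np.arange(8.0, 40.0, 1.0))
print(f"modal cycle frequency: {edges[np.argmax(hist)] + 0.5:.1f} Hz")
print("A strongly positive r means rate changes track oscillation "
      "frequency: both are downstream of the same WM drive.")
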