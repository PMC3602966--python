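"""Cumulative-history analysis with a shuffle control.

Generates a synthetic reversal sequence whose log-durations depend on the
percept's own leaky-integrated dominance history (coupling time constant
3 s), scans integrator time constants for the correlation peak, and compares
against sequences with resampled durations (the shuffle null).
"""

import numpy as np

from multistable import (SynthConfig, history_coupled_sequence, history_null,
                         history_scan)

cfg = SynthConfig(n_blocks=12, block_length=300.0, mean_duration=2.0,
                  shape=4.0, coupling_b=2.0, coupling_tau=3.0, seed=7)
seq = history_coupled_sequence(cfg)

c_h, tau_h, (taus, curve) = history_scan(seq)
null = history_null(seq, n_shuffles=100, seed=1)

print(f"peak history correlation c_H = {c_h:.3f} at tau_H = {tau_h:.2f} s")
print(f"generator coupling time constant: {cfg.coupling_tau:.2f} s")
print(f"shuffle null: 95th percentile of c_H = {np.quantile(null, 0.95):.3f}")
print()
print("The correlation peak recovers the generator's history time constant;")
print("after shuffling durations the correlation falls to the null level,")
print("showing the signal reflects genuine sequential dependence.")
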