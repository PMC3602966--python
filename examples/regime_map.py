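"""Map the noiseless dynamical regimes over a small parameter slice.

Classifies each (I0, beta, phi_a) point as stationary (one symmetric fixed
point), oscillatory (adaptation-driven limit cycle) or bistable (two
winner-take-all attractors) from a 600-s noiseless run.
"""

import numpy as np

from multistable import GridSpec, regime_map

grid = GridSpec(i0_axis=[0.5], beta_axis=np.linspace(0, 2, 5).tolist(),
                phi_a_axis=np.linspace(0, 1, 5).tolist(),
                sigma_n_axis=[0.15], tau_a_axis=[2.0])
labels = regime_map(grid)

print("regime at I0 = 0.5 (rows: beta, columns: phi_a)")
print("        " + "  ".join(f"{p:6.2f}" for p in grid.phi_a_axis))
for beta in grid.beta_axis:
    row = [labels[(0.5, beta, p)][:6] for p in grid.phi_a_axis]
    print(f"b={beta:4.1f}  " + "  ".join(f"{r:>6}" for r in row))
print()
print("Reversals require a non-stationary regime: in the bistable region")
print("noise drives them, in the oscillatory region adaptation does.")
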