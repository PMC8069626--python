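"""Decompose the built-in release curves into their mechanism contributions.

Evaluates the forward composite model for each built-in condition and prints
how much of the release at selected times comes from the initial burst, from
plane-sheet diffusion, and from osmotic pumping.
"""

import numpy as np

from relmech import (
    builtin_conditions,
    burst_fraction,
    condition_params,
    diffusion_fraction,
    osmotic_fraction,
)
from relmech.mechanisms import DEFAULT_THICKNESS

table = builtin_conditions()
print("built-in conditions:")
print(table[["concentration_pct", "flow_ml_s", "k_b", "D_e", "delta_pi"]].to_string())
print()

times = np.array([1.0, 10.0, 50.0, 100.0])
for label in table.index:
    p = condition_params(label)
    burst = p.mu_burst * burst_fraction(p.k_b, times)
    diff = p.mu_diffusion * diffusion_fraction(p.D_e, DEFAULT_THICKNESS, times)
    osmo = p.mu_osmosis * osmotic_fraction(p.k_os, times)
    total = burst + diff + osmo
    print(label)
    print(f"  t (h)      " + "".join(f"{t:>9.0f}" for t in times))
    print(f"  burst      " + "".join(f"{v:>9.3f}" for v in burst))
    print(f"  diffusion  " + "".join(f"{v:>9.3f}" for v in diff))
    print(f"  osmosis    " + "".join(f"{v:>9.3f}" for v in osmo))
    print(f"  total      " + "".join(f"{v:>9.3f}" for v in total))
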