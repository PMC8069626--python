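"""Predict the release profile of an untested film from fitted correlations.

Fits the inverse-concentration correlations (ln k = a + b/C) to the kinetic
constants of the three drug loads at 7.5 mL/s, then predicts the full release
profile of a hypothetical 15% load.
"""

import numpy as np

from relmech import (
    builtin_conditions,
    fit_concentration_correlation,
    predict_constant,
    predict_release_profile,
)

table = builtin_conditions()
loads = table[table["flow_ml_s"] == 7.5].sort_values("concentration_pct")
C = loads["concentration_pct"]

models = {
    name: fit_concentration_correlation(list(zip(C, loads[name])), name)
    for name in ("k_b", "D_e", "k_os")
}
for name, m in models.items():
    print(f"{name}: ln k = {m.intercept:.4f} + {m.slope:.4f}/C  "
          f"(R^2 on fit scale = {m.fit_r_squared:.4f})")

target = 15.0
print(f"\npredicted constants at C = {target}%:")
for name, m in models.items():
    print(f"  {name} = {predict_constant(m, target):.4g}")

weights = [
    (c, (row["mu_burst"], row["mu_diffusion"], row["mu_osmosis"]))
    for c, (_, row) in zip(C, loads.iterrows())
]
times = np.linspace(0.0, 100.0, 11)
profile = predict_release_profile(models, weights, target, times)
print(f"\npredicted release profile at C = {target}%:")
for t, f in zip(profile.times, profile.fractions):
    print(f"  t = {t:5.1f} h   Mt/Minf = {f:.3f}")
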