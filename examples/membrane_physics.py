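"""Membrane hydraulics behind the osmotic-pumping mechanism.

Checks whether the osmotic pressure gradient dominates the hydrostatic
pressure drop that the release flux itself induces across a porous membrane —
the condition under which the linear osmotic release term is justified.
"""

from relmech import (
    MembraneSpec,
    free_volume_fraction,
    hydraulic_permeability,
    osmosis_dominance_check,
    pressure_drop,
    reflection_coefficient,
)

spec = MembraneSpec(
    pore_radius=1e-6,      # m
    pore_density=1e6,      # pores per membrane
    thickness=1e-3,        # m
    viscosity=8.9e-4,      # Pa s (water, 25 C)
)

lp = hydraulic_permeability(spec)
print(f"hydraulic permeability Lp = {lp:.3e} m/(Pa s)")

delta_pi = 0.009  # atm, mid-load film
for jv in (1e-6, 1e-11):  # volumetric flux, m^3 m^-2 s^-1
    dp = pressure_drop(spec, jv)
    ok, ratio = osmosis_dominance_check(delta_pi, dp)
    print(f"Jv = {jv:g}: hydrostatic drop {dp:.3e} Pa vs osmotic {delta_pi} atm, "
          f"ratio = {ratio:.3g} -> osmosis {'dominates' if ok else 'does NOT dominate'}")

print()
for phi in (0.1, 0.5, 0.9):
    print(f"reflection coefficient at solute/pore ratio {phi}: "
          f"{reflection_coefficient(phi):.4f}")

print(f"free-volume coefficient f_g = "
      f"{free_volume_fraction(1.0, 1e-4, 96.3):.3e}")
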