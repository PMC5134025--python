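"""The constitutive core: rheology, clot porosity, and the shear gates.

Evaluates the pointwise laws at their anchor points and prints what each
number means for thrombus formation.
"""

import numpy as np

from thromboflow import (
    FluidProps,
    ThrombosisParams,
    clot_porosity,
    coagulant_wall_flux,
    momentum_sink,
    quemada_viscosity,
    switch_up,
)

p = ThrombosisParams()
f = FluidProps()

print("Quemada whole-blood viscosity (H = 0.45):")
for g in (0.01, 1.0, 10.0, 100.0, 1000.0):
    print(f"  gamma_dot = {g:8.2f} 1/s   mu = {quemada_viscosity(g, f)*1e3:7.2f} mPa s")
print("  -> shear-thinning: stagnant pockets are orders of magnitude more viscous.\n")

print("Clot porosity eps(BP), BP_t = 20 nmol/l:")
for bp in (0.0, 10.0, 20.0, 200.0):
    print(f"  BP = {bp:6.1f} nmol/l   eps = {clot_porosity(bp, p):.3f}")
print("  -> 1.0 means open lumen; 0.75 is a completely formed clot.\n")

print("Coagulant wall flux (released only at TAWSS < 0.2 Pa, shut off at BP > 200):")
for tawss, bp in ((0.05, 0.0), (0.05, 250.0), (0.5, 0.0)):
    fx = coagulant_wall_flux(tawss, bp, p)
    print(f"  TAWSS = {tawss:4.2f} Pa, BP_wall = {bp:5.1f}  ->  flux = {fx:4.1f} nmol m^-1 l^-1 s^-1")
print()

print("Brinkman momentum sink at |u| = 1 mm/s:")
for bp in (0.0, 20.0, 200.0):
    s = momentum_sink(bp, 1e-3, p)
    print(f"  BP = {bp:6.1f} nmol/l   S_M = {s:12.1f} kg m^-2 s^-2  (phi_BP = {switch_up(bp, p.BP_t, p.n_sw):.2f})")
print("  -> a formed clot resists flow with ~k_M|u| = 1e4 kg m^-2 s^-2 at 1 mm/s.")
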